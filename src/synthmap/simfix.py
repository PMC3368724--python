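"""Ground-truth simulator for every pipeline stage.

Generates a known "true" linkage map with duplicated loci (4th-WGD
homeolog structure) and a planted model-species synteny layout, then
simulates doubled-haploid segregation data and BLAST-tabular homology
fixtures from it.  Every generator is a pure function of its parameters
and seed, so tests can assert exact recovery.

Defaults mirror the study conditions of the rainbow trout consensus map:
DH families of 50 offspring, ~26% of loci in duplicate pairs, complete
crossover interference within a chromosome arm (interference is close to
one in salmonids), markers spaced at least 5 cM apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segdata import CentromereRange, DatasetMeta, GameteMatrix, MISSING

__all__ = [
    "TrueGroup",
    "TrueMap",
    "simulate_true_map",
    "simulate_dh_dataset",
    "simulate_homology_table",
    "SimulatedHomology",
    "label_duplicate_pairs",
    "true_synthetic_map",
]


@dataclass
class TrueGroup:
    name: str
    markers: list[str]
    positions: list[float]  # true cM, recombination-percent scale
    centromere: CentromereRange
    arm_labels: list[str]  # "p" | "q" | "centromeric"

    @property
    def length(self) -> float:
        return self.positions[-1] - self.positions[0]

    def arm_of(self, marker: str) -> str | None:
        lab = self.arm_labels[self.markers.index(marker)]
        return f"{self.name}{lab}" if lab in ("p", "q") else None


@dataclass
class TrueMap:
    groups: list[TrueGroup]
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    # planted synteny: arm -> model chromosome, and marker -> (chrom, bp)
    arm_chromosome: dict[str, str] = field(default_factory=dict)
    marker_location: dict[str, tuple[str, int]] = field(default_factory=dict)
    homeolog_pairs: set = field(default_factory=set)  # model 3rd-WGD pairs
    ancestor_map: dict[str, list[str]] = field(default_factory=dict)
    arm_homeologs: list[tuple[str, str]] = field(default_factory=list)  # planted 4th-WGD arm pairs

    @property
    def markers(self) -> list[str]:
        return [m for g in self.groups for m in g.markers]

    @property
    def total_length(self) -> float:
        return sum(g.length for g in self.groups)

    def group(self, name: str) -> TrueGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def arm_of(self, marker: str) -> str | None:
        for g in self.groups:
            if marker in g.markers:
                return g.arm_of(marker)
        raise KeyError(marker)


def simulate_true_map(n_groups: int = 2, markers_per_group: int = 10, length_cM: float = 100.0,
                      dup_fraction: float = 0.26, seed: int = 0,
                      min_spacing_cM: float = 5.0) -> TrueMap:
    """Seed-deterministic true map with planted homeolog and synteny layout.

    Marker positions per group span *length_cM* with inter-marker gaps of
    at least *min_spacing_cM* (remainder split by a Dirichlet draw); the
    centromere sits between the two middle markers (metacentric).  Arms are
    paired round-robin into 4th-WGD homeologs, and about
    ``dup_fraction x total markers`` loci form duplicate pairs placed on
    homeologous arms.  Each arm is assigned its own model-species
    chromosome; model chromosomes are paired into 3rd-WGD homeologs and
    homeologous chromosomes share an ancestor proto-chromosome label.
    """
    if not (0.0 <= dup_fraction <= 1.0):
        raise ValueError("dup_fraction must be in [0, 1]")
    if n_groups < 1 or markers_per_group < 2 or length_cM <= 0:
        raise ValueError("parameters must be positive (>= 2 markers per group)")
    n_gaps = markers_per_group - 1
    if min_spacing_cM * n_gaps > length_cM:
        raise ValueError("length_cM too short for the requested spacing")
    rng = np.random.default_rng(seed)
    groups: list[TrueGroup] = []
    for gi in range(n_groups):
        name = f"LG{gi + 1:02d}"
        markers = [f"{name}_M{j + 1:03d}" for j in range(markers_per_group)]
        slack = length_cM - min_spacing_cM * n_gaps
        gaps = min_spacing_cM + slack * rng.dirichlet(np.ones(n_gaps))
        positions = np.concatenate([[0.0], np.cumsum(gaps)])
        mid = markers_per_group // 2
        cent = CentromereRange(group=name, start_locus=markers[mid - 1], end_locus=markers[mid])
        labels = ["p"] * (mid - 1) + ["centromeric", "centromeric"] + ["q"] * (markers_per_group - mid - 1)
        groups.append(TrueGroup(name=name, markers=markers, positions=[float(p) for p in positions],
                                centromere=cent, arm_labels=labels))

    tm = TrueMap(groups=groups)

    arms = [f"{g.name}{a}" for g in groups for a in ("p", "q")]
    # 4th-WGD arm homeologs: pair arm i with arm i + half (round-robin)
    half = len(arms) // 2
    tm.arm_homeologs = [(arms[i], arms[i + half]) for i in range(half)]

    # planted model-species synteny: one chromosome per arm
    for i, arm in enumerate(arms):
        tm.arm_chromosome[arm] = f"Chr{i + 1:02d}"
    # 3rd-WGD model homeologs follow the arm homeologs; each pair gets one
    # ancestor proto-chromosome label
    labels = [chr(ord("A") + i % 13) for i in range(half)]
    for i, (a1, a2) in enumerate(tm.arm_homeologs):
        c1, c2 = tm.arm_chromosome[a1], tm.arm_chromosome[a2]
        tm.homeolog_pairs.add(frozenset((c1, c2)))
        tm.ancestor_map[c1] = [labels[i]]
        tm.ancestor_map[c2] = [labels[i]]

    # marker bp on the planted chromosome: arm-local cM converted at 0.5 Mb/cM
    for g in groups:
        arm_start = {"p": g.positions[0], "q": None}
        for m, pos, lab in zip(g.markers, g.positions, g.arm_labels):
            arm = g.arm_of(m)
            if arm is None:
                continue
            chrom = tm.arm_chromosome[arm]
            local = pos - g.positions[0]
            tm.marker_location[m] = (chrom, int(round(local * 0.5e6)) + 1)

    # duplicate pairs on homeologous arms
    n_pairs = int(round(len(tm.markers) * dup_fraction / 2.0))
    by_arm: dict[str, list[str]] = {}
    for g in groups:
        for m in g.markers:
            arm = g.arm_of(m)
            if arm is not None:
                by_arm.setdefault(arm, []).append(m)
    pool = [(a1, a2) for a1, a2 in tm.arm_homeologs if by_arm.get(a1) and by_arm.get(a2)]
    used: set[str] = set()
    pi = 0
    while len(tm.duplicate_pairs) < n_pairs and pool:
        a1, a2 = pool[pi % len(pool)]
        c1 = [m for m in by_arm[a1] if m not in used]
        c2 = [m for m in by_arm[a2] if m not in used]
        if not c1 or not c2:
            pool.pop(pi % len(pool))
            continue
        m1 = c1[int(rng.integers(len(c1)))]
        m2 = c2[int(rng.integers(len(c2)))]
        tm.duplicate_pairs.append((m1, m2))
        used.update((m1, m2))
        pi += 1
    return tm


def simulate_dh_dataset(true_map: TrueMap, N: int = 50, missing_rate: float = 0.0,
                        error_rate: float = 0.0, interference: str = "complete",
                        seed: int = 0, dataset_id: str | None = None) -> GameteMatrix:
    """Simulate one DH family of *N* gametes over the true map.

    ``interference="none"``: recombination between adjacent markers is an
    independent Bernoulli event with probability = interval length / 100
    (capped at 0.5).  ``"complete"``: at most one crossover per chromosome
    arm, occurring with probability arm length / 100 and placed in an
    interval with probability proportional to its length — the salmonid
    regime.  Symmetric call errors then flip calls at *error_rate* and
    masking hides calls at *missing_rate*.
    """
    for name, v in (("missing_rate", missing_rate), ("error_rate", error_rate)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    if interference not in ("none", "complete"):
        raise ValueError(f"unknown interference model {interference!r}")
    rng = np.random.default_rng(seed)
    if dataset_id is None:
        dataset_id = f"sim{seed}"
    loci: list[str] = []
    group_col: list[str] = []
    blocks = []
    for g in true_map.groups:
        nm = len(g.markers)
        pos = np.asarray(g.positions)
        gaps = np.diff(pos)
        calls = np.empty((nm, N), dtype=np.int8)
        start = rng.integers(0, 2, size=N).astype(np.int8)
        if interference == "none":
            p = np.minimum(gaps / 100.0, 0.5)
            rec = rng.random((nm - 1, N)) < p[:, None]
        else:
            rec = np.zeros((nm - 1, N), dtype=bool)
            # split intervals into arms at the centromere midpoint
            ci0 = g.markers.index(g.centromere.start_locus)
            arm_intervals = [list(range(0, ci0 + 1)), list(range(ci0 + 1, nm - 1))]
            for ivs in arm_intervals:
                if not ivs:
                    continue
                lens = gaps[ivs]
                arm_len = float(lens.sum())
                p_cross = min(arm_len / 100.0, 1.0)
                crosses = rng.random(N) < p_cross
                if lens.sum() > 0:
                    which = rng.choice(len(ivs), size=N, p=lens / lens.sum())
                else:
                    which = np.zeros(N, dtype=int)
                for gam in np.nonzero(crosses)[0]:
                    rec[ivs[which[gam]], gam] = True
        calls[0] = start
        for i in range(1, nm):
            calls[i] = np.where(rec[i - 1], 1 - calls[i - 1], calls[i - 1])
        blocks.append(calls)
        loci.extend(g.markers)
        group_col.extend([g.name] * nm)
    calls = np.vstack(blocks)
    if error_rate > 0:
        flip = rng.random(calls.shape) < error_rate
        calls = np.where(flip, 1 - calls, calls).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls = np.where(mask, MISSING, calls).astype(np.int8)
    meta = DatasetMeta(dataset_id=dataset_id, N=N, kind="raw_genotypes")
    individuals = [f"{dataset_id}_g{j + 1}" for j in range(N)]
    return GameteMatrix(dataset=meta, loci=loci, groups=group_col, calls=calls,
                        individuals=individuals)


def label_duplicate_pairs(tm: TrueMap) -> TrueMap:
    """Rename each duplicate pair to the field's "/1"–"/2" twin convention
    (shared base name), in place, so downstream name-based pairing works.

    Centromere flanking loci are never pair members (pairs link arms), so
    centromere ranges stay valid.
    """
    mapping: dict[str, str] = {}
    for i, (a, b) in enumerate(tm.duplicate_pairs):
        base = f"Dup{i + 1:03d}"
        mapping[a] = f"{base}/1"
        mapping[b] = f"{base}/2"
    for g in tm.groups:
        g.markers = [mapping.get(m, m) for m in g.markers]
    tm.duplicate_pairs = [(mapping[a], mapping[b]) for a, b in tm.duplicate_pairs]
    tm.marker_location = {mapping.get(m, m): v for m, v in tm.marker_location.items()}
    return tm


def true_synthetic_map(tm: TrueMap):
    """The true map promoted to a positioned SyntheticMap (oracle layout)."""
    from .mapbuild import PositionedGroup, SyntheticMap, partition_arms
    groups = []
    for g in tm.groups:
        pg = PositionedGroup(name=g.name, loci=list(g.markers),
                             positions=[p - g.positions[0] for p in g.positions])
        partition_arms(pg, g.centromere)
        groups.append(pg)
    return SyntheticMap(groups=groups)


@dataclass
class SimulatedHomology:
    """A written BLAST-tabular fixture plus its ground truth."""

    path: str
    planted_cells: dict[tuple[str, str], int]  # (arm, chrom) -> expected marker count
    orphan_decoys: list[tuple[str, str]]  # (marker, wrong chromosome)
    tie_dropped: list[str]  # markers rule 3 must drop


def simulate_homology_table(true_map: TrueMap, path, orphan_noise: float = 0.0,
                            tie_noise: float = 0.0, seed: int = 0,
                            program: str = "blastn") -> SimulatedHomology:
    """Write a parseable BLAST-tabular fixture with planted decoys.

    Every arm-assigned marker hits its planted model location below the
    e-value cutoff.  ``orphan_noise`` and ``tie_noise`` are the expected
    (Poisson) numbers of planted decoys: orphan decoys override a marker's
    true hit with a stronger hit to a random wrong chromosome, creating a
    single-marker cell the orphan rule must remove; tie decoys add a second
    hit with identical e-value and HSP score, which rule 3 must drop.
    Decoy victims are capped so every planted (arm, chromosome) cell keeps
    at least two true markers.
    """
    rng = np.random.default_rng(seed)
    mapped = [m for m in true_map.markers if true_map.arm_of(m) is not None
              and m in true_map.marker_location]
    by_arm: dict[str, list[str]] = {}
    for m in mapped:
        by_arm.setdefault(true_map.arm_of(m), []).append(m)

    n_orphan = int(rng.poisson(orphan_noise)) if orphan_noise > 0 else 0
    n_tie = int(rng.poisson(tie_noise)) if tie_noise > 0 else 0

    budget = {arm: max(len(ms) - 2, 0) for arm, ms in by_arm.items()}
    chroms = sorted(set(true_map.arm_chromosome.values()))

    def pick_victims(k: int, taken: set[str]) -> list[str]:
        out = []
        cand = [m for m in mapped if m not in taken]
        rng.shuffle(cand)
        for m in cand:
            arm = true_map.arm_of(m)
            if budget[arm] > 0 and len(out) < k:
                out.append(m)
                budget[arm] -= 1
        return out

    taken: set[str] = set()
    orphan_victims = pick_victims(n_orphan, taken)
    taken.update(orphan_victims)
    tie_victims = pick_victims(n_tie, taken)

    orphan_decoys: list[tuple[str, str]] = []
    used_cells: set[tuple[str, str]] = set()
    for m in orphan_victims:
        arm = true_map.arm_of(m)
        own = true_map.arm_chromosome[arm]
        # exclude the sibling arm's chromosome: a decoy there would look like
        # a cross-centromere mis-assignment and be reassigned, not removed
        sibling = arm[:-1] + ("q" if arm.endswith("p") else "p")
        excl = {own, true_map.arm_chromosome.get(sibling)}
        wrong = [c for c in chroms if c not in excl and (arm, c) not in used_cells]
        if not wrong:
            budget[arm] += 1
            continue
        c = wrong[int(rng.integers(len(wrong)))]
        used_cells.add((arm, c))
        orphan_decoys.append((m, c))
    orphan_set = dict(orphan_decoys)

    rows = []
    for m in mapped:
        chrom, bp = true_map.marker_location[m]
        pident = 90.0 + 9.0 * rng.random()
        length = int(rng.integers(200, 800))
        ev = 10.0 ** -float(rng.uniform(10, 40))
        if m in orphan_set:
            # stronger decoy hit displaces the true one after filtration
            rows.append((m, orphan_set[m], round(pident, 2), length,
                         int(rng.integers(1, 5_000_000)), 1e-50))
        rows.append((m, chrom, round(pident, 2), length, bp, ev))
        if m in tie_victims:
            other = chroms[(chroms.index(chrom) + 1) % len(chroms)]
            rows.append((m, other, round(pident, 2), length,
                         int(rng.integers(1, 5_000_000)), ev))

    with open(path, "w") as fh:
        fh.write(f"# {program.upper()} 2.2.x\n# Fields: query id, subject id, % identity, "
                 "alignment length, mismatches, gap opens, q. start, q. end, s. start, "
                 "s. end, evalue, bit score\n")
        for q, s, pid, ln, sstart, ev in rows:
            send = sstart + ln - 1
            fh.write(f"{q}\t{s}\t{pid}\t{ln}\t0\t0\t1\t{ln}\t{sstart}\t{send}\t{ev:.2g}\t{ln}\n")

    planted: dict[tuple[str, str], int] = {}
    removed = set(orphan_set) | set(tie_victims)
    for arm, ms in by_arm.items():
        n_true = sum(1 for m in ms if m not in removed)
        if n_true:
            planted[(arm, true_map.arm_chromosome[arm])] = n_true
    return SimulatedHomology(path=str(path), planted_cells=planted,
                             orphan_decoys=orphan_decoys, tie_dropped=list(tie_victims))
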