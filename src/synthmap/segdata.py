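"""Data model and I/O for doubled-haploid segregation datasets and distance maps.

A doubled-haploid (DH) individual is fully homozygous, so its genotype *is*
a gamete: segregation data reduce to binary vectors per locus and
recombination fractions are directly countable.  This module holds the
containers for such data — :class:`GameteMatrix` for raw genotype tables,
:class:`DistanceMap` for published maps that only report inter-locus
distances — together with TSV readers/writers and the locus-name
bookkeeping (synonym standardisation, redundant-locus detection) needed
before maps from different laboratories can be merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # internal code for a missing call in GameteMatrix.calls

__all__ = [
    "MISSING",
    "MarkerRecord",
    "DatasetMeta",
    "GameteMatrix",
    "MapGroup",
    "DistanceMap",
    "CentromereRange",
    "read_gamete_matrix",
    "write_gamete_matrix",
    "read_distance_map",
    "write_distance_map",
    "read_synonym_table",
    "read_centromere_table",
    "standardize_locus_names",
    "apply_renames",
    "detect_redundant_loci",
    "duplicate_base_name",
]


class SegDataError(ValueError):
    """Raised on malformed segregation or distance-map input."""


@dataclass
class MarkerRecord:
    """One locus with its cross-database bookkeeping.

    ``duplicate_partner`` links the "/1"–"/2" twin produced by the salmonid
    whole-genome duplication; ``origin_suffix`` is set only when the locus
    was split into per-dataset copies after an unresolvable conflict.
    """

    name: str
    accessions: set[str] = field(default_factory=set)
    source_datasets: set[str] = field(default_factory=set)
    duplicate_partner: str | None = None
    origin_suffix: str | None = None


@dataclass(frozen=True)
class DatasetMeta:
    """Provenance and family size of one source dataset.

    ``N`` is the number of DH offspring; ``weight_size`` is the family size
    used when a dataset is deliberately down-weighted during pseudo-gamete
    reconstruction (defaults to ``N``).
    """

    dataset_id: str
    N: int
    kind: str = "raw_genotypes"  # or "distance_map"
    weight_size: int | None = None

    def __post_init__(self):
        if self.N < 2:
            raise SegDataError(f"dataset {self.dataset_id}: family size N must be >= 2, got {self.N}")
        if self.kind not in ("raw_genotypes", "distance_map"):
            raise SegDataError(f"dataset {self.dataset_id}: unknown kind {self.kind!r}")
        if self.weight_size is None:
            object.__setattr__(self, "weight_size", self.N)

    @property
    def is_rescaled(self) -> bool:
        return self.weight_size != self.N


@dataclass
class GameteMatrix:
    """Binary loci × individuals segregation data for one DH dataset.

    ``calls`` is an int8 array with values 0, 1 or :data:`MISSING`; loci are
    grouped by linkage group via the parallel ``groups`` list.
    """

    dataset: DatasetMeta
    loci: list[str]
    groups: list[str]
    calls: np.ndarray
    individuals: list[str]

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.loci), len(self.individuals)):
            raise SegDataError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.loci)} loci x {len(self.individuals)} individuals"
            )
        if len(self.groups) != len(self.loci):
            raise SegDataError("groups list must parallel loci list")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise SegDataError("calls must be 0, 1 or missing (DH data have no heterozygotes)")
        all_missing = (self.calls == MISSING).all(axis=1)
        if all_missing.any():
            names = [self.loci[i] for i in np.nonzero(all_missing)[0]]
            raise SegDataError(f"loci with no non-missing call: {names}")
        if len(set(self.loci)) != len(self.loci):
            raise SegDataError("duplicate locus names in matrix")

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g)
        return list(seen)

    def loci_of_group(self, group: str) -> list[str]:
        return [l for l, g in zip(self.loci, self.groups) if g == group]

    def row(self, locus: str) -> np.ndarray:
        return self.calls[self.loci.index(locus)]

    def subset(self, keep: list[str]) -> "GameteMatrix":
        idx = [self.loci.index(l) for l in keep]
        return GameteMatrix(
            dataset=self.dataset,
            loci=[self.loci[i] for i in idx],
            groups=[self.groups[i] for i in idx],
            calls=self.calls[idx].copy(),
            individuals=list(self.individuals),
        )

    def rename_locus(self, old: str, new: str) -> None:
        self.loci[self.loci.index(old)] = new

    def drop_loci(self, names: set[str]) -> "GameteMatrix":
        keep = [l for l in self.loci if l not in names]
        return self.subset(keep)


@dataclass
class MapGroup:
    """One linkage group of a distance-only map: ordered loci plus the
    interval value to each locus's right-hand neighbour."""

    name: str
    loci: list[str]
    intervals: list[float]

    def __post_init__(self):
        if len(self.intervals) != max(len(self.loci) - 1, 0):
            raise SegDataError(
                f"group {self.name}: {len(self.loci)} loci need "
                f"{max(len(self.loci) - 1, 0)} intervals, got {len(self.intervals)}"
            )


@dataclass
class DistanceMap:
    """Ordered loci per linkage group with adjacent-interval distances.

    ``distance_kind`` is ``"kosambi_cM"`` (Kosambi centimorgans, >= 0) or
    ``"recomb_fraction"`` (r in [0, 0.5]).
    """

    dataset: DatasetMeta
    groups: list[MapGroup]
    distance_kind: str

    def __post_init__(self):
        if self.distance_kind not in ("kosambi_cM", "recomb_fraction"):
            raise SegDataError(f"unknown distance_kind {self.distance_kind!r}")
        for g in self.groups:
            for v in g.intervals:
                if v < 0:
                    raise SegDataError(f"group {g.name}: negative distance {v}")
                if self.distance_kind == "recomb_fraction" and v > 0.5:
                    raise SegDataError(f"group {g.name}: recombination fraction {v} > 0.5")

    @property
    def group_names(self) -> list[str]:
        return [g.name for g in self.groups]

    def group(self, name: str) -> MapGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)


@dataclass
class CentromereRange:
    """Approximate centromere border for one linkage group, given as the two
    flanking loci; acrocentric groups carry a terminal range."""

    group: str
    start_locus: str
    end_locus: str
    acrocentric: bool = False


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_gamete_matrix(path, meta: DatasetMeta, missing: set[str] = frozenset({"-"})) -> GameteMatrix:
    """Read a segregation TSV: header row names individuals, first two
    columns are linkage group and locus name, remaining cells are calls.

    Calls must be "0", "1" or a member of *missing*; anything else is an
    error naming the locus and column.  Duplicate locus names are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise SegDataError(f"{path}: need linkage_group, locus and >=1 individual column")
    individuals = list(df.columns[2:])
    groups = df.iloc[:, 0].tolist()
    loci = df.iloc[:, 1].tolist()
    seen: set[str] = set()
    for l in loci:
        if l in seen:
            raise SegDataError(f"{path}: duplicate locus name {l!r}")
        seen.add(l)
    calls = np.full((len(loci), len(individuals)), MISSING, dtype=np.int8)
    for i, locus in enumerate(loci):
        for j, ind in enumerate(individuals):
            v = df.iat[i, j + 2].strip()
            if v == "0":
                calls[i, j] = 0
            elif v == "1":
                calls[i, j] = 1
            elif v in missing or v == "":
                if v == "":
                    logger.warning("%s: empty call at locus %s, column %s treated as missing", path, locus, ind)
                calls[i, j] = MISSING
            else:
                raise SegDataError(f"{path}: unparseable call {v!r} at locus {locus!r}, column {ind!r}")
    return GameteMatrix(dataset=meta, loci=loci, groups=groups, calls=calls, individuals=individuals)


def write_gamete_matrix(m: GameteMatrix, path, missing_symbol: str = "-") -> None:
    cols = {"linkage_group": m.groups, "locus": m.loci}
    sym = np.array(["0", "1"], dtype=object)
    for j, ind in enumerate(m.individuals):
        col = m.calls[:, j]
        cols[ind] = [missing_symbol if c == MISSING else sym[c] for c in col]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_distance_map(path, meta: DatasetMeta, distance_kind: str) -> DistanceMap:
    """Read a distance-map TSV with columns ``linkage_group``, ``locus``,
    ``interval_to_next`` (empty for the last locus of each group)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    groups: list[MapGroup] = []
    for name, sub in df.groupby(df.columns[0], sort=False):
        loci = sub.iloc[:, 1].tolist()
        raw = sub.iloc[:, 2].tolist()
        intervals = []
        for v in raw[:-1]:
            v = v.strip()
            if v == "":
                raise SegDataError(f"{path}: missing interval in group {name}")
            intervals.append(float(v))
        if raw and raw[-1].strip() not in ("", "NA", "."):
            raise SegDataError(f"{path}: group {name}: last locus must not carry an interval")
        groups.append(MapGroup(name=str(name), loci=loci, intervals=intervals))
    return DistanceMap(dataset=meta, groups=groups, distance_kind=distance_kind)


def write_distance_map(dmap: DistanceMap, path) -> None:
    rows = []
    for g in dmap.groups:
        for i, locus in enumerate(g.loci):
            iv = f"{g.intervals[i]:g}" if i < len(g.intervals) else ""
            rows.append((g.name, locus, iv))
    pd.DataFrame(rows, columns=["linkage_group", "locus", "interval_to_next"]).to_csv(
        path, sep="\t", index=False
    )


def read_synonym_table(path) -> dict[str, str]:
    """Read an (alias, canonical) TSV into a dict; a duplicate alias mapping
    to two different canonical names is an error."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table: dict[str, str] = {}
    for alias, canonical in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if alias in table and table[alias] != canonical:
            raise SegDataError(f"alias {alias!r} maps to both {table[alias]!r} and {canonical!r}")
        table[alias] = canonical
    return table


def read_centromere_table(path) -> list[CentromereRange]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        acro = str(row.get("acrocentric", "0")).strip().lower() in ("1", "true", "yes")
        out.append(CentromereRange(row["group"], row["start_locus"], row["end_locus"], acro))
    return out


# ---------------------------------------------------------------------------
# Locus-name bookkeeping
# ---------------------------------------------------------------------------

def standardize_locus_names(names, synonyms: dict[str, str]):
    """Replace aliased locus names by their canonical form.

    Returns ``(new_names, log)`` where *log* is a list of ``(old, new, rule)``
    tuples ("synonym" is the only rule emitted here).  Names absent from the
    table pass through unchanged and unlogged, which makes the operation
    idempotent.  A table whose canonical names are themselves aliases
    (chains or cycles) is rejected.
    """
    for alias, canonical in synonyms.items():
        if canonical in synonyms and synonyms[canonical] != canonical:
            raise SegDataError(
                f"synonym chain/cycle: {alias!r} -> {canonical!r} -> {synonyms[canonical]!r}"
            )
    out, log = [], []
    for name in names:
        target = synonyms.get(name, name)
        if target != name:
            log.append((name, target, "synonym"))
        out.append(target)
    return out, log


def apply_renames(m: GameteMatrix | DistanceMap, synonyms: dict[str, str]):
    """Standardise every locus name in a dataset in place; returns the log."""
    if isinstance(m, GameteMatrix):
        m.loci, log = standardize_locus_names(m.loci, synonyms)
    else:
        log = []
        for g in m.groups:
            g.loci, sub = standardize_locus_names(g.loci, synonyms)
            log.extend(sub)
    return log


def duplicate_base_name(name: str) -> str | None:
    """Base name of a "/1"–"/2" duplicated-locus twin, else None."""
    if name.endswith("/1") or name.endswith("/2"):
        return name[:-2]
    return None


def detect_redundant_loci(records: list[MarkerRecord], within: str) -> list[tuple[str, str]]:
    """Pairs of distinct locus names used in the same dataset that share an
    accession — i.e. one physical locus mapped under two names.

    "/1"–"/2" duplicate twins legitimately share accessions (they are the
    two copies retained after genome duplication) and are never reported.
    Output pairs are sorted and unique (symmetric, irreflexive).
    """
    in_ds = [r for r in records if within in r.source_datasets]
    pairs: set[tuple[str, str]] = set()
    for i, a in enumerate(in_ds):
        for b in in_ds[i + 1:]:
            if a.name == b.name or not (a.accessions & b.accessions):
                continue
            ba, bb = duplicate_base_name(a.name), duplicate_base_name(b.name)
            if ba is not None and ba == bb:
                continue
            if a.duplicate_partner == b.name or b.duplicate_partner == a.name:
                continue
            pairs.add(tuple(sorted((a.name, b.name))))
    return sorted(pairs)
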