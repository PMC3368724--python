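"""Merging, two-point estimation, marker ordering and map emission.

Because interference is close to one in salmonids, the recombination
percentage itself is used as the mapping function: positions on the
synthetic map are cumulative sums of adjacent two-point recombination
fractions (x100, in cM).  Marker ordering therefore minimises the expected
map length, the sum of adjacent r-hat — a path-TSP objective.  An exact
Held–Karp dynamic program is provided for small groups and three
seed-deterministic heuristics (simulated annealing, taboo search, and
exhaustive sliding-window "flips") for larger ones.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .segdata import CentromereRange, DatasetMeta, GameteMatrix, MISSING

__all__ = [
    "MergedMatrix",
    "TwoPointEstimate",
    "PositionedGroup",
    "SyntheticMap",
    "merge_matrices",
    "two_point_tables",
    "estimate_two_point",
    "order_markers",
    "order_objective",
    "compute_positions",
    "partition_arms",
    "build_group",
    "build_synthetic_map",
    "write_map_tsv",
    "write_mapchart",
    "NO_INFO_COST",
]

# cost assigned to a zero-information adjacency so heuristics avoid it;
# large relative to any sum of r-hat values but finite so ordering still
# succeeds (the junction is flagged downstream)
NO_INFO_COST = 1.0e3


@dataclass
class MergedMatrix:
    """Union-of-loci, concatenation-of-individuals matrix for one linkage
    group; ``blocks`` maps each source dataset to its column range."""

    group: str
    loci: list[str]
    calls: np.ndarray
    individuals: list[str]
    blocks: dict[str, tuple[int, int]]


@dataclass
class TwoPointEstimate:
    pair: tuple[str, str]
    rhat: float
    n_informative: int
    phase: str | None  # "coupling" | "repulsion" | None when uninformative


@dataclass
class PositionedGroup:
    """One ordered, positioned linkage group of the synthetic map."""

    name: str
    loci: list[str]
    positions: list[float]  # cM, first locus at 0, non-decreasing
    arm_labels: list[str] = field(default_factory=list)  # "p" | "q" | "centromeric"
    centromere: CentromereRange | None = None
    flagged_junctions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def length(self) -> float:
        return self.positions[-1] if self.positions else 0.0

    def arm_of(self, locus: str) -> str | None:
        """Arm name like 'RT01p', or None if centromeric/unlabelled."""
        if not self.arm_labels:
            return None
        lab = self.arm_labels[self.loci.index(locus)]
        if lab in ("p", "q"):
            return f"{self.name}{lab}"
        return None


@dataclass
class SyntheticMap:
    groups: list[PositionedGroup]

    def group(self, name: str) -> PositionedGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    @property
    def n_loci(self) -> int:
        return sum(len(g.loci) for g in self.groups)

    @property
    def total_length(self) -> float:
        return sum(g.length for g in self.groups)

    def locate(self, locus: str):
        """(group name, position cM, arm or None) of a locus; KeyError if absent."""
        for g in self.groups:
            if locus in g.loci:
                i = g.loci.index(locus)
                return g.name, g.positions[i], g.arm_of(locus)
        raise KeyError(locus)

    @property
    def loci(self) -> list[str]:
        return [l for g in self.groups for l in g.loci]


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_matrices(datasets: list[GameteMatrix], group: str) -> MergedMatrix:
    """Merge several screened datasets on one linkage group.

    Loci are unioned (order of first appearance); individuals are
    concatenated, namespaced by dataset id; a locus untyped in a dataset is
    missing across that dataset's column block.
    """
    loci: list[str] = []
    for m in datasets:
        for l in m.loci_of_group(group):
            if l not in loci:
                loci.append(l)
    individuals: list[str] = []
    blocks: dict[str, tuple[int, int]] = {}
    col = 0
    for m in datasets:
        if m.dataset.dataset_id in blocks:
            raise ValueError(f"dataset id {m.dataset.dataset_id!r} appears twice in merge")
        names = [f"{m.dataset.dataset_id}:{ind}" for ind in m.individuals]
        if set(names) & set(individuals):
            raise ValueError("individual ID collision after namespacing")
        blocks[m.dataset.dataset_id] = (col, col + len(names))
        individuals.extend(names)
        col += len(names)
    calls = np.full((len(loci), len(individuals)), MISSING, dtype=np.int8)
    for m in datasets:
        lo, hi = blocks[m.dataset.dataset_id]
        for l in m.loci_of_group(group):
            calls[loci.index(l), lo:hi] = m.row(l)
    return MergedMatrix(group=group, loci=loci, calls=calls, individuals=individuals, blocks=blocks)


# ---------------------------------------------------------------------------
# Two-point estimation
# ---------------------------------------------------------------------------

def two_point_tables(calls: np.ndarray):
    """All-pairs two-point tables for a loci x individuals call matrix.

    Returns ``(rhat, ninf, disc)``: the recombination-fraction matrix
    (min(discordant, concordant)/n over columns where both loci are typed;
    0.5 where no column is shared), the informative-meiosis counts, and the
    raw discordance counts.  Vectorised; used by ordering and screening.
    """
    a1 = (calls == 1).astype(np.float64)
    a0 = (calls == 0).astype(np.float64)
    disc = a1 @ a0.T + a0 @ a1.T
    conc = a1 @ a1.T + a0 @ a0.T
    ninf = disc + conc
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.minimum(disc, conc) / ninf
    rhat[ninf == 0] = 0.5
    return rhat, ninf.astype(np.int64), disc.astype(np.int64)


def estimate_two_point(m: MergedMatrix, a: str, b: str) -> TwoPointEstimate:
    """Two-point estimate between two loci of a merged matrix.

    Over the columns where both loci are non-missing, r-hat is
    min(discordant, concordant)/n; the phase is coupling when discordant
    calls are the minority and repulsion otherwise.  With no shared
    informative meiosis r-hat defaults to 0.5 with weight 0.
    """
    if a == b:
        raise ValueError("two-point estimate needs two distinct loci")
    ra, rb = m.calls[m.loci.index(a)], m.calls[m.loci.index(b)]
    both = (ra != MISSING) & (rb != MISSING)
    n = int(both.sum())
    if n == 0:
        return TwoPointEstimate(pair=(a, b), rhat=0.5, n_informative=0, phase=None)
    d = int((ra[both] != rb[both]).sum())
    c = n - d
    if d <= c:
        return TwoPointEstimate(pair=(a, b), rhat=d / n, n_informative=n, phase="coupling")
    return TwoPointEstimate(pair=(a, b), rhat=c / n, n_informative=n, phase="repulsion")


# ---------------------------------------------------------------------------
# Ordering
# ---------------------------------------------------------------------------

def order_objective(order: np.ndarray, cost: np.ndarray) -> float:
    """Expected map length of an order: sum of adjacent pair costs."""
    return float(cost[order[:-1], order[1:]].sum())


def _cost_matrix(rhat: np.ndarray, ninf: np.ndarray, weighted: bool = False) -> np.ndarray:
    cost = rhat.copy()
    if weighted:
        w = ninf / max(ninf.max(), 1)
        cost = rhat * (2.0 - w)  # favour well-supported adjacencies on ties
    cost[ninf == 0] = NO_INFO_COST
    np.fill_diagonal(cost, 0.0)
    return cost


def _greedy_path(cost: np.ndarray) -> np.ndarray:
    """Nearest-neighbour path grown from the cheapest edge at both ends."""
    n = cost.shape[0]
    if n == 1:
        return np.array([0])
    c = cost + np.diag(np.full(n, np.inf))
    i, j = np.unravel_index(np.argmin(c), c.shape)
    path = [int(i), int(j)]
    used = set(path)
    while len(path) < n:
        rest = [k for k in range(n) if k not in used]
        head, tail = path[0], path[-1]
        bh = min(rest, key=lambda k: (cost[head, k], k))
        bt = min(rest, key=lambda k: (cost[tail, k], k))
        if cost[head, bh] < cost[tail, bt]:
            path.insert(0, bh)
            used.add(bh)
        else:
            path.append(bt)
            used.add(bt)
    return np.array(path)


def _exact_order(cost: np.ndarray) -> np.ndarray:
    """Held–Karp dynamic program over subsets: optimal open path."""
    n = cost.shape[0]
    if n == 1:
        return np.array([0])
    full = 1 << n
    dp = np.full((full, n), np.inf)
    parent = np.full((full, n), -1, dtype=np.int32)
    for i in range(n):
        dp[1 << i, i] = 0.0
    for mask in range(full):
        row = dp[mask]
        for last in range(n):
            base = row[last]
            if not np.isfinite(base):
                continue
            for nxt in range(n):
                if mask & (1 << nxt):
                    continue
                nm = mask | (1 << nxt)
                val = base + cost[last, nxt]
                if val < dp[nm, nxt]:
                    dp[nm, nxt] = val
                    parent[nm, nxt] = last
    endmask = full - 1
    last = int(np.argmin(dp[endmask]))
    order = [last]
    mask = endmask
    while parent[mask, last] >= 0:
        prev = int(parent[mask, last])
        mask ^= 1 << last
        order.append(prev)
        last = prev
    order.reverse()
    return np.array(order)


def _reversal_delta(c: list[list[float]], o: list[int], a: int, b: int) -> float:
    """Objective change of reversing o[a..b]; O(1) because cost is symmetric."""
    n = len(o)
    if a == 0 and b == n - 1:
        return 0.0
    d = 0.0
    if a > 0:
        d += c[o[a - 1]][o[b]] - c[o[a - 1]][o[a]]
    if b < n - 1:
        d += c[o[a]][o[b + 1]] - c[o[b]][o[b + 1]]
    return d


def _anneal(cost: np.ndarray, seed: int, t0: float = 1.0, cooling: float = 0.95,
            moves_per_temp: int = 300, t_min: float = 1e-3) -> np.ndarray:
    """Simulated annealing with incremental (delta) objective evaluation.

    Moves: adjacent transposition, segment reversal, single-locus
    reinsertion; geometric cooling; Metropolis acceptance.
    """
    rng = np.random.default_rng(seed)
    c = cost.tolist()
    order = list(map(int, _greedy_path(cost)))
    n = len(order)
    cur_obj = sum(c[order[k]][order[k + 1]] for k in range(n - 1))
    best, best_obj = order[:], cur_obj
    t = t0
    while t > t_min:
        kinds = rng.integers(3, size=moves_per_temp)
        ii = rng.integers(n, size=moves_per_temp)
        jj = rng.integers(n, size=moves_per_temp)
        us = rng.random(moves_per_temp)
        for kind, i, j, u in zip(kinds, ii, jj, us):
            if kind == 0:  # adjacent transposition = reversal of length 2
                a = int(i) % (n - 1)
                b = a + 1
                d = _reversal_delta(c, order, a, b)
                if d <= 0 or u < math.exp(-d / t):
                    order[a], order[b] = order[b], order[a]
                    cur_obj += d
            elif kind == 1:  # segment reversal
                a, b = int(i), int(j)
                if a > b:
                    a, b = b, a
                if a == b:
                    continue
                d = _reversal_delta(c, order, a, b)
                if d <= 0 or u < math.exp(-d / t):
                    order[a:b + 1] = order[a:b + 1][::-1]
                    cur_obj += d
            else:  # single-locus reinsertion
                src = int(i)
                dst = int(j) % (n - 1)
                v = order[src]
                d = 0.0
                if src > 0:
                    d -= c[order[src - 1]][v]
                if src < n - 1:
                    d -= c[v][order[src + 1]]
                if 0 < src < n - 1:
                    d += c[order[src - 1]][order[src + 1]]
                order.pop(src)
                if dst > 0:
                    d += c[order[dst - 1]][v]
                if dst < n - 1:
                    d += c[v][order[dst]]
                if 0 < dst < n - 1:
                    d -= c[order[dst - 1]][order[dst]]
                if d <= 0 or u < math.exp(-d / t):
                    order.insert(dst, v)
                    cur_obj += d
                else:
                    order.insert(src, v)
            if cur_obj < best_obj - 1e-12:
                best, best_obj = order[:], cur_obj
        t *= cooling
    return np.array(best)


def _flips(cost: np.ndarray, window: int = 5) -> np.ndarray:
    """Exhaustive sliding-window permutation descent until no window of
    *window* consecutive loci can be improved by any permutation."""
    order = _greedy_path(cost)
    n = len(order)
    w = min(window, n)
    improved = True
    while improved:
        improved = False
        for start in range(0, n - w + 1):
            seg = order[start:start + w]
            base = order.copy()
            best_obj = order_objective(order, cost)
            best_perm = None
            for perm in itertools.permutations(seg):
                base[start:start + w] = perm
                obj = order_objective(base, cost)
                if obj < best_obj - 1e-12:
                    best_obj = obj
                    best_perm = perm
            if best_perm is not None:
                order[start:start + w] = best_perm
                improved = True
    return order


def _taboo(cost: np.ndarray, seed: int, tenure: int = 15, iterations: int | None = None) -> np.ndarray:
    """Taboo search over segment reversals; recently reversed segments are
    taboo for *tenure* iterations unless they beat the incumbent best."""
    n = cost.shape[0]
    if iterations is None:
        iterations = max(20 * n, 100)
    c = cost.tolist()
    cur = list(map(int, _greedy_path(cost)))
    cur_obj = sum(c[cur[k]][cur[k + 1]] for k in range(n - 1))
    best, best_obj = cur[:], cur_obj
    taboo_until: dict[tuple[int, int], int] = {}
    for it in range(iterations):
        best_key = None
        best_delta = np.inf
        for i in range(n - 1):
            for j in range(i + 1, n):
                d = _reversal_delta(c, cur, i, j)
                tabooed = taboo_until.get((i, j), -1) >= it
                if tabooed and cur_obj + d >= best_obj:  # aspiration: allow new global best
                    continue
                if d < best_delta:
                    best_delta = d
                    best_key = (i, j)
        if best_key is None:
            break
        i, j = best_key
        cur[i:j + 1] = cur[i:j + 1][::-1]
        cur_obj += best_delta
        taboo_until[best_key] = it + tenure
        if cur_obj < best_obj - 1e-12:
            best, best_obj = cur[:], cur_obj
    return np.array(best)


def _canonicalize(order: np.ndarray, loci: list[str]) -> np.ndarray:
    if len(order) > 1 and loci[order[0]] > loci[order[-1]]:
        return order[::-1].copy()
    return order


def order_markers(m: MergedMatrix, method: str = "annealing", params: dict | None = None,
                  seed: int = 0) -> list[str]:
    """Order the loci of a merged linkage group by minimising expected map
    length (sum of adjacent two-point r-hat).

    ``method`` is one of ``exact`` (Held–Karp, guaranteed optimal, <= 15
    loci), ``annealing``, ``taboo`` or ``flips``.  Heuristics are
    deterministic given *seed* and never worsen their greedy start.  The
    returned order is canonicalised so that the first locus name sorts
    before the last.  Loci not linked directly or transitively (no shared
    informative meioses) raise an error listing the components.
    """
    params = dict(params or {})
    rhat, ninf, _ = two_point_tables(m.calls)
    g = nx.Graph()
    g.add_nodes_from(range(len(m.loci)))
    ii, jj = np.nonzero(ninf > 0)
    g.add_edges_from((int(i), int(j)) for i, j in zip(ii, jj) if i < j)
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        named = [sorted(m.loci[i] for i in c) for c in comps]
        raise ValueError(f"group {m.group}: loci not transitively linked; components: {named}")
    weighted = params.pop("weighted", False)
    cost = _cost_matrix(rhat, ninf, weighted=weighted)
    n = len(m.loci)
    if n <= 2:
        order = np.arange(n)
    elif method == "exact":
        if n > 15:
            raise ValueError(f"exact ordering limited to 15 loci, got {n} (use a heuristic)")
        order = _exact_order(cost)
    elif method == "annealing":
        order = _anneal(cost, seed, **params)
    elif method == "flips":
        order = _flips(cost, **params)
    elif method == "taboo":
        order = _taboo(cost, seed, **params)
    else:
        raise ValueError(f"unknown ordering method {method!r}")
    order = _canonicalize(order, m.loci)
    return [m.loci[i] for i in order]


# ---------------------------------------------------------------------------
# Positions and arms
# ---------------------------------------------------------------------------

def compute_positions(order: list[str], m: MergedMatrix) -> PositionedGroup:
    """Cumulative cM positions along an ordered group.

    position(locus 1) = 0 and each interval adds 100 x r-hat of the
    adjacent pair; zero-information junctions contribute the uninformative
    default r-hat = 0.5 and are flagged.
    """
    positions = [0.0]
    flagged = []
    for a, b in zip(order[:-1], order[1:]):
        est = estimate_two_point(m, a, b)
        if est.n_informative == 0:
            flagged.append((a, b))
        positions.append(positions[-1] + 100.0 * est.rhat)
    return PositionedGroup(name=m.group, loci=list(order), positions=positions,
                           flagged_junctions=flagged)


def partition_arms(group: PositionedGroup, centromere: CentromereRange) -> PositionedGroup:
    """Label each locus p-side / q-side / centromeric from a centromere
    range given as two flanking loci (inclusive).  Acrocentric groups get a
    terminal centromeric range and a single q arm."""
    loci = group.loci
    for l in (centromere.start_locus, centromere.end_locus):
        if l not in loci:
            raise ValueError(f"centromere locus {l!r} absent from group {group.name}")
    i0 = loci.index(centromere.start_locus)
    i1 = loci.index(centromere.end_locus)
    if i0 > i1:
        i0, i1 = i1, i0
    labels = []
    for i in range(len(loci)):
        if i0 <= i <= i1:
            labels.append("centromeric")
        elif centromere.acrocentric:
            labels.append("q")  # acrocentric: the single arm is q by convention
        else:
            labels.append("p" if i < i0 else "q")
    group.arm_labels = labels
    group.centromere = centromere
    return group


# ---------------------------------------------------------------------------
# Assembly and export
# ---------------------------------------------------------------------------

def build_group(datasets: list[GameteMatrix], group: str, method: str = "annealing",
                seed: int = 0, params: dict | None = None,
                centromere: CentromereRange | None = None) -> PositionedGroup:
    merged = merge_matrices(datasets, group)
    order = order_markers(merged, method=method, params=params, seed=seed)
    pg = compute_positions(order, merged)
    if centromere is not None:
        pg = partition_arms(pg, centromere)
    return pg


def build_synthetic_map(datasets: list[GameteMatrix], method: str = "annealing", seed: int = 0,
                        params: dict | None = None,
                        centromeres: list[CentromereRange] | None = None) -> SyntheticMap:
    """Order and position every linkage group present in the datasets."""
    cent = {c.group: c for c in (centromeres or [])}
    names: list[str] = []
    for m in datasets:
        for g in m.group_names:
            if g not in names:
                names.append(g)
    groups = [
        build_group(datasets, g, method=method, seed=seed + i, params=params,
                    centromere=cent.get(g))
        for i, g in enumerate(names)
    ]
    return SyntheticMap(groups=groups)


def write_map_tsv(smap: SyntheticMap, path) -> None:
    import pandas as pd
    rows = []
    for g in smap.groups:
        labels = g.arm_labels or [""] * len(g.loci)
        for locus, pos, arm in zip(g.loci, g.positions, labels):
            rows.append((g.name, locus, round(pos, 4), arm))
    pd.DataFrame(rows, columns=["group", "locus", "position_cM", "arm"]).to_csv(
        path, sep="\t", index=False
    )


def write_mapchart(smap: SyntheticMap, path) -> None:
    """MapChart-format text export: a 'group' header per linkage group then
    one 'locus position' line per marker."""
    with open(path, "w") as fh:
        for g in smap.groups:
            fh.write(f"group {g.name}\n")
            for locus, pos in zip(g.loci, g.positions):
                fh.write(f"{locus} {pos:.2f}\n")
            fh.write("\n")
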