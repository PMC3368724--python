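"""Cross-dataset consistency screening before map merging.

Independent mapping panels disagree: a marker may sit on different linkage
groups in different datasets, or the shared markers of one group may come
in conflicting orders.  This module detects both kinds of discrepancy and
applies the resolution rules used to build the synthetic map:

* a single deviant dataset against two or more concordant ones loses the
  marker;
* a conflict between exactly two datasets is ignored when one or two
  genotype-call changes would reconcile the orders (the conflict is then
  attributed to genotyping error), and otherwise the marker is split into
  per-dataset copies distinguished by a source suffix;
* group-assignment conflicts are always suffix-split, and linkage groups a
  source itself flags as merged/ambiguous are dropped from that source.

Order discrepancy is operationalised as exclusion from the orientation-free
longest common subsequence (LCS) of the shared-locus orders — a whole-group
reversal is not a conflict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np

from .segdata import DistanceMap, GameteMatrix, MISSING
from .mapbuild import two_point_tables

__all__ = [
    "DiscrepancyReport",
    "check_group_consistency",
    "check_order_consistency",
    "resolve_discrepancies",
    "orientation_free_lcs",
    "min_flip_reconciliation",
    "write_audit_log",
]

Dataset = GameteMatrix | DistanceMap


@dataclass
class DiscrepancyReport:
    locus: str
    datasets: tuple[str, ...]
    kind: str  # "group_conflict" | "order_conflict"
    resolution: str | None = None  # removed_from_deviant | ignored_small | suffix_split | dropped_group
    evidence: int = 0  # supporting datasets, or inconsistent-genotype count


def _group_names(ds: Dataset) -> list[str]:
    return ds.group_names if isinstance(ds, GameteMatrix) else [g.name for g in ds.groups]


def _loci_of_group(ds: Dataset, group: str) -> list[str]:
    if isinstance(ds, GameteMatrix):
        return ds.loci_of_group(group)
    return list(ds.group(group).loci)


def _locus_groups(ds: Dataset) -> dict[str, str]:
    out = {}
    for g in _group_names(ds):
        for l in _loci_of_group(ds, g):
            out[l] = g
    return out


# ---------------------------------------------------------------------------
# Group-assignment consistency
# ---------------------------------------------------------------------------

def check_group_consistency(datasets: list[Dataset],
                            merged_groups: dict[str, set[str]] | None = None) -> list[DiscrepancyReport]:
    """Report every locus assigned to different linkage groups in different
    datasets, and every locus sitting in a source-flagged merged/ambiguous
    group (``merged_groups`` maps dataset id -> group names to drop)."""
    merged_groups = merged_groups or {}
    reports: list[DiscrepancyReport] = []
    assignments: dict[str, dict[str, str]] = {}
    for ds in datasets:
        ds_id = ds.dataset.dataset_id
        for locus, group in _locus_groups(ds).items():
            assignments.setdefault(locus, {})[ds_id] = group
        for group in merged_groups.get(ds_id, set()):
            for locus in _loci_of_group(ds, group) if group in _group_names(ds) else []:
                reports.append(DiscrepancyReport(
                    locus=locus, datasets=(ds_id,), kind="group_conflict",
                    resolution="dropped_group", evidence=1,
                ))
    for locus in sorted(assignments):
        by_ds = assignments[locus]
        if len(by_ds) < 2 or len(set(by_ds.values())) < 2:
            continue
        reports.append(DiscrepancyReport(
            locus=locus, datasets=tuple(sorted(by_ds)), kind="group_conflict",
            evidence=len(by_ds),
        ))
    return reports


# ---------------------------------------------------------------------------
# Order consistency
# ---------------------------------------------------------------------------

def _all_max_lcs(a: tuple[str, ...], b: tuple[str, ...], cap: int = 2000) -> list[tuple[str, ...]]:
    """All maximum-length common subsequences of two sequences (capped)."""
    na, nb = len(a), len(b)
    L = np.zeros((na + 1, nb + 1), dtype=int)
    for i in range(na - 1, -1, -1):
        for j in range(nb - 1, -1, -1):
            L[i, j] = 1 + L[i + 1, j + 1] if a[i] == b[j] else max(L[i + 1, j], L[i, j + 1])

    @lru_cache(maxsize=None)
    def collect(i: int, j: int) -> frozenset:
        if L[i, j] == 0:
            return frozenset({()})
        out: set[tuple[str, ...]] = set()
        if i < na and j < nb and a[i] == b[j] and L[i, j] == 1 + L[i + 1, j + 1]:
            out.update((a[i],) + t for t in collect(i + 1, j + 1))
        if i < na and L[i + 1, j] == L[i, j]:
            out.update(collect(i + 1, j))
        if j < nb and L[i, j + 1] == L[i, j]:
            out.update(collect(i, j + 1))
        if len(out) > cap:
            out = set(sorted(out)[:cap])
        return frozenset(out)

    res = sorted(collect(0, 0))
    collect.cache_clear()
    return res


def orientation_free_lcs(a: list[str], b: list[str]) -> tuple[list[str], set[str]]:
    """Longest common subsequence of two locus orders, allowing whole-group
    reversal of the second; returns (chosen LCS, deviant loci outside it).

    When several maximum LCSs exist the deviant set is chosen to minimise
    total displaced rank distance between the two orders, then
    lexicographically.
    """
    ta, tb = tuple(a), tuple(b)
    cands = _all_max_lcs(ta, tb) + _all_max_lcs(ta, tuple(reversed(tb)))
    best_len = max(len(c) for c in cands)
    cands = [c for c in cands if len(c) == best_len]
    rank_a = {l: i for i, l in enumerate(a)}
    rank_b = {l: i for i, l in enumerate(b)}

    def key(lcs):
        deviants = sorted(set(a) - set(lcs))
        disp = sum(abs(rank_a[l] - rank_b[l]) for l in deviants)
        return (disp, tuple(deviants))

    chosen = min(cands, key=key)
    return list(chosen), set(a) - set(chosen)


def check_order_consistency(datasets: list[Dataset], group: str) -> list[DiscrepancyReport]:
    """Pairwise orientation-free LCS screening of shared-locus orders on one
    linkage group; each locus outside an LCS is reported with the number of
    dataset pairs in which it is deviant as evidence."""
    orders = {}
    for ds in datasets:
        if group in _group_names(ds):
            orders[ds.dataset.dataset_id] = _loci_of_group(ds, group)
    reports: dict[str, DiscrepancyReport] = {}
    for (id1, o1), (id2, o2) in combinations(orders.items(), 2):
        shared = [l for l in o1 if l in set(o2)]
        if len(shared) < 3:
            continue
        s1 = shared
        s2 = [l for l in o2 if l in set(shared)]
        _, deviants = orientation_free_lcs(s1, s2)
        for locus in deviants:
            if locus in reports:
                r = reports[locus]
                reports[locus] = DiscrepancyReport(
                    locus=locus,
                    datasets=tuple(sorted(set(r.datasets) | {id1, id2})),
                    kind="order_conflict",
                    evidence=r.evidence + 1,
                )
            else:
                reports[locus] = DiscrepancyReport(
                    locus=locus, datasets=(id1, id2), kind="order_conflict", evidence=1,
                )
    return [reports[l] for l in sorted(reports)]


# ---------------------------------------------------------------------------
# Minimum-flip reconciliation (two-dataset conflicts)
# ---------------------------------------------------------------------------

def _pair_objective(calls: np.ndarray, order: list[int]) -> float:
    rhat, ninf, _ = two_point_tables(calls)
    o = np.array(order)
    seg = rhat[o[:-1], o[1:]]
    return float(seg.sum())


def min_flip_reconciliation(ds_a: Dataset, ds_b: Dataset, group: str, locus: str,
                            max_flips: int = 3) -> int | None:
    """Minimum number of genotype-call flips at *locus*, in either raw
    dataset, after which that dataset's own two-point data support the other
    dataset's shared-locus order at least as well as its own.

    Only raw-genotype datasets can be flipped; pseudo-gamete or
    distance-only data return None (not computable).  Flips are counted,
    never applied to the stored data.
    """
    raw = [d for d in (ds_a, ds_b) if isinstance(d, GameteMatrix) and d.dataset.kind == "raw_genotypes"]
    if not raw:
        return None
    oa = _loci_of_group(ds_a, group)
    ob = _loci_of_group(ds_b, group)
    shared = [l for l in oa if l in set(ob)]
    for f in range(0, max_flips + 1):
        for ds, other_order_src in ((ds_a, ob), (ds_b, oa)):
            if not (isinstance(ds, GameteMatrix) and ds.dataset.kind == "raw_genotypes"):
                continue
            own = [l for l in _loci_of_group(ds, group) if l in set(shared)]
            other = [l for l in other_order_src if l in set(shared)]
            idx = {l: ds.loci.index(l) for l in shared}
            sub = ds.calls[[idx[l] for l in shared]].copy()
            pos = {l: i for i, l in enumerate(shared)}
            own_o = [pos[l] for l in own]
            oth_o = [pos[l] for l in other]
            li = pos[locus]
            cols = np.nonzero(sub[li] != MISSING)[0]
            for combo in combinations(cols, f):
                trial = sub.copy()
                for c in combo:
                    trial[li, c] = 1 - trial[li, c]
                own_obj = _pair_objective(trial, own_o)
                oth_obj = min(_pair_objective(trial, oth_o),
                              _pair_objective(trial, oth_o[::-1]))
                if oth_obj <= own_obj + 1e-12:
                    return f
    return None


# ---------------------------------------------------------------------------
# Resolution
# ---------------------------------------------------------------------------

def _single_deviant_dataset(by_id: dict[str, Dataset], present_in: list[str],
                            locus: str) -> str | None:
    """The one dataset whose order of *locus* conflicts with >= 2 concordant
    others, or None if deviance is not of the one-vs-many shape."""
    deviance: dict[str, int] = {i: 0 for i in present_in}
    for i1, i2 in combinations(present_in, 2):
        d1, d2 = by_id[i1], by_id[i2]
        g1 = _locus_groups(d1).get(locus)
        if g1 is None or g1 != _locus_groups(d2).get(locus):
            continue
        o1 = _loci_of_group(d1, g1)
        o2 = _loci_of_group(d2, g1)
        shared = [l for l in o1 if l in set(o2)]
        if locus not in shared or len(shared) < 3:
            continue
        s2 = [l for l in o2 if l in set(shared)]
        _, deviants = orientation_free_lcs(shared, s2)
        if locus in deviants:
            deviance[i1] += 1
            deviance[i2] += 1
    ranked = sorted(deviance.items(), key=lambda kv: (-kv[1], kv[0]))
    if ranked and ranked[0][1] >= 2 and (len(ranked) < 2 or ranked[1][1] <= 1):
        return ranked[0][0]
    return None


def _split_suffix(locus: str, ds_id: str) -> str:
    return f"{locus}_{ds_id}"


def resolve_discrepancies(reports: list[DiscrepancyReport], datasets: list[Dataset],
                          flip_threshold: int = 2):
    """Apply the resolution rules and return (cleaned datasets, audit log).

    The audit log is the list of input reports with ``resolution`` filled
    in; cleaned datasets are copies with loci removed, renamed
    (suffix-split) or groups dropped as the rules dictate.
    """
    by_id = {d.dataset.dataset_id: d for d in datasets}
    removals: dict[str, set[str]] = {i: set() for i in by_id}
    renames: dict[str, dict[str, str]] = {i: {} for i in by_id}
    dropped: dict[str, set[str]] = {i: set() for i in by_id}
    audit: list[DiscrepancyReport] = []

    for r in reports:
        if r.kind == "group_conflict":
            if r.resolution == "dropped_group":
                ds_id = r.datasets[0]
                ds = by_id[ds_id]
                grp = _locus_groups(ds).get(r.locus)
                if grp is not None:
                    dropped[ds_id].add(grp)
                audit.append(r)
                continue
            for ds_id in r.datasets:
                renames[ds_id][r.locus] = _split_suffix(r.locus, ds_id)
            audit.append(DiscrepancyReport(r.locus, r.datasets, r.kind, "suffix_split", r.evidence))
            continue

        # order conflicts
        present_in = [i for i, d in by_id.items() if r.locus in _locus_groups(d)]
        if len(present_in) >= 3:
            deviant = _single_deviant_dataset(by_id, present_in, r.locus)
            if deviant is not None:
                removals[deviant].add(r.locus)
                audit.append(DiscrepancyReport(r.locus, r.datasets, r.kind,
                                               "removed_from_deviant", len(present_in) - 1))
                continue
        if len(present_in) == 2:
            a, b = (by_id[present_in[0]], by_id[present_in[1]])
            grp = _locus_groups(a).get(r.locus)
            flips = (min_flip_reconciliation(a, b, grp, r.locus, max_flips=flip_threshold)
                     if grp else None)
            if flips is not None and flips <= flip_threshold:
                audit.append(DiscrepancyReport(r.locus, r.datasets, r.kind,
                                               "ignored_small", flips))
                continue
        for ds_id in present_in:
            renames[ds_id][r.locus] = _split_suffix(r.locus, ds_id)
        audit.append(DiscrepancyReport(r.locus, r.datasets, r.kind, "suffix_split", r.evidence))

    cleaned: list[Dataset] = []
    for ds_id, ds in by_id.items():
        cleaned.append(_apply(ds, removals[ds_id], renames[ds_id], dropped[ds_id]))
    return cleaned, audit


def _apply(ds: Dataset, remove: set[str], rename: dict[str, str], drop_groups: set[str]) -> Dataset:
    if isinstance(ds, GameteMatrix):
        keep = [l for l, g in zip(ds.loci, ds.groups) if l not in remove and g not in drop_groups]
        out = ds.subset(keep)
        out.loci = [rename.get(l, l) for l in out.loci]
        return out
    from .segdata import MapGroup, DistanceMap as DM
    groups = []
    for g in ds.groups:
        if g.name in drop_groups:
            continue
        loci, intervals = list(g.loci), list(g.intervals)
        # remove loci, merging flanking intervals additively
        for l in [x for x in loci if x in remove]:
            i = loci.index(l)
            loci.pop(i)
            if not intervals:
                continue
            if i == 0:
                intervals.pop(0)
            elif i == len(loci):
                intervals.pop(-1)
            else:
                merged = intervals[i - 1] + intervals[i]
                intervals[i - 1:i + 1] = [merged]
        loci = [rename.get(l, l) for l in loci]
        groups.append(MapGroup(name=g.name, loci=loci, intervals=intervals))
    return DM(dataset=ds.dataset, groups=groups, distance_kind=ds.distance_kind)


def unresolved_reports(datasets: list[Dataset], audit: list[DiscrepancyReport]) -> list[DiscrepancyReport]:
    """Re-run both checks on cleaned datasets, dropping conflicts the audit
    log already marks as deliberately ignored."""
    ignored = {r.locus for r in audit if r.resolution == "ignored_small"}
    out = [r for r in check_group_consistency(datasets) if r.locus not in ignored]
    groups: list[str] = []
    for ds in datasets:
        for g in _group_names(ds):
            if g not in groups:
                groups.append(g)
    for g in groups:
        out.extend(r for r in check_order_consistency(datasets, g) if r.locus not in ignored)
    return out


def write_audit_log(audit: list[DiscrepancyReport], path) -> None:
    import pandas as pd
    rows = [(r.locus, r.kind, ";".join(r.datasets), r.resolution or "", r.evidence) for r in audit]
    pd.DataFrame(rows, columns=["locus", "kind", "datasets", "resolution", "evidence"]).to_csv(
        path, sep="\t", index=False
    )
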