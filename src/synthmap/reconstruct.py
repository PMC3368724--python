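"""Pseudo-gamete reconstruction from distance-only maps.

Published maps that report only inter-locus distances cannot be merged
directly with raw doubled-haploid genotype tables.  This module converts
such maps into synthetic "pseudo-gamete" matrices that reproduce, exactly,
the pairwise adjacent recombination fractions the distances encode: the
first locus of a group is half zeros, half ones, and each subsequent locus
vector introduces ``round(r * N)`` recombinants by flipping, alternately,
the leftmost unflipped zero and the leftmost unflipped one.  Merging these
with real gamete matrices lets one two-point engine drive the whole map.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .segdata import DatasetMeta, DistanceMap, GameteMatrix, MISSING

logger = logging.getLogger(__name__)

__all__ = [
    "RecombinationProfile",
    "kosambi_to_recomb",
    "recomb_to_kosambi",
    "profiles_from_distance_map",
    "gametes_from_profile",
    "gametes_from_distance_map",
    "rescale_profile",
]


def kosambi_to_recomb(k):
    """Recombination fraction for a Kosambi map distance *k* in Morgans.

    r = 0.5 (e^{4k} - 1) / (e^{4k} + 1) = 0.5 tanh(2k); r in [0, 0.5),
    strictly increasing in k.  Accepts scalars or arrays; negative input is
    an error.
    """
    arr = np.asarray(k, dtype=float)
    if np.any(arr < 0):
        raise ValueError("Kosambi distance must be >= 0")
    r = 0.5 * np.tanh(2.0 * arr)
    return float(r) if np.isscalar(k) or arr.ndim == 0 else r


def recomb_to_kosambi(r):
    """Inverse map function: m = 0.25 ln((1+2r)/(1-2r)) Morgans, r < 0.5."""
    arr = np.asarray(r, dtype=float)
    if np.any((arr < 0) | (arr >= 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    m = 0.25 * np.log((1 + 2 * arr) / (1 - 2 * arr))
    return float(m) if np.isscalar(r) or arr.ndim == 0 else m


@dataclass
class RecombinationProfile:
    """One linkage group ready for reconstruction: ordered loci, adjacent
    recombination fractions, and the family size N of the source cross."""

    group: str
    loci: list[str]
    recomb: list[float]
    family_size: int

    def __post_init__(self):
        if len(self.recomb) != max(len(self.loci) - 1, 0):
            raise ValueError(
                f"group {self.group}: {len(self.loci)} loci need "
                f"{max(len(self.loci) - 1, 0)} r values, got {len(self.recomb)}"
            )
        for r in self.recomb:
            if not (0.0 <= r <= 0.5):
                raise ValueError(f"group {self.group}: r={r} outside [0, 0.5]")


def profiles_from_distance_map(dmap: DistanceMap) -> list[RecombinationProfile]:
    """Convert a DistanceMap to per-group recombination profiles.

    Kosambi centimorgans are divided by 100 (the map function takes
    Morgans) before inversion; recombination fractions pass through.
    """
    n = dmap.dataset.weight_size or dmap.dataset.N
    out = []
    for g in dmap.groups:
        if dmap.distance_kind == "kosambi_cM":
            rs = [kosambi_to_recomb(v / 100.0) for v in g.intervals]
        else:
            rs = list(g.intervals)
        out.append(RecombinationProfile(group=g.name, loci=list(g.loci), recomb=rs, family_size=n))
    return out


def rescale_profile(profile: RecombinationProfile, new_N: int) -> RecombinationProfile:
    """Replace the family size used for reconstruction, keeping loci and r.

    Used to down-weight large families so one source does not dominate the
    merged data.  Shrinking N coarsens the recombinant grid (r*N may round
    to fewer recombinants); any interval that loses all its recombinants is
    logged.
    """
    if new_N < 2:
        raise ValueError("new_N must be >= 2")
    if new_N != profile.family_size:
        for i, r in enumerate(profile.recomb):
            if r > 0 and _round_half_away(r * new_N) == 0:
                logger.warning(
                    "group %s interval %d: r=%.4g yields 0 recombinants at N=%d (information lost)",
                    profile.group, i, r, new_N,
                )
    return replace(profile, family_size=new_N)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def gametes_from_profile(profile: RecombinationProfile, meta: DatasetMeta | None = None) -> GameteMatrix:
    """Reconstruct a pseudo-gamete matrix for one linkage group.

    The first locus is ceil(N/2) zeros followed by floor(N/2) ones.  For
    each interval, ``round(r*N)`` recombinants are introduced by flipping
    alternately the leftmost not-yet-flipped 0 to 1 and the leftmost
    not-yet-flipped 1 to 0, so adjacent locus vectors differ at exactly
    ``round(r*N)`` positions.  Deterministic: no randomness is involved.
    """
    n = profile.family_size
    if meta is None:
        meta = DatasetMeta(dataset_id=f"pseudo_{profile.group}", N=n, kind="raw_genotypes")
    vec = np.zeros(n, dtype=np.int8)
    vec[(n + 1) // 2:] = 1
    rows = [vec]
    for i, r in enumerate(profile.recomb):
        nrec = _round_half_away(r * n)
        if nrec > n:
            raise ValueError(
                f"group {profile.group} interval {i}: round(r*N)={nrec} exceeds N={n}"
            )
        prev = rows[-1]
        nxt = prev.copy()
        flipped = np.zeros(n, dtype=bool)
        want = 0  # flip a 0 -> 1 first, then alternate
        for _ in range(nrec):
            cand = np.nonzero((nxt == want) & ~flipped)[0]
            if cand.size == 0:
                # alternate target exhausted; try the other direction
                cand = np.nonzero((nxt == 1 - want) & ~flipped)[0]
                if cand.size == 0:
                    raise ValueError(
                        f"group {profile.group} interval {i}: cannot place {nrec} recombinants"
                    )
                want = 1 - want
            j = cand[0]
            nxt[j] = 1 - nxt[j]
            flipped[j] = True
            want = 1 - want
        rows.append(nxt)
    calls = np.vstack(rows)
    individuals = [f"{meta.dataset_id}_g{j+1}" for j in range(n)]
    return GameteMatrix(
        dataset=meta,
        loci=list(profile.loci),
        groups=[profile.group] * len(profile.loci),
        calls=calls,
        individuals=individuals,
    )


def gametes_from_distance_map(dmap: DistanceMap, rescale_to: int | None = None) -> GameteMatrix:
    """Full reconstruction of a distance-only map into one pseudo-gamete
    matrix covering all its linkage groups."""
    profiles = profiles_from_distance_map(dmap)
    if rescale_to is not None:
        profiles = [rescale_profile(p, rescale_to) for p in profiles]
    n = profiles[0].family_size if profiles else (rescale_to or dmap.dataset.N)
    meta = DatasetMeta(dataset_id=dmap.dataset.dataset_id, N=n, kind="raw_genotypes")
    loci: list[str] = []
    groups: list[str] = []
    blocks = []
    for p in profiles:
        gm = gametes_from_profile(p, meta=meta)
        loci.extend(gm.loci)
        groups.extend(gm.groups)
        blocks.append(gm.calls)
    calls = np.vstack(blocks) if blocks else np.zeros((0, n), dtype=np.int8)
    individuals = [f"{meta.dataset_id}_g{j+1}" for j in range(n)]
    return GameteMatrix(dataset=meta, loci=loci, groups=groups, calls=calls, individuals=individuals)
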