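"""BLAST-homology filtration and cross-species synteny analysis.

Marker sequences mapped on the synthetic linkage map are compared (blastn /
blastx) against model-species genomes (medaka, stickleback, zebrafish).
This module filters the tabular BLAST output down to at most one reliable
hit per marker, builds Oxford grids of trout chromosome arms against model
chromosomes, prunes them (metacentric single-marker re-assignment, orphan
removal, reduction to the expected 3rd-WGD homeolog), projects medaka
homologies back onto the reconstructed teleost-ancestor proto-chromosomes,
and exports side-by-side comparative maps in MapChart text format.

Filtration rules, in order, per query: (1) keep only minimum-e-value hits;
(2) among those, keep only maximum-HSP hits, where HSP score = percent
identity x alignment length; (3) keep the query only if exactly one hit
remains.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace

import pandas as pd

from .homeology import OxfordGrid
from .mapbuild import SyntheticMap

logger = logging.getLogger(__name__)

__all__ = [
    "HomologyHit",
    "DEFAULT_EVALUE_CUTOFF",
    "parse_blast_tabular",
    "read_protein2gene",
    "read_homeolog_pairs",
    "read_ancestor_map",
    "collapse_to_gene",
    "filter_hits",
    "species_oxford_grid",
    "refine_grid",
    "reduce_to_expected_homeolog",
    "project_ancestor",
    "export_comparative_map",
    "CM_PER_BP",
]

DEFAULT_EVALUE_CUTOFF = 1e-5
# display conversion for comparative maps: 0.5 Mb per cM
CM_PER_BP = 1.0 / 0.5e6


@dataclass(frozen=True)
class HomologyHit:
    """One marker -> model-genome match (a filtered BLAST hit)."""

    query: str
    program: str  # "blastn" | "blastx"
    subject: str  # chromosome for blastn; protein/gene id for blastx
    sstart: int  # 1-based bp on the subject
    send: int
    evalue: float
    pident: float
    length: int
    gene_id: str | None = None
    chromosome: str | None = None  # resolved chromosome unit

    @property
    def hsp_score(self) -> float:
        """Percent identity x alignment length, used to break e-value ties."""
        return self.pident * self.length

    @property
    def chrom(self) -> str:
        return self.chromosome if self.chromosome is not None else self.subject


def parse_blast_tabular(path, program: str,
                        evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF) -> list[HomologyHit]:
    """Parse 12-column BLAST tabular output (the commented ``-m 9`` /
    ``outfmt 7`` dialect); ``#`` lines are ignored; rows above the e-value
    cutoff are discarded at parse time.  A malformed row raises with its
    line number."""
    if program not in ("blastn", "blastx"):
        raise ValueError(f"unknown program {program!r}")
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 tab-separated fields, got {len(parts)}")
            try:
                q, s = parts[0], parts[1]
                pident = float(parts[2])
                length = int(parts[3])
                sstart, send = int(parts[8]), int(parts[9])
                evalue = float(parts[10])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed row ({e})") from None
            if evalue > evalue_cutoff:
                continue
            chromosome = s if program == "blastn" else None
            hits.append(HomologyHit(query=q, program=program, subject=s, sstart=sstart,
                                    send=send, evalue=evalue, pident=pident, length=length,
                                    chromosome=chromosome))
    return hits


def read_protein2gene(path) -> dict[str, tuple[str, str | None, int | None]]:
    """Protein-ID -> (gene-ID, chromosome, gene start bp) table.  The
    chromosome/start columns are optional; without them a collapsed blastx
    hit keeps its own subject coordinates."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = {}
    for _, row in df.iterrows():
        chrom = row.get("chromosome", "") or None
        start = row.get("start_bp", "")
        out[row.iloc[0]] = (row.iloc[1], chrom, int(start) if start else None)
    return out


def read_homeolog_pairs(path) -> set[frozenset]:
    """Unordered within-species chromosome pairs descending from the 3rd
    (teleost) WGD, as a TSV with two chromosome columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {frozenset((a, b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])}


def read_ancestor_map(path) -> dict[str, list[str]]:
    """Medaka chromosome -> teleost-ancestor proto-chromosome labels (A-M),
    one row per segment so multiplicity is preserved."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, list[str]] = defaultdict(list)
    for chrom, label in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out[chrom].append(label)
    return dict(out)


def collapse_to_gene(hits: list[HomologyHit],
                     protein2gene: dict[str, tuple[str, str | None, int | None]]) -> list[HomologyHit]:
    """Rename blastx protein subjects to their gene IDs (one gene encodes
    several peptides, so hits to alternative peptides of one gene become
    same-gene hits and no longer trip the single-hit rule).  blastn hits
    pass through; unknown proteins are kept with a warning."""
    out = []
    for h in hits:
        if h.program != "blastx":
            out.append(h)
            continue
        entry = protein2gene.get(h.subject)
        if entry is None:
            logger.warning("protein %s absent from protein->gene table; hit kept as-is", h.subject)
            out.append(h)
            continue
        gene, chrom, start = entry
        out.append(replace(h, gene_id=gene,
                           chromosome=chrom if chrom is not None else h.chromosome,
                           sstart=start if start is not None else h.sstart))
    return out


def filter_hits(hits: list[HomologyHit]) -> list[HomologyHit]:
    """Reduce to at most one hit per query by the three filtration rules.

    Per query: survivors of the minimum e-value (rule 1), then of the
    maximum HSP score (rule 2); hits to the same gene count as one hit.  A
    query with more than one distinct survivor is dropped entirely
    (rule 3).  Idempotent; output queries are unique.
    """
    by_query: dict[str, list[HomologyHit]] = defaultdict(list)
    for h in hits:
        by_query[h.query].append(h)
    kept = []
    for q in sorted(by_query):
        hs = by_query[q]
        emin = min(h.evalue for h in hs)
        hs = [h for h in hs if h.evalue == emin]
        smax = max(h.hsp_score for h in hs)
        hs = [h for h in hs if h.hsp_score == smax]
        # alternative peptides of one gene collapse to a single survivor
        distinct = {(h.gene_id or h.subject) for h in hs}
        if len(distinct) == 1:
            kept.append(hs[0])
    return kept


def species_oxford_grid(filtered: list[HomologyHit], smap: SyntheticMap) -> OxfordGrid:
    """Oxford grid of trout chromosome arms x model-species chromosomes:
    cell (arm, chromosome) counts the filtered markers of that arm hitting
    that chromosome.  Markers absent from the map (or centromeric, hence
    arm-less) are excluded and logged."""
    grid = OxfordGrid(row_labels=[], col_labels=[], symmetric=False)
    for h in filtered:
        try:
            _, _, arm = smap.locate(h.query)
        except KeyError:
            grid.log.append(f"unmapped:{h.query}")
            continue
        if arm is None:
            grid.log.append(f"no-arm:{h.query}")
            continue
        grid.add(arm, h.chrom, h)
    return grid


def _arm_pairs_from_map(smap: SyntheticMap) -> list[tuple[str, str]]:
    out = []
    for g in smap.groups:
        if g.centromere is not None and not g.centromere.acrocentric:
            out.append((f"{g.name}p", f"{g.name}q"))
    return out


def refine_grid(grid: OxfordGrid, metacentrics: list[tuple[str, str]] | None = None,
                smap: SyntheticMap | None = None, orphan_min: int = 2) -> OxfordGrid:
    """Prune a species grid in two logged steps.

    1. Metacentric re-assignment: when both arms of one metacentric hit the
       same model chromosome and one arm's support is a single marker, that
       marker is assumed mis-assigned across the centromere and its count
       moves to the better-supported arm.
    2. Orphan removal: cells still supported by a single marker are noise
       and are zeroed.
    """
    if metacentrics is None:
        metacentrics = _arm_pairs_from_map(smap) if smap is not None else []
    for p_arm, q_arm in metacentrics:
        for chrom in sorted(set(grid.col_labels)):
            cp, cq = grid.count(p_arm, chrom), grid.count(q_arm, chrom)
            if cp == 0 or cq == 0 or cp == cq == 1:
                continue
            if cp == 1 or cq == 1:
                src, dst = (p_arm, q_arm) if cp == 1 else (q_arm, p_arm)
                item = grid.cells[grid.key(src, chrom)].pop()
                grid.cells[grid.key(dst, chrom)].append(item)
                name = getattr(item, "query", item)
                grid.log.append(f"reassigned:{name}:{src}->{dst}:{chrom}")
    for cell in grid.nonzero_cells():
        if len(grid.cells[cell]) < orphan_min:
            for item in grid.cells[cell]:
                name = getattr(item, "query", item)
                grid.log.append(f"orphan-removed:{name}:{cell[0]}:{cell[1]}")
            grid.cells[cell] = []
    return grid


def reduce_to_expected_homeolog(grid: OxfordGrid, homeologs: set[frozenset]) -> OxfordGrid:
    """Keep, per trout arm, only the "expected homologous chromosome" of
    each 3rd-WGD homeolog pair — the member with more sequence homologies;
    a tie keeps both cells and is flagged in the grid log."""
    for arm in sorted(set(grid.row_labels)):
        for pair in sorted(homeologs, key=sorted):
            c1, c2 = sorted(pair)
            n1, n2 = grid.count(arm, c1), grid.count(arm, c2)
            if n1 == 0 or n2 == 0:
                continue
            if n1 == n2:
                grid.log.append(f"homeolog-tie:{arm}:{c1}={c2}:{n1}")
                continue
            drop = c1 if n1 < n2 else c2
            for item in grid.cells[grid.key(arm, drop)]:
                name = getattr(item, "query", item)
                grid.log.append(f"homeolog-dropped:{name}:{arm}:{drop}")
            grid.cells[grid.key(arm, drop)] = []
    return grid


def project_ancestor(grid: OxfordGrid, ancestor: dict[str, list[str]]) -> dict[str, list[str]]:
    """Translate each arm's retained medaka chromosomes into teleost-ancestor
    proto-chromosome labels (multiset per arm).  Medaka, having kept the
    ancestral chromosome structure, acts as the bridge; a retained medaka
    chromosome missing from the ancestor table is an error."""
    out: dict[str, list[str]] = {}
    for arm in sorted(set(grid.row_labels)):
        labels: list[str] = []
        for chrom in sorted(set(grid.col_labels)):
            if grid.count(arm, chrom) == 0:
                continue
            if chrom not in ancestor:
                raise KeyError(f"medaka chromosome {chrom!r} absent from ancestor map")
            labels.extend(sorted(set(ancestor[chrom])))
        out[arm] = sorted(labels)
    return out


def single_ancestor_arms(projection: dict[str, list[str]]) -> list[str]:
    """Arms traced back to exactly one ancestral proto-chromosome."""
    return sorted(a for a, labels in projection.items() if len(set(labels)) == 1 and labels)


def export_comparative_map(grid: OxfordGrid, smap: SyntheticMap, path) -> None:
    """MapChart text export of model chromosomes aligned to trout groups.

    Each retained marker is displayed on its model chromosome at
    subject-start bp / 0.5e6 cM, named by its gene ID when a protein was
    identified and by its start position otherwise; each model chromosome
    group is paired with the trout group(s) its markers map to.
    """
    by_chrom: dict[str, list[HomologyHit]] = defaultdict(list)
    for (arm, chrom), items in grid.cells.items():
        by_chrom[chrom].extend(h for h in items if isinstance(h, HomologyHit))
    with open(path, "w") as fh:
        for chrom in sorted(by_chrom):
            hits = sorted(by_chrom[chrom], key=lambda h: h.sstart)
            trout_groups = sorted({smap.locate(h.query)[0] for h in hits})
            fh.write(f"group {chrom} ; trout: {','.join(trout_groups)}\n")
            for h in hits:
                name = h.gene_id if h.gene_id else str(h.sstart)
                fh.write(f"{name} {h.sstart * CM_PER_BP:.2f}\n")
            fh.write("\n")
        for g in smap.groups:
            fh.write(f"group {g.name}\n")
            for locus, pos in zip(g.loci, g.positions):
                fh.write(f"{locus} {pos:.2f}\n")
            fh.write("\n")
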