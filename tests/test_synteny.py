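"""BLAST filtration rules, grid pruning and ancestor projection."""

import itertools

import pytest

from synthmap import simfix
from synthmap.homeology import OxfordGrid
from synthmap.synteny import (
    CM_PER_BP,
    HomologyHit,
    collapse_to_gene,
    export_comparative_map,
    filter_hits,
    parse_blast_tabular,
    project_ancestor,
    reduce_to_expected_homeolog,
    refine_grid,
    single_ancestor_arms,
    species_oxford_grid,
)


def hit(query, subject, evalue=1e-20, pident=95.0, length=200, sstart=1000,
        program="blastn", gene_id=None):
    return HomologyHit(query=query, program=program, subject=subject, sstart=sstart,
                       send=sstart + length - 1, evalue=evalue, pident=pident,
                       length=length, gene_id=gene_id,
                       chromosome=subject if program == "blastn" else None)


class TestParse:
    def _write(self, path, rows, comments=True):
        with open(path, "w") as fh:
            if comments:
                fh.write("# BLASTN 2.2.26\n# Fields: ...\n")
            for r in rows:
                fh.write("\t".join(map(str, r)) + "\n")

    def row(self, q="m1", s="Ola13", ev="1e-20"):
        return (q, s, "95.00", "200", "3", "0", "1", "200", "1000", "1199", ev, "370")

    def test_three_rows(self, tmp_path):
        p = tmp_path / "b.tsv"
        self._write(p, [self.row(q=f"m{i}") for i in range(3)])
        assert len(parse_blast_tabular(p, "blastn")) == 3

    def test_only_comments(self, tmp_path):
        p = tmp_path / "b.tsv"
        self._write(p, [])
        assert parse_blast_tabular(p, "blastn") == []

    def test_scientific_evalue(self, tmp_path):
        p = tmp_path / "b.tsv"
        self._write(p, [self.row(ev="1e-20")])
        assert parse_blast_tabular(p, "blastn")[0].evalue == 1e-20

    def test_cutoff_applied_at_parse(self, tmp_path):
        p = tmp_path / "b.tsv"
        self._write(p, [self.row(ev="1e-20"), self.row(q="m2", ev="1e-3")])
        assert [h.query for h in parse_blast_tabular(p, "blastn")] == ["m1"]

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "b.tsv"
        self._write(p, [("m1", "x", "bad")])
        with pytest.raises(ValueError, match=":3"):
            parse_blast_tabular(p, "blastn")

    def test_simfix_fixture_roundtrips(self, tmp_path, true_map_small):
        sim = simfix.simulate_homology_table(true_map_small, tmp_path / "h.tsv", seed=1)
        hits = parse_blast_tabular(sim.path, "blastn")
        assert len(hits) > 0
        assert all(h.evalue <= 1e-5 for h in hits)


class TestFiltration:
    def test_rule1_min_evalue(self):
        hits = [hit("m1", "A", evalue=1e-20), hit("m1", "B", evalue=1e-10)]
        out = filter_hits(hits)
        assert len(out) == 1 and out[0].subject == "A"

    def test_rule2_max_hsp_on_tie(self):
        hits = [hit("m1", "A", evalue=1e-20, pident=95.0, length=200),
                hit("m1", "B", evalue=1e-20, pident=90.0, length=150)]
        out = filter_hits(hits)
        assert out[0].subject == "A" and out[0].hsp_score == 19000.0

    def test_rule3_full_tie_drops_query(self):
        hits = [hit("m1", "A"), hit("m1", "B")]
        assert filter_hits(hits) == []

    def test_idempotent_unique_queries(self):
        hits = [hit("m1", "A", evalue=1e-20), hit("m1", "B", evalue=1e-10),
                hit("m2", "C"), hit("m3", "D"), hit("m3", "E")]
        once = filter_hits(hits)
        assert sorted({h.query for h in once}) == ["m1", "m2"]
        assert filter_hits(once) == once

    def test_matches_brute_force_enumeration(self):
        import numpy as np
        rng = np.random.default_rng(5)
        hits = []
        for q in range(30):
            for _ in range(int(rng.integers(1, 5))):
                hits.append(hit(f"m{q}", f"C{rng.integers(6)}",
                                evalue=float(rng.choice([1e-20, 1e-10, 1e-8])),
                                pident=float(rng.choice([90.0, 95.0])),
                                length=int(rng.choice([100, 200]))))
        # brute force: enumerate per query
        expected = {}
        for q, grp in itertools.groupby(sorted(hits, key=lambda h: h.query),
                                        key=lambda h: h.query):
            grp = list(grp)
            emin = min(h.evalue for h in grp)
            s1 = [h for h in grp if h.evalue == emin]
            smax = max(h.hsp_score for h in s1)
            s2 = [h for h in s1 if h.hsp_score == smax]
            if len({h.subject for h in s2}) == 1:
                expected[q] = s2[0].subject
        got = {h.query: h.subject for h in filter_hits(hits)}
        assert got == expected

    def test_gene_collapse_rescues_peptide_tie(self):
        p2g = {"P1": ("G", "Chr01", 500), "P2": ("G", "Chr01", 500)}
        hits = [hit("m1", "P1", program="blastx"), hit("m1", "P2", program="blastx")]
        collapsed = collapse_to_gene(hits, p2g)
        assert all(h.gene_id == "G" and h.chromosome == "Chr01" for h in collapsed)
        out = filter_hits(collapsed)
        assert len(out) == 1 and out[0].gene_id == "G"

    def test_collapse_leaves_blastn_and_unknown_proteins(self, caplog):
        hits = [hit("m1", "Chr01"), hit("m2", "Punknown", program="blastx")]
        out = collapse_to_gene(hits, {})
        assert out == hits


class TestGrids:
    def _grid(self, cells):
        g = OxfordGrid(row_labels=[], col_labels=[], symmetric=False)
        for (arm, chrom), markers in cells.items():
            for m in markers:
                g.add(arm, chrom, m)
        return g

    def test_species_grid_counts(self, true_map_small, tmp_path):
        from synthmap import mapbuild
        sim = simfix.simulate_homology_table(true_map_small, tmp_path / "h.tsv", seed=2)
        hits = filter_hits(parse_blast_tabular(sim.path, "blastn"))
        # synthetic map == true map for this check
        smap = _true_as_synthetic(true_map_small)
        grid = species_oxford_grid(hits, smap)
        assert grid.counts == sim.planted_cells
        assert grid.grand_total == len([h for h in hits
                                        if smap.locate(h.query)[2] is not None])

    def test_refine_reassigns_single_marker_cross_centromere(self):
        g = self._grid({("RT01p", "Ola13"): ["a", "b", "c", "d", "e", "f"],
                        ("RT01q", "Ola13"): ["x"]})
        refine_grid(g, metacentrics=[("RT01p", "RT01q")])
        assert g.count("RT01p", "Ola13") == 7
        assert g.count("RT01q", "Ola13") == 0
        assert any("reassigned:x" in line for line in g.log)

    def test_refine_removes_orphans(self):
        g = self._grid({("RT01p", "Ola13"): ["a", "b"], ("RT02q", "Ola05"): ["z"]})
        refine_grid(g, metacentrics=[])
        assert g.count("RT02q", "Ola05") == 0
        assert g.count("RT01p", "Ola13") == 2

    def test_refine_leaves_supported_distinct_cells(self):
        g = self._grid({("RT01p", "Ola13"): ["a", "b"], ("RT01q", "Ola05"): ["c", "d"]})
        total = g.grand_total
        refine_grid(g, metacentrics=[("RT01p", "RT01q")])
        assert g.grand_total == total

    def test_refine_never_increases_total(self):
        g = self._grid({("RT01p", "Ola13"): ["a"], ("RT01q", "Ola13"): ["b", "c"],
                        ("RT02p", "Ola01"): ["d"]})
        before = g.grand_total
        refine_grid(g, metacentrics=[("RT01p", "RT01q")])
        assert g.grand_total <= before

    def test_reduce_keeps_expected_homeolog(self):
        g = self._grid({("RT06q", "groupVI"): list("abcde"),
                        ("RT06q", "groupV"): list("xy")})
        reduce_to_expected_homeolog(g, {frozenset(("groupV", "groupVI"))})
        assert g.count("RT06q", "groupVI") == 5
        assert g.count("RT06q", "groupV") == 0

    def test_reduce_ignores_non_homeologs(self):
        g = self._grid({("RT06q", "groupVI"): list("abcde"),
                        ("RT06q", "groupXII"): list("xy")})
        reduce_to_expected_homeolog(g, {frozenset(("groupV", "groupVI"))})
        assert g.count("RT06q", "groupXII") == 2

    def test_reduce_tie_keeps_both_and_flags(self):
        g = self._grid({("RT06q", "groupVI"): list("abcde"),
                        ("RT06q", "groupV"): list("vwxyz")})
        reduce_to_expected_homeolog(g, {frozenset(("groupV", "groupVI"))})
        assert g.count("RT06q", "groupVI") == 5 and g.count("RT06q", "groupV") == 5
        assert any("homeolog-tie" in line for line in g.log)


class TestAncestor:
    def test_single_chromosome_lookup(self):
        g = OxfordGrid(row_labels=[], col_labels=[], symmetric=False)
        for m in ("a", "b"):
            g.add("RT01p", "Ola13", m)
        proj = project_ancestor(g, {"Ola13": ["D"]})
        assert proj == {"RT01p": ["D"]}
        assert single_ancestor_arms(proj) == ["RT01p"]

    def test_multi_fragment_arm(self):
        g = OxfordGrid(row_labels=[], col_labels=[], symmetric=False)
        anc = {}
        for i, chrom in enumerate(["Ola02", "Ola08", "Ola14", "Ola21"]):
            g.add("Omy7p", chrom, f"m{i}")
            g.add("Omy7p", chrom, f"n{i}")
            anc[chrom] = [chr(ord("A") + i)]
        proj = project_ancestor(g, anc)
        assert proj["Omy7p"] == ["A", "B", "C", "D"]
        assert single_ancestor_arms(proj) == []

    def test_missing_chromosome_is_error(self):
        g = OxfordGrid(row_labels=[], col_labels=[], symmetric=False)
        g.add("RT01p", "Ola13", "a")
        with pytest.raises(KeyError):
            project_ancestor(g, {"Ola01": ["A"]})


class TestExport:
    def test_bp_to_cm_conversion_and_naming(self, tmp_path, true_map_small):
        g = OxfordGrid(row_labels=[], col_labels=[], symmetric=False)
        smap = _true_as_synthetic(true_map_small)
        marker = smap.groups[0].loci[0]
        h1 = hit(marker, "Ola13", sstart=1_000_000)
        h2 = hit(smap.groups[0].loci[1], "Pgene", program="blastx", gene_id="ENSG1", sstart=0)
        g.add("LG01p", "Ola13", h1)
        g.add("LG01p", "Ola13", h2)
        out = tmp_path / "cmp.txt"
        export_comparative_map(g, smap, out)
        text = out.read_text()
        assert f"{marker.split('_')[0]}" in text
        assert "1000000 2.00" in text  # bp / 0.5e6
        assert "ENSG1 0.00" in text


def _true_as_synthetic(tm):
    """Promote a simfix TrueMap to a SyntheticMap with its true layout."""
    from synthmap.mapbuild import PositionedGroup, SyntheticMap, partition_arms
    groups = []
    for g in tm.groups:
        pg = PositionedGroup(name=g.name, loci=list(g.markers),
                             positions=[p - g.positions[0] for p in g.positions])
        partition_arms(pg, g.centromere)
        groups.append(pg)
    return SyntheticMap(groups=groups)
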