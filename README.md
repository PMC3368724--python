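# synthmap

Tools for building a **synthetic (consensus) genetic linkage map** from
heterogeneous doubled-haploid (DH) mapping data, and for the comparative
analyses such a map enables in a salmonid genome: duplicated-locus
homeology grids (4th whole-genome duplication), BLAST-homology filtration,
cross-species Oxford-grid synteny with pruning rules, and projection onto
the reconstructed teleost ancestor.

## Who this is for

Linkage-map builders and comparative genomicists working with species —
rainbow trout is the motivating case — whose mapping resources are
scattered across laboratories: some panels published raw gamete genotypes,
others only ordered loci with inter-locus distances. Because a DH
individual is fully homozygous, its genotype *is* a gamete vector, so both
kinds of data can be unified at the gamete level.

## The method

1. **Pseudo-gamete reconstruction.** A distance-only map is converted to
   synthetic gamete vectors. Kosambi distances k (Morgans) become
   recombination fractions by the inverse map function

   r = ½ (e⁴ᵏ − 1)/(e⁴ᵏ + 1) = ½ tanh(2k).

   For a family of N offspring the first locus of a group is ⌈N/2⌉ zeros
   followed by ⌊N/2⌋ ones; each next locus introduces round(r·N)
   recombinants by flipping, alternately, the leftmost unflipped 0→1 and
   1→0. Adjacent vectors then differ at exactly round(r·N) positions, so
   the reconstruction preserves every pairwise adjacent r.
2. **Screening.** Linkage-group assignments and shared-locus orders are
   compared across datasets (orientation-free longest common subsequence).
   A lone deviant dataset loses the marker; a two-dataset conflict
   explicable by ≤ 2 genotype-call changes is ignored; anything else is
   split into per-dataset suffixed copies.
3. **Map building.** Datasets are merged per linkage group (union of loci,
   concatenation of gametes). Because crossover interference is close to
   one in salmonids, the recombination percentage itself is the mapping
   function: two-point r̂ = min(discordant, concordant)/n, marker orders
   minimise the expected map length Σ adjacent r̂ (exact Held–Karp dynamic
   programming up to 15 loci; simulated annealing, taboo search and
   sliding-window "flips" beyond), and positions are cumulative 100·r̂ cM.
   Centromere ranges partition each group into p/q arms.
4. **Homeology.** Duplicated loci ("/1"–"/2" twins) shared between arm
   pairs fill a within-genome Oxford grid; single-marker cells are orphans.
   Enrichment of homologies on homeologous model chromosomes is tested with
   an exact binomial tail P(X ≥ k | n, p).
5. **Synteny.** BLAST tabular hits (e-value ≤ 1e-5) are reduced to one hit
   per marker: minimum e-value, then maximum HSP score
   (%identity × alignment length), then drop any still-ambiguous query.
   Arm × model-chromosome grids are pruned (metacentric single-marker
   re-assignment, orphan removal, reduction to the expected 3rd-WGD
   homeolog) and medaka homologies are translated into teleost-ancestor
   proto-chromosome labels (A–M).

A seed-deterministic simulator (`synthmap.simfix`) generates ground-truth
maps, DH families (at-most-one-crossover-per-arm interference) and BLAST
fixtures with planted decoys, so every stage is testable end to end.

## Worked example

```sh
synthmap simulate --outdir demo/fx --seed 11      # 2 groups x 20 markers, 3 DH families of 50
synthmap run --config demo/config.yaml            # see tests/test_pipeline.py for the config shape
```

The output directory contains the positioned map, MapChart exports, grids
and audit logs. On this fixture:

```
$ head -4 demo/out/synthetic_map.tsv
group   locus       position_cM  arm
LG01    Dup002/1    0.0          p
LG01    LG01_M009   7.0707       p
LG01    LG01_M008   13.5223      p

$ cat demo/out/medaka_grid_parsimonious.tsv
        Chr01  Chr02  Chr03  Chr04
LG01p   0      3      0      0
LG01q   4      0      0      0
LG02p   0      0      0      3
LG02q   0      0      4      0
```

Each linkage group is recovered up to reversal (a group's orientation is
arbitrary, so here LG01's p arm corresponds to the simulator's q arm), and
every retained arm × chromosome cell is a planted synteny supported by ≥ 2
markers — orphan decoys have been removed. The ancestor projection traces
each arm to a single proto-chromosome, as planted.

In the library:

```pycon
>>> from synthmap.homeology import binomial_tail
>>> binomial_tail(12, 24, 1/24)       # homeolog enrichment, 12 of 24 arms
4.627796328129183e-11                 # ~ 5e-11: far beyond chance
>>> from synthmap.reconstruct import RecombinationProfile, gametes_from_profile
>>> gm = gametes_from_profile(RecombinationProfile("g", ["A", "B"], [0.04], 50))
>>> (gm.calls[0] != gm.calls[1]).sum()   # 4% x 50 offspring
2
```

## Layout

- `synthmap.segdata` — containers and TSV I/O for segregation data,
  distance maps, locus-name standardisation, redundant-locus detection
- `synthmap.reconstruct` — Kosambi inversion, pseudo-gamete reconstruction
- `synthmap.screen` — cross-dataset consistency checks and resolution
- `synthmap.mapbuild` — merging, two-point estimation, ordering, positions,
  arms, MapChart export
- `synthmap.homeology` — arm Oxford grids, classification, binomial test
- `synthmap.synteny` — BLAST parsing/filtration, species grids, pruning,
  ancestor projection, comparative-map export
- `synthmap.simfix` — ground-truth simulator
- `synthmap.pipeline` / `synthmap.cli` — orchestration and the `synthmap`
  command

See `docs/methods.md` for the model, parameter and design notes.
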