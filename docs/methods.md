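# Methods notes

## The problem and the model

A doubled-haploid (DH) offspring carries two identical copies of a single
gamete, so its multilocus genotype is a binary gamete vector and the
recombination fraction between two loci is directly countable as the
discordance rate across offspring. This package merges DH mapping panels
from different sources into one synthetic map. Sources that published only
ordered loci with distances are converted into *pseudo-gamete* vectors
that reproduce, exactly, the adjacent recombination fractions their
distances encode; from there on all data are treated uniformly.

The mapping function is the recombination percentage itself, not Kosambi
or Haldane distance: in salmonids crossover interference is close to
complete (rarely more than one crossover per chromosome arm per meiosis),
so adjacent-interval recombination fractions are effectively additive and
100·r̂ is used as the cM increment directly. Kosambi arises only on input,
when a source map's distances must be inverted back to fractions:
r = ½·tanh(2k), k in Morgans (input cM are divided by 100).

## Pseudo-gamete reconstruction

- First locus: ⌈N/2⌉ zeros then ⌊N/2⌋ ones (balanced segregation).
- Interval with fraction r: round(r·N) recombinants, rounding half away
  from zero; the example 4% × 50 = 2 is exact. Flips alternate 0→1 / 1→0,
  always at the leftmost not-yet-flipped position; if one symbol class is
  exhausted the other is used, and an impossible count raises.
- Per-interval rounding (no accumulation of fractional recombinants across
  intervals): each interval's Hamming distance is then exactly round(r·N),
  which is the property the merge step relies on.
- Down-weighting: a source may be rescaled to a smaller effective family
  (e.g. 86 → 50) so one large panel does not dominate; intervals whose
  round(r·N) collapses to zero under the new N are logged as information
  loss.

## Screening rules

"Order discrepancy" is operationalised as exclusion from the
orientation-free longest common subsequence (LCS) of the shared-locus
orders of a dataset pair — whole-group reversal is never a conflict. When
several maximum LCSs exist, the deviant set minimising total displaced
rank distance is chosen, then lexicographic order breaks ties.

Resolution, in order:

1. one deviant dataset against ≥ 2 concordant ones → the locus is removed
   from the deviant dataset only;
2. conflict between exactly two datasets → find the minimum number of
   genotype-call flips at the locus, in either raw dataset, after which
   that dataset's own two-point objective supports the other dataset's
   order at least as well as its own; ≤ 2 flips → the conflict is
   attributed to genotyping error and ignored; otherwise (or when neither
   dataset has raw genotypes — pseudo-gamete data cannot be "genotype
   inconsistent") the locus is split into per-dataset suffixed copies;
3. group-assignment conflicts are always suffix-split; groups a source
   itself flags as merged/ambiguous are dropped from that source.

Flips are only counted, never applied: no automatic genotype correction.

## Two-point estimation and ordering

r̂ = min(discordant, concordant)/n over the meioses where both loci are
typed; the minority class fixes the phase (coupling/repulsion), so marker
coding polarity is irrelevant. n = 0 gives r̂ = 0.5 with weight zero; such
pairs are barred from adjacency (cost 10³) unless the group would
disconnect, in which case the junction is flagged.

Ordering minimises the expected map length Σ adjacent r̂ — an open-path
travelling-salesman objective chosen because it matches the mapping
function, is brute-force verifiable, and avoids re-implementing a hidden
multipoint EM. Methods:

- `exact`: Held–Karp dynamic programming over subsets; optimal, ≤ 15 loci.
- `annealing`: T₀ = 1.0, geometric cooling 0.95, 300 moves per
  temperature, stop at T = 10⁻³; moves are adjacent transpositions,
  segment reversals and single-locus reinsertions, with O(1) delta
  evaluation (the cost matrix is symmetric).
- `taboo`: steepest segment-reversal search, tenure 15, aspiration on new
  global best, 20·n iterations.
- `flips`: exhaustive permutation of every sliding window of width 5 until
  no window improves.

All heuristics start from a greedy nearest-neighbour path and never return
something worse than it; all are deterministic given the seed. Orders are
canonicalised so the first locus name sorts before the last (an order and
its reversal have identical objective). A weighted objective
(r̂ · n_informative) is available by config but measurably *hurts* order
recovery on simulated data and is not the default.

Positions: position₁ = 0, positionᵢ₊₁ = positionᵢ + 100·r̂ cM, so the
interval sum equals the group length identically. Centromere ranges (two
flanking loci, input data — centromere mapping itself is out of scope)
partition loci into p / centromeric / q; acrocentric groups carry one arm
(q) and a terminal range.

## Homeology and the binomial test

The within-genome Oxford grid counts duplicate pairs ("/1"–"/2" twins)
with one member on each of two arms; pairs with a centromeric or unmapped
member go to an unassigned bucket, so cell sum + bucket = pair count by
construction. Cells under `min_support` (default 2, matching the
treatment of single-marker homeologies as noise) are orphans; the rest are
classified against a prior-knowledge table (known → previously_known,
suggested → confirmed, absent → new).

`binomial_tail(k, n, p)` sums the exact binomial upper tail in log space
(log-gamma coefficients, running log-sum-exp); with k=12, n=24, p=1/24 it
gives 4.63×10⁻¹¹. n defaults to nothing — the chromosome number is an
explicit parameter, since using one species' count for another's test is a
modelling choice the caller should own.

## Synteny filtration and pruning

Parsing accepts the commented 12-column BLAST tabular dialect; the e-value
cutoff (1e-5) applies at parse time. blastx protein subjects are renamed
to gene IDs before filtration so alternative peptides of one gene cannot
masquerade as multiple hits. Filtration per query: minimum e-value, then
maximum HSP score (%identity × alignment length), then keep only queries
with a single surviving subject. The procedure is idempotent.

Grid pruning: (1) if both arms of a metacentric hit the same model
chromosome and one arm's support is a single marker, that marker is
re-assigned across the centromere to the supported arm; (2) remaining
single-marker cells are zeroed as orphans; (3) when an arm hits both
members of a 3rd-WGD homeolog pair, only the better-supported ("expected")
chromosome is kept — ties keep both and are flagged. Every move is logged
with marker identities. Re-assignment precedes orphan removal; reduction
operates on the refined grid. Comparative-map display positions are
subject-start bp / 0.5×10⁶ cM (0.5 Mb per cM, chosen for drawing
convenience over the usual 1 Mb/cM), markers named by gene ID when a
protein was identified, else by start position. Strand is ignored.

Ancestor projection translates each arm's retained medaka chromosomes into
proto-chromosome labels (A–M) via the medaka → ancestor table; medaka acts
as the bridge because it retains the ancestral chromosome structure.

## The simulator and what passing tests mean

`simfix` plants a full ground truth: marker positions (gap = 5 cM minimum
plus a Dirichlet-distributed remainder), a mid-group centromere, 4th-WGD
arm homeologs with duplicate pairs at 26% of loci, one model chromosome
per arm, 3rd-WGD chromosome pairs sharing an ancestor label, and per-marker
bp at 0.5 Mb/cM. DH gametes default to complete interference (at most one
crossover per arm, probability arm-length/100, placed length-
proportionally); the independent-interval model exists for calibration
only. Noise: symmetric call flips (error_rate) and per-call masking
(missing_rate). BLAST fixtures plant orphan decoys (a stronger hit to a
wrong chromosome, never the sibling arm's chromosome, capped so every true
cell keeps ≥ 2 markers) and tied-hit queries that rule 3 must drop.

What the simulator does **not** emulate: segregation distortion, marker
ascertainment bias, dataset-specific marker panels (all families type all
markers), genotyping-error clustering, real sequence evolution (homology
fixtures are coordinate-level). Passing tests therefore demonstrate
algorithmic correctness and statistical behaviour under clean MCAR noise,
not robustness to every artefact of historical datasets.

## Problem sizes and numerical choices

The test suite and acceptance script use: ordering-oracle equivalence on
groups of 5–8 markers (exact enumeration is feasible there); pipeline
recovery on one 20-marker group of 120 cM — near the mean group length of
a dense salmonid map (~3600 cM over 29 groups) — with three N=50 families,
20% missing and 0.5% error, 100 seeds in tests and 60 in the script;
filtration checks over 20 seeds with Poisson(2) orphan and Poisson(1) tie
decoys. Objective comparisons use a 10⁻⁹ absolute slack; position output
rounds to 4 decimals.

## Known limitations

- Under the documented noise the argmin of the two-point objective differs
  from the true order by one adjacent swap in roughly 10% of simulated
  20-marker groups: missing data break the near-exact cancellation that
  makes two-point swap comparisons noise-free on complete DH data. The
  heuristics reliably find the objective's optimum; the residual is a
  property of the objective, which a multipoint likelihood (out of scope)
  would reduce. Map length inflates by ~13% at 0.5% call error — classic
  map expansion; no correction is applied.
- For very long metacentric groups (arms approaching 100 cM under complete
  interference) the folded estimator can map arm-end discordance (> 0.85)
  below adjacent r̂ and the objective may reverse an arm; realistic group
  lengths sit well below this regime.
- The 35-vs-21 style split of ignored vs suffix-split two-dataset
  conflicts depends on the flip-threshold operationalisation (≤ 2); the
  original criterion was informal, so exact replication on historical data
  is not guaranteed.
- Exact ordering is capped at 15 loci (2¹⁵·15² DP states); beyond that
  only heuristic optimality holds.
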