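# Methods

This document records the statistical model behind each stage, the
default parameters and why they were chosen, the numerical design
decisions, and the limitations of the implementation.

## 1. Regulatory-network inference

**Mutual information estimator.** Expression profiles are first mapped
to copula normal scores (rank-transform, then inverse standard-normal),
which makes the estimator invariant under monotone transforms of either
variable. MI is then estimated with a Gaussian kernel density estimator
(bandwidth `1.06 σ n^{-1/5}`). The estimator's positive bias for
independent pairs depends only on the sample count `n` after the copula
transform, so a per-`n` null mean is computed once (200 seeded draws,
fixed internal seed) and subtracted; estimates are clipped at 0.

**Significance threshold.** The MI cutoff is the Bonferroni-corrected
`mi_alpha` quantile of a permutation null over gene pairs. Where the
corrected quantile outruns the number of permutations the tail is
extrapolated with a generalized Pareto fit to the largest null values.
Inside bootstrap inference the null pairs are *jointly resampled with
replacement* before scoring: bootstrap resampling duplicates whole
samples, and the duplicated points inflate kernel MI even for
independent profiles, so a threshold calibrated on non-resampled
shuffles is far too permissive for bootstrap networks.

**DPI pruning.** For every triangle in the thresholded graph the
minimum-MI edge is marked for removal when strictly below
`(1 − tolerance)` times the second-smallest; all marks are evaluated on
the input graph (mark-and-sweep), so pruning is order-independent and
idempotent. Because a TF-star graph has no triangles, single-network
inference also scores the gene pairs adjacent to a common TF (the
"second ring"); those edges serve as DPI evidence but only TF-incident
edges are reported.

**Bootstrap consensus.** `bootstraps` (default 100) resampled networks
are inferred; an edge's support count is tested against an exact
Poisson-binomial null with per-bootstrap inclusion probability
`q_b = (edges in bootstrap b) / (possible TF–gene pairs)` — the analytic
limit of shuffled-network support nulls, which resolves the default
`consensus_alpha = 1e-7` exactly where an empirical shuffle null cannot.
Edge signs come from Spearman correlation on the full matrix; *activated
targets* are positively-signed consensus targets, and a TF qualifies
with at least `min_targets` (default 30) of them.

**Co-expression alternatives.** `coexpression_targets` (Spearman,
Bonferroni-corrected at `coexpr_alpha = 1e-4`) and `coexpression_star`
(top-n by p-value) are provided as baselines for the same interface.

## 2. Promoters and masking

Promoters are the window [−1000, +500) around the 5′-most annotated
TSS, reverse-complemented for minus-strand genes. Overlapping windows
are eliminated deterministically (lexicographically earlier gene id
wins). Repeat and coding-exon BED intervals are mapped into
promoter-local coordinates and unioned into the mask ("MCR" stage). The
background set is `n_background` random non-target promoters processed
identically to the foreground at every later stage — identical
processing is what makes foreground/background classification
statistics comparable.

Masks are hard exclusions: a motif window overlapping even one masked
base is never scored, which prevents chimeric sites assembled across
mask boundaries.

## 3. Conservation

**Coverage calibration.** Rather than fixing a score threshold,
`threshold_for_coverage` maps a requested retained-DNA fraction
(default `coverage_fraction = 0.10`) to the smallest attained score
whose retained fraction does not exceed the request (closest from
below). This makes the alignment-based and pattern-based masks directly
comparable: both retain (approximately) the same amount of DNA.

**Alignment-based mask.** Bases scoring below the calibrated threshold
on the per-base conservation track are masked.

**Pattern-based mask.** Every fully-specified 8-base window of the
reference promoter is a seed pattern. A species supports a seed when
any of its unmasked 8-base windows matches the seed exactly on either
strand (the reference trivially supports its own seeds). Exact
occurrence matching is essential: allowing even 2 mismatches makes a
chance hit near-certain in promoter-length sequence (the Hamming-≤2
neighborhood of an 8-mer contains 277 words), saturating support for
every seed and destroying the statistic. Patterns supported by fewer
than `min_pattern_species` (default 4) species are dropped; the rest
are ranked by a z-score of observed support against a per-species
3rd-order Markov background (per-species hit probability
`q_s = 1 − (1 − p)^{W_s}`, Poisson-binomial mean and variance).
Top-z patterns are consumed greedily until the coverage budget is
reached; everything they do not cover is masked.

**Combined-conservation set.** The union of the conserved (unmasked)
regions of the two masks. The pattern mask is what keeps relocated
binding sites: under complete binding-site turnover (site neighborhoods
shuffled in order between species) an alignment-style track misses the
sites entirely, while exact-recurrence patterns recover them.

## 4. Motif evaluation

A PWM is scanned over both strands of every unmasked window; each
sequence's score is its best site. The motif's quality is
`err = (FPR + FNR)/2` minimized over all attained score cutoffs
(sequence positive iff score ≥ cutoff; ties break toward the largest
cutoff; `err ≤ 0.5` always, since the all-negative cutoff attains 0.5).
The log-odds background is the background set's base composition at the
same processing stage.

**Library p-values.** The foreground/background labels are permuted
`library_permutations` (default 10,000) times; the null statistic is
the per-permutation minimum err over the whole library, which controls
library-wide selection. P-values use the add-one estimator, hence are
in (0, 1] and conservative under ties.

**De novo p-values.** Full discovery is re-run on
`denovo_permutations` (default 100) random foreground/background
reassignments; the best err per permutation forms the null.

**Calibration note.** Add-one permutation p-values are conservative
when the observed err ties null errs exactly. err over two groups lives
on the grid `a/(2 n_fg) + b/(2 n_bg)`, so *balanced* group sizes make
ties common and the realized type-I error can fall well below nominal.
Calibration benchmarks therefore use coprime-ish unbalanced sizes;
users testing small balanced designs should expect conservative
p-values, not anti-conservative ones.

**Motif comparison.** Divergence between two PWMs is the minimum over
relative offsets (≥ 4 aligned columns) and orientations of the mean
per-column symmetrized Kullback–Leibler divergence in bits; two motifs
match at ≤ 1.0 bit. Merging visits motifs in err order and absorbs
every later motif within the cutoff, keeping each cluster's best
member.

## 5. De novo discovery

For each length in `motif_lengths` (default 6, 8, 10):

1. **Word seeding.** All unmasked words are counted in foreground and
   background; the top `seed_words` (default 500) by a Poisson
   log-likelihood ratio of the foreground count against the
   background-rate expectation seed the search. (A raw rate ratio
   floods the top ranks with words seen once in the foreground and
   never in the background; the likelihood form weighs evidence.)
2. **Coarse search.** Seed words become PWMs over a discretized column
   lattice (4 point-mass columns, 6 two-base mixtures, uniform). For
   the default lattice, a point-mass-column PWM's window score is
   affine in the match count with a strand-shared background term, so
   the exact err of *every* seed word is computed from match counts via
   one one-hot matrix product per strand. The best `beam_width`
   (default 50) candidates survive.
3. **Refinement.** Coordinate ascent over (column, lattice vector)
   substitutions, accepting any strict err improvement, up to
   `refine_max_iter` passes. All candidate substitutions of a column
   are evaluated in one vectorized pass.

Candidates from all lengths are pooled, similar motifs merged (1.0-bit
cutoff), and survivors ranked by err. In the pipeline, discovery runs
independently on the conservation-free and combined-conservation sets
and `rerank_across_sets` merges the two rankings, each motif keeping
its minimum err and a source label.

Scores inside the coarse/refine search accumulate in float32; exact
score ties can split at ~1e-6 relative to float64 evaluation. This is
tie-sensitivity of the search heuristic only — reported errs are always
recomputed self-consistently.

## 6. Synthetic benchmark generators

All generators are pure functions of a spec and a seed, and ground
truth is recorded exactly.

- **Expression**: TF profiles i.i.d. normal; direct targets are linear
  in the TF plus noise; cascade distal genes depend on the TF only
  through a mediator (so DPI should prune TF→distal edges); all other
  genes are independent noise.
- **Promoters**: 3rd-order Markov background (matching the conservation
  null's order) with one site sampled from the planted PWM inserted at
  a uniform position/strand in `site_frequency` of foreground
  sequences.
- **Orthologs**: planted-site neighborhoods become conserved islands
  copied across species with a low substitution rate; spacers are
  regenerated per species; with probability `turnover_rate` a species
  receives the islands in permuted order (content preserved, linear
  alignability destroyed). The emitted conservation track scores
  islands high only when most species kept the original order,
  emulating the blindness of alignment-based conservation to turnover.
- **Planted PWM**: 10 columns, ~13 bits. The strength is chosen from
  first principles: a motif's own err on 1500 bp promoters must be well
  below 0.5 for "recovery" to be meaningful, and ~13 bits corresponds
  to roughly one random hit per 8 kb — detectable but not trivial.
- **Bundle writer**: `write_synthetic_bundle` writes every file the
  pipeline reads (FASTA, BED, bedGraph, TSV, TRANSFAC), so end-to-end
  runs exercise the real I/O paths.

## 7. Benchmark problem sizes

The acceptance-style benchmarks in `tests/test_acceptance.py` use:
planted-motif recovery on 30 foreground / 200 background 1500 bp
promoters at site frequency 0.9 (10 seeds); the turnover benchmark on
20 foreground / 100 background at turnover rate 1 with both sets
conservation-processed identically; permutation calibration on 200 null
replicates with unbalanced groups (17/29 library at 199 permutations,
11/19 de novo at 39 permutations with a reduced single-length search);
network recovery on 35 direct targets and 10 cascades over 254 samples
and 100 bootstraps; coverage calibration on 50 random tracks. Each size
is the smallest at which the stage under test operates in its intended
regime (e.g. conservation-free discovery still functional in the
turnover benchmark, so the combined-set comparison is against a working
baseline).

## 8. Limitations

- MI inference assumes monotone TF–target relationships for sign
  assignment; non-monotone regulation gets sign 0 and is excluded from
  activated targets.
- The pattern-conservation null is a homogeneous 3rd-order Markov
  model; strongly heterogeneous promoter composition (CpG islands) will
  miscalibrate pattern z-scores.
- Conservation inputs are promoter-local: the bedGraph is keyed by gene
  id over promoter coordinates, and orthologs are provided per gene.
  Genome-coordinate conservation tracks must be lifted to promoters
  upstream.
- De novo search is a heuristic (beam + coordinate ascent); it offers
  no global-optimality guarantee, and float32 scoring can split exact
  ties.
- `err` weighs false positives and false negatives equally and ignores
  multiple sites per sequence.
- The synthetic expression generator is linear-Gaussian; it does not
  attempt to mimic real expression covariance beyond the planted
  structure.
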