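# Methods

## The problem and the model

A mouse's CD4 TCRβ repertoire is summarized as a table of unique CDR3β
amino-acid sequences with read counts. Because antigen-expanded clones are
almost entirely private to each animal, classification of immunization
status cannot rely on shared sequences; instead each repertoire (or a
random subsample of it) is mapped to the 20^p-dimensional vector of
term frequencies of its length-p substrings (p = 3 by default, 8,000
features), and a linear classifier with a 1-norm soft margin is trained on
labelled repertoires.

### The boosting LP

With H the m×n weak-learner matrix (rows: samples, columns: signed p-mer
features), y ∈ {−1,+1}^m, and D > 1/m the per-sample penalty cap:

primal  max ρ − D Σξ_i  s.t. y_i(H_i a) + ξ_i ≥ ρ, Σa_j = 1, a ≥ 0, ξ ≥ 0
dual    min β           s.t. Σ_i u_i y_i H_ij ≤ β, Σu_i = 1, 0 ≤ u_i ≤ D

Strong duality gives β* = ρ* − D Σξ*; the package asserts this certificate
(|ρ − DΣξ − β| ≤ 1e-5) at every converged solve.

**Column generation.** The restricted master is solved in dual form (m+1
variables, one constraint per admitted column) with HiGHS via
`scipy.optimize.linprog`. The primal weights a are the constraint
marginals; (ρ, ξ) follow in closed form: ρ is the ⌈1/D⌉-th smallest margin
y_i(H_i a) and ξ_i = max(0, ρ − margin_i). Each iteration admits the single
column maximizing Σ_i u_i y_i H_ij (ties broken by p-mer rank, + before −)
and stops when no column exceeds β + 1e-6 — at that point the restricted
optimum is the global optimum, which the test suite verifies against a
direct dense solve of the full signed dictionary on small instances. Note
the restricted objective β climbs monotonically toward the optimum (each
admitted column is a new dual constraint); it does not decrease.

**Signed dictionary.** Every p-mer contributes a (+) and a (−) column
(outputs ±its term frequency), so the nonnegative weight vector expresses
negative effective coefficients a(+) − a(−); motifs with negative effective
coefficients predict the −1 class.

**Penalty D.** D is expressed through the soft-margin fraction ν as
D = 1/(ν·m), clipped into (1/m, 1] (the dual is infeasible at D ≤ 1/m).
Default ν = 0.8. The training rows are 99 subsamples per mouse, which are
strongly correlated — the effective sample count is the number of mice —
so a large tolerated margin-error fraction is the appropriate regime: small
ν (absolute D of order 0.1 at m ≈ 10^3) behaves like a hard margin, fits
subsample noise, and needs hundreds of columns, while ν = 0.8 converges in
tens of iterations to solutions with a few dozen active features at most.
An absolute-D grid remains available in `select_D`, which implements the
disjoint-split protocol: each mouse's sequences are split at random into
two halves sharing no sequences, the grid is scored by leave-one-out on
half 1, and the winner is applied to half 2.

**Decision threshold.** The printed LP has no bias term. Scores are
thresholded at θ = midpoint of the class-wise mean training scores
(deterministic, symmetric; ties go to +1). A zero threshold was evaluated
and is markedly worse calibrated under label permutation.

### Leave-one-out protocol

Each repertoire contributes 99 subsamples of 1,000 unique sequences
(uniform, without replacement; counts are deliberately ignored — the
singlet analyses are count-free). For each fold the held-out mouse's class
is the majority over its 99 subsample predictions (odd count: no ties).
Accuracy is summarized with a Clopper–Pearson 95% interval and a two-sided
Fisher exact test on the true×predicted table.

**Class balancing.** Leaving one mouse out makes the training classes
unequal (e.g. 5 vs 6 mice). Under a pure-noise fit the background score of
an unseen repertoire tilts toward the larger class — always the wrong one
for the held-out mouse — and the majority vote amplifies this into strong
anti-learning (permuted-label accuracy far below chance). Per fold the
larger class is therefore subsampled to the same number of mice (a seeded
random drop) and any residual row-count difference is trimmed evenly
across mice. With both balances in place, permuted-label runs sit at
chance; row trimming alone leaves a measurable deficit because five
distinct mice against six is itself asymmetric.

**Filters.** `all` (default), `top5` (top 5% of clones by count; the
filtered set is so small that a single whole-set sample replaces the 99
subsamples) and `singlets` (clones with count 1). If a filter leaves fewer
sequences than the subsample size, the size is reduced for that mouse and
logged.

**Two-stage variant.** LPBoost's active p-mers are passed to an SVM
(`sklearn.svm.SVC`, linear kernel by default) as a second-stage maximum
margin classifier; if no features were selected the fold falls back to the
training-majority class.

### Expansion index

EI(s, r) = log2(cpm_r(s) / b(s)), with b(s) the mean cpm over unimmunized
baselines, zeros included for baseline mice lacking s; b(s) is replaced by
the 1-cpm pseudo-abundance only when s is absent from every baseline.
Means are taken over cpm (not raw counts) because sequencing depths
differ. Both selection thresholds are strict (> 6, < 4), EI > 6
corresponding to at least six doublings; a clone absent from a repertoire
fails "> hi" there and satisfies "< lo" there.

## Synthetic cohorts

`SyntheticConfig` defaults describe the emulated study: 6+6 labelled mice,
10^4 unique clones and 10^5 reads per mouse drawn from a 2×10^5-sequence
universe of CDR3-like strings ("CAS" + random core + "F", lengths 10–17).
Generation probabilities follow a power law with density exponent 2.5
(rank-frequency slope −1/(α−1) ≈ −0.67, in the range reported for murine
repertoires); counts are 1 + multinomial over the selected clones, which
preserves the heavy tail while guaranteeing presence. The 100
top-probability clones are public (forced into every mouse, including
unimmunized baselines). Each immunized mouse receives 200 private expanded
clones drawn from the universe and forced present with counts multiplied
by the expansion factor (default 16; 64 = six doublings in the strong
benchmark, making the factor interpretable against the EI > 6 threshold).

Class signal: a `carrier_fraction` (default 1%) of the universe carries
each configured signal motif, implanted at a start position
rejection-sampled inside the motif's 10-bin relative position; class +1
mice bias their expanded picks by the motif enrichment factor. The bias
operates at the level of which clones are *present*, not only their
counts, because the downstream subsampling is count-free. With no motifs
and enrichment 1 the two classes are exchangeable by construction, which
is what the permuted-label calibration relies on.

The benchmark `strong_signal_config` (enrichment 50, expansion factor 64,
motifs WGN at bin 3 and FGS at bin 7, carrier fraction 2%) is desk-scaled
to 2,000 clones/mouse so a full recovery experiment runs in seconds.
Benchmark motifs must not overlap the conserved flanks: a motif like ASG
is created by every core starting with G after the CAS prefix, inflating
its background ~30-fold and drowning the implant.

What the generator does **not** emulate: VDJ recombination statistics and
germline-templated sequence correlations, sequencing error, PCR bias,
count overdispersion beyond multinomial, V/J–CDR3 dependence (V/J labels
are drawn independently of sequence), and cross-timepoint structure.
Passing tests therefore demonstrate correctness and power of the
*algorithms* under the assumed statistical structure, not performance on
real sequencing data.

## Numerical choices

- LP solver: HiGHS; marginals clipped at 0 and renormalized (Σa = 1).
- Convergence: dual violation ≤ 1e-6; max 500 iterations; a duplicate
  most-violated column (numerical stall) terminates with the certificate
  holding to solver precision.
- Active features: weights > 1e-9; per-solve count obeys the basic-solution
  bound ≤ m+2.
- Edit distance: textbook two-row DP; `edlib` used as an accelerated
  backend when installed, and as an independent oracle in tests.
- Positional bins: floor(10·s/L)+1 for 0-based start s in length L,
  clamped to bin 10; note starts > L−3 are impossible, so the last bin is
  structurally depleted for short sequences.
- Top-fraction filter keeps ⌈fraction·n⌉ clones, ties at the cutoff broken
  lexicographically.
- Subsampling, universe generation and permutations derive all randomness
  from numpy Generators seeded via SeedSequence tuples; identical seeds
  reproduce cohorts, models and accuracies exactly.

## Problem sizes used in the shipped analyses

The permuted-label control runs the full protocol (6+6 mice at the default
10^4-clone scale, 99×1,000 subsamples, 20 permutations, ~4 minutes on one
CPU); the recovery benchmark runs 10 cohorts at the 2,000-clone benchmark
scale with the same subsample protocol (~1 minute). Oracle comparisons use
≥ 20 random instances with m ≤ 12 and n ≤ 400.

## Known limitations

- The sparsity of 1-norm solutions means strongly correlated informative
  motifs may not all be selected in every fold; selection proportions
  across folds (not single models) are the supported readout.
- The expansion index has no uncertainty quantification; it is a selection
  statistic, not a test.
- `select_D` is expensive (a full LOO per grid value) and intended for
  final analyses, not routine runs.
- Anti-learning under leave-one-out is controlled by row balancing for the
  two-class design; designs with more than two classes are out of scope.
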