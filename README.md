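# cdr3boost

Analysis of CD4 T-cell receptor β-chain (TCRβ) CDR3 repertoires from
immunized mice: repertoire sharing, selection of antigen-associated clones
by a clonal expansion index, and classification of immunization status from
short amino-acid motif frequencies with a sparse 1-norm boosting
classifier.

High-throughput TCR sequencing shows that two genetically identical mice
immunized with the same antigen expand almost entirely different ("private")
sets of CDR3β sequences, so no shared clone list can tell an
antigen-plus-adjuvant repertoire from an adjuvant-only one. This package
implements the complementary strategy: look for *sequence features* —
length-p substrings (p-mers, typically amino-acid triplets) — whose
frequencies are reshaped by the antigen-specific response, and train a
classifier that selects a small, interpretable set of them.

## What it computes

**Sharing and similarity.** Jaccard index between repertoires (over unique
sequences), Levenshtein edit distance, and the p-spectrum kernel
k_p(s,t) = Σ_u c_s(u)·c_t(u) over length-p substrings u, with null
distributions from random same-size CDR3 sets.

**Expansion index.** For clone s in repertoire r with baselines B
(unimmunized mice),

    EI(s, r) = log2( cpm_r(s) / mean_{b∈B} cpm_b(s) ),

where a baseline mouse lacking s contributes 0 to the mean and a clone
absent from *all* baselines uses a pseudo-abundance of 1 cpm. Clones with
EI > 6 (≥ six doublings) in at least one antigen-class repertoire and
EI < 4 in every control repertoire are called antigen-associated.

**LPBoost.** With H the m×n matrix of signed p-mer term frequencies over
repertoire subsamples and y_i ∈ {−1,+1} the labels:

    max_{a,ξ,ρ}  ρ − D Σ_i ξ_i        s.t. y_i(H_i a) + ξ_i ≥ ρ,
                                           Σ_j a_j = 1, a ≥ 0, ξ ≥ 0

solved via its dual (min β s.t. Σ_i u_i y_i H_ij ≤ β, Σu = 1, 0 ≤ u ≤ D)
by column generation: repeatedly add the feature maximizing Σ_i u_i y_i H_ij
until no feature violates the dual constraint. The optimum is provably
global and typically uses only tens of non-zero features. Each p-mer
contributes a (+) and a (−) column, so the nonnegative weights express
negative effective coefficients a(+) − a(−).

**Evaluation.** Leave-one-mouse-out with a majority vote over 99 random
1,000-sequence subsamples per repertoire; optional second-stage SVM on the
selected features; randomized-label controls; Fisher exact test and
Clopper–Pearson intervals. Selected motifs are summarized by their
selection proportion across folds, their position along the CDR3 (10
relative-length bins) and their per-10⁴-CDR3 frequency per class.

**Synthetic cohorts.** `cdr3boost.simulate` generates labelled cohorts with
the structure the analysis assumes — power-law clone sizes, public clones,
private expanded clones, and class-specific motif enrichment — with full
ground truth, so every stage is testable without sequencing data.

## Worked example

```python
from cdr3boost import (
    generate_cohort, strong_signal_config, loo_classify, selection_summary,
)

cfg = strong_signal_config(seed=11)       # implants WGN (bin 3) and FGS (bin 7)
cohort, truth = generate_cohort(cfg)
result, models = loo_classify(cohort, seed=3, collect_models=True)
print(f"accuracy {result.n_correct}/{result.n_total}, "
      f"CI {result.ci95[0]:.2f}-{result.ci95[1]:.2f}, Fisher p={result.fisher_p:.2g}")
summary = selection_summary(models, threshold=0.5)
for pmer in summary.reported[:4]:
    print(pmer, summary.signs[pmer], round(summary.proportions[pmer], 2))
```

prints

```
accuracy 11/12, CI 0.62-1.00, Fisher p=0.015
ASF -1 1.0
FGS 1 1.0
WGN 1 1.0
CAS -1 0.83
```

Eleven of twelve mice are classified correctly (the Fisher p is for the
2×2 true-vs-predicted table). Both implanted motifs are selected in every
leave-one-out fold with positive coefficients (a higher frequency predicts
the antigen class); the negatively signed features (ASF, CAS) are
background p-mers whose relative frequency is depressed by the motif
enrichment and which therefore predict the control class.

A thin CLI mirrors the library: `cdr3boost sim`, `cdr3boost jaccard`,
`cdr3boost expansion`, `cdr3boost evaluate` (see `--help`).

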