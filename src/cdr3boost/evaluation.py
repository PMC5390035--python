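"""Leave-one-mouse-out classification with subsample majority voting.

Each repertoire is represented by ``n_samples`` (default 99) random
fixed-size subsamples of its unique CDR3s, featurized as normalized p-mer
term frequencies. Training uses the subsamples of all other mice as rows
(so the LP's m is (mice-1) * n_samples); the held-out mouse's class is the
majority label over its own subsamples — odd n_samples cannot tie.

Also provides the two-stage variant (LPBoost feature selection followed by
a maximum-margin classifier on the selected p-mers), randomized-label
controls, the exact Fisher test / Clopper-Pearson interval used to
summarize accuracy, and a V/J-gene usage comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import lpboost
from .features import sequence_feature_matrix
from .repertoires import Cohort, Repertoire, filter_singlets, filter_top_fraction

logger = logging.getLogger(__name__)

DEFAULT_N_SAMPLES = 99
DEFAULT_SAMPLE_SIZE = 1000


@dataclass
class LooResult:
    """Outcome of one leave-one-mouse-out run."""

    per_mouse: dict[str, tuple[int, int, int, int]]  # true, pred, votes+, votes-
    n_correct: int
    n_total: int
    accuracy: float
    ci95: tuple[float, float]
    fisher_p: float
    table: np.ndarray  # 2x2, rows true (+1,-1) x cols predicted (+1,-1)


@dataclass
class SelectDResult:
    """Outcome of the disjoint-split penalty-selection protocol."""

    best_D: float
    half1: Cohort
    half2: Cohort
    accuracies: dict[float, float]


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric tails)."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer entries")
    if table.sum() == 0:
        raise ValueError("Fisher exact test undefined for an all-zero table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n."""
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=1 - alpha, method="exact")
    return (float(ci.low), float(ci.high))


def _eligible_sequences(rep: Repertoire, filter: str) -> list[str]:
    if filter == "all":
        return rep.sequences()
    if filter == "top5":
        return filter_top_fraction(rep, 0.05).sequences()
    if filter == "singlets":
        return filter_singlets(rep).sequences()
    raise ValueError(f"unknown filter {filter!r}")


def _prepare_blocks(
    cohort: Cohort,
    p: int,
    n_samples: int,
    sample_size: int,
    filter: str,
    seed: int,
) -> tuple[list[np.ndarray], list[str], np.ndarray]:
    """Per-mouse feature blocks (n_samples x 20**p, row-normalized).

    The top-5% filter restricts the analysis to so few sequences that only
    a single sample per repertoire is taken: the whole filtered set.
    """
    if filter == "top5" and n_samples != 1:
        logger.info("top5 filter: forcing a single whole-set sample per repertoire")
        n_samples = 1
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    blocks, ids, labels = [], [], []
    for rep in cohort.labelled():
        seqs = _eligible_sequences(rep, filter)
        if not seqs:
            raise ValueError(f"filter {filter!r} leaves mouse {rep.mouse_id} empty")
        X = sequence_feature_matrix(seqs, p)
        if filter == "top5":
            sample_idx = [np.arange(len(seqs))]
        else:
            size = sample_size
            if size > len(seqs):
                logger.warning(
                    "mouse %s: only %d eligible sequences; reducing sample_size from %d",
                    rep.mouse_id, len(seqs), sample_size,
                )
                size = len(seqs)
            sample_idx = [
                rng.choice(len(seqs), size=size, replace=False)
                for _ in range(n_samples)
            ]
        block = np.stack([np.asarray(X[idx].sum(axis=0)).ravel() for idx in sample_idx])
        totals = block.sum(axis=1, keepdims=True)
        np.divide(block, totals, out=block, where=totals > 0)
        blocks.append(block)
        ids.append(rep.mouse_id)
        labels.append(rep.label)
    return blocks, ids, np.asarray(labels, dtype=int)


def _majority(preds: np.ndarray) -> tuple[int, int, int]:
    votes_pos = int((preds == 1).sum())
    votes_neg = int((preds == -1).sum())
    if votes_pos == votes_neg:
        logger.info("tied majority vote; resolving to +1")
        return +1, votes_pos, votes_neg
    return (+1 if votes_pos > votes_neg else -1), votes_pos, votes_neg


def _train_predict(
    train_F: np.ndarray,
    train_y: np.ndarray,
    test_F: np.ndarray,
    algo: str,
    D: float | None,
    nu: float,
    svm_C: float,
    svm_kernel: str,
    p: int,
    max_iter: int,
) -> tuple[np.ndarray, lpboost.LPBoostModel]:
    model = lpboost.lpboost_train(
        train_F, train_y, D=D, nu=nu, p=p, max_iter=max_iter
    )
    if algo == "lpboost":
        return lpboost.predict(model, test_F), model
    if algo != "lpboost_svm":
        raise ValueError(f"unknown algo {algo!r}")
    selected = sorted({j for (j, _s), w in zip(model.columns, model.a) if w > 1e-9})
    if not selected:
        majority = +1 if (train_y == 1).sum() >= (train_y == -1).sum() else -1
        logger.warning("stage 1 selected no features; predicting training majority")
        return np.full(test_F.shape[0], majority, dtype=int), model
    from sklearn.svm import SVC

    clf = SVC(C=svm_C, kernel=svm_kernel)
    clf.fit(train_F[:, selected], train_y)
    return clf.predict(test_F[:, selected]).astype(int), model


def _balanced_training_rows(
    blocks: list[np.ndarray],
    labels: np.ndarray,
    hold: int,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Training rows with equal numbers of mice and rows per class.

    Leaving one mouse out makes the training classes unequal (e.g. 5 vs 6
    mice). Under a pure-noise fit that asymmetry tilts the background score
    of an unseen repertoire toward the larger class — which is always the
    wrong one for the held-out mouse — and the majority vote amplifies the
    tilt into anti-learning. The larger class is therefore subsampled to
    the same number of mice (drop chosen by ``rng``, deterministic given
    the evaluation seed), and any residual row-count difference is trimmed
    evenly across mice.
    """
    idx_pos = [i for i in range(len(blocks)) if i != hold and labels[i] == 1]
    idx_neg = [i for i in range(len(blocks)) if i != hold and labels[i] == -1]

    n_keep = min(len(idx_pos), len(idx_neg))
    if rng is None:
        rng = np.random.default_rng(0)
    idx_pos = sorted(rng.choice(idx_pos, size=n_keep, replace=False))
    idx_neg = sorted(rng.choice(idx_neg, size=n_keep, replace=False))

    total_pos = sum(len(blocks[i]) for i in idx_pos)
    total_neg = sum(len(blocks[i]) for i in idx_neg)
    target = min(total_pos, total_neg)

    def take(indices: list[int], total: int) -> list[np.ndarray]:
        if total <= target:
            return [blocks[i] for i in indices]
        base, extra = divmod(target, len(indices))
        return [
            blocks[i][: base + (1 if k < extra else 0)]
            for k, i in enumerate(indices)
        ]

    parts = [(i, b) for i, b in zip(idx_pos, take(idx_pos, total_pos))]
    parts += [(i, b) for i, b in zip(idx_neg, take(idx_neg, total_neg))]
    train_F = np.concatenate([b for _, b in parts])
    train_y = np.concatenate([np.full(len(b), labels[i]) for i, b in parts])
    return train_F, train_y


def _loo_from_blocks(
    blocks: list[np.ndarray],
    ids: list[str],
    labels: np.ndarray,
    algo: str,
    D: float | None,
    nu: float,
    svm_C: float,
    svm_kernel: str,
    p: int,
    max_iter: int,
    collect_models: bool = False,
    seed: int = 0,
) -> tuple[LooResult, list[lpboost.LPBoostModel]]:
    n_mice = len(blocks)
    per_mouse = {}
    models = []
    table = np.zeros((2, 2), dtype=int)
    n_correct = 0
    for hold in range(n_mice):
        fold_rng = np.random.default_rng(np.random.SeedSequence((seed, 37, hold)))
        train_F, train_y = _balanced_training_rows(blocks, labels, hold, fold_rng)
        preds, model = _train_predict(
            train_F, train_y, blocks[hold], algo, D, nu, svm_C, svm_kernel, p, max_iter
        )
        if collect_models:
            models.append(model)
        pred, votes_pos, votes_neg = _majority(preds)
        true = int(labels[hold])
        per_mouse[ids[hold]] = (true, pred, votes_pos, votes_neg)
        n_correct += int(pred == true)
        table[0 if true == 1 else 1, 0 if pred == 1 else 1] += 1
    n_total = n_mice
    accuracy = n_correct / n_total
    result = LooResult(
        per_mouse=per_mouse,
        n_correct=n_correct,
        n_total=n_total,
        accuracy=accuracy,
        ci95=clopper_pearson(n_correct, n_total),
        fisher_p=fisher_exact_2x2(table) if table.sum() else 1.0,
        table=table,
    )
    return result, models


def loo_classify(
    cohort: Cohort,
    p: int = 3,
    algo: str = "lpboost",
    D: float | None = None,
    nu: float = lpboost.DEFAULT_NU,
    n_samples: int = DEFAULT_N_SAMPLES,
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    filter: str = "all",
    seed: int = 0,
    svm_C: float = 1.0,
    svm_kernel: str = "linear",
    max_iter: int = lpboost.DEFAULT_MAX_ITER,
    collect_models: bool = False,
) -> LooResult | tuple[LooResult, list[lpboost.LPBoostModel]]:
    """Leave-one-mouse-out majority-vote classification.

    ``algo`` is "lpboost" or "lpboost_svm" (two-stage). ``filter`` is
    applied to each repertoire before subsampling: "all", "top5" (top 5% by
    count; forces a single whole-set sample) or "singlets" (count == 1
    clones only). With ``collect_models`` the per-fold stage-1 models are
    returned as well (for motif selection summaries).
    """
    if len(cohort.by_class(+1)) < 2 or len(cohort.by_class(-1)) < 2:
        raise ValueError("need at least 2 mice per class for leave-one-out")
    blocks, ids, labels = _prepare_blocks(cohort, p, n_samples, sample_size, filter, seed)
    result, models = _loo_from_blocks(
        blocks, ids, labels, algo, D, nu, svm_C, svm_kernel, p, max_iter,
        collect_models=collect_models, seed=seed,
    )
    return (result, models) if collect_models else result


def two_stage_classify(cohort: Cohort, **kwargs) -> LooResult:
    """LPBoost feature selection followed by a max-margin classifier."""
    kwargs["algo"] = "lpboost_svm"
    return loo_classify(cohort, **kwargs)


def randomized_label_control(
    cohort: Cohort,
    n_permutations: int = 20,
    seed: int = 0,
    p: int = 3,
    algo: str = "lpboost",
    D: float | None = None,
    nu: float = lpboost.DEFAULT_NU,
    n_samples: int = DEFAULT_N_SAMPLES,
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    filter: str = "all",
    svm_C: float = 1.0,
    svm_kernel: str = "linear",
    max_iter: int = lpboost.DEFAULT_MAX_ITER,
) -> list[float]:
    """LOO accuracy under label permutation (class sizes preserved).

    Features are computed once and reused across permutations; only the
    mouse-to-label assignment is shuffled.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    blocks, ids, labels = _prepare_blocks(cohort, p, n_samples, sample_size, filter, seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 23)))
    accuracies = []
    for k in range(n_permutations):
        perm = rng.permutation(len(labels))
        perm_seed = int(np.random.SeedSequence((seed, 29, k)).generate_state(1)[0])
        result, _ = _loo_from_blocks(
            blocks, ids, labels[perm], algo, D, nu, svm_C, svm_kernel, p, max_iter,
            seed=perm_seed,
        )
        accuracies.append(result.accuracy)
    return accuracies


def vj_usage_compare(
    reps_a: list[Repertoire],
    reps_b: list[Repertoire],
    gene: str = "v_gene",
    n_resamples: int = 50,
    resample_size: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene usage frequencies of two repertoire groups.

    For each group, ``n_resamples`` count-weighted samples of
    ``resample_size`` TCRs are drawn with replacement from the pooled group
    repertoire; the per-gene frequency mean and SD over samples is reported
    for both groups (columns mean_a, sd_a, mean_b, sd_b).
    """
    rng = np.random.default_rng(seed)

    def pool(reps: list[Repertoire]) -> tuple[np.ndarray, np.ndarray]:
        genes, weights, missing = [], [], []
        for rep in reps:
            for c in rep.clones:
                g = getattr(c, gene)
                if g is None:
                    missing.append(rep.mouse_id)
                    break
                genes.append(g)
                weights.append(c.count)
        if missing:
            raise ValueError(f"missing {gene} annotations in mice: {sorted(set(missing))}")
        w = np.asarray(weights, dtype=float)
        return np.asarray(genes, dtype=object), w / w.sum()

    genes_a, w_a = pool(reps_a)
    genes_b, w_b = pool(reps_b)
    all_genes = sorted(set(genes_a) | set(genes_b))
    gene_idx = {g: i for i, g in enumerate(all_genes)}

    def sample_freqs(genes: np.ndarray, w: np.ndarray) -> np.ndarray:
        out = np.zeros((n_resamples, len(all_genes)))
        codes = np.asarray([gene_idx[g] for g in genes])
        for r in range(n_resamples):
            draw = rng.choice(codes, size=resample_size, replace=True, p=w)
            out[r] = np.bincount(draw, minlength=len(all_genes)) / resample_size
        return out

    fa = sample_freqs(genes_a, w_a)
    fb = sample_freqs(genes_b, w_b)
    return pd.DataFrame(
        {
            "gene": all_genes,
            "mean_a": fa.mean(axis=0),
            "sd_a": fa.std(axis=0, ddof=1),
            "mean_b": fb.mean(axis=0),
            "sd_b": fb.std(axis=0, ddof=1),
        }
    )
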