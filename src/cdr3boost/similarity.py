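"""Repertoire sharing and CDR3 sequence similarity.

Sharing between two repertoires is the Jaccard index of their unique
sequence sets. Two CDR3s are compared either by the Levenshtein edit
distance or by the p-spectrum kernel (the inner product of their length-p
substring count vectors). Observed CDR3 sets are benchmarked against null
distributions built from random same-size sets drawn from a pooled
repertoire.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import features
from .repertoires import Cohort, Repertoire

try:  # optional accelerated edit distance
    import edlib as _edlib
except ImportError:  # pragma: no cover
    _edlib = None


def jaccard_index(a: Repertoire | set, b: Repertoire | set) -> float:
    """|A ∩ B| / |A ∪ B| over unique sequence sets; counts are ignored."""
    sa = set(a.sequences()) if isinstance(a, Repertoire) else set(a)
    sb = set(b.sequences()) if isinstance(b, Repertoire) else set(b)
    union = sa | sb
    if not union:
        raise ValueError("Jaccard index undefined for two empty repertoires")
    return len(sa & sb) / len(union)


def _levenshtein_dp(s: str, t: str) -> int:
    """Textbook two-row dynamic programme for the edit distance."""
    if len(s) < len(t):
        s, t = t, s
    prev = list(range(len(t) + 1))
    for i, cs in enumerate(s, start=1):
        cur = [i] + [0] * len(t)
        for j, ct in enumerate(t, start=1):
            cur[j] = min(
                prev[j] + 1,  # deletion
                cur[j - 1] + 1,  # insertion
                prev[j - 1] + (cs != ct),  # substitution
            )
        prev = cur
    return prev[-1]


def levenshtein(s: str, t: str, backend: str = "auto") -> int:
    """Number of single-character edits transforming ``s`` into ``t``.

    ``backend`` is "dp" for the pure dynamic programme, "edlib" for the
    C library, or "auto" (edlib when available).
    """
    if backend == "auto":
        backend = "edlib" if _edlib is not None else "dp"
    if backend == "edlib":
        if _edlib is None:
            raise RuntimeError("edlib backend requested but edlib is not installed")
        return int(_edlib.align(s, t)["editDistance"])
    if backend == "dp":
        return _levenshtein_dp(s, t)
    raise ValueError(f"unknown backend {backend!r}")


def p_spectrum_kernel(s: str, t: str, p: int, distinct: bool = False) -> int:
    """Shared length-p substrings between two CDR3s.

    The default is the canonical p-spectrum kernel: the inner product of the
    two p-mer count vectors, Σ_u count_s(u)·count_t(u). With ``distinct``
    the number of distinct shared p-mers is counted instead. Strings shorter
    than p score 0.
    """
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    cs: dict[str, int] = {}
    for i in range(len(s) - p + 1):
        u = s[i : i + p]
        cs[u] = cs.get(u, 0) + 1
    total = 0
    if distinct:
        seen = set()
        for i in range(len(t) - p + 1):
            u = t[i : i + p]
            if u in cs and u not in seen:
                seen.add(u)
                total += 1
        return total
    ct: dict[str, int] = {}
    for i in range(len(t) - p + 1):
        u = t[i : i + p]
        ct[u] = ct.get(u, 0) + 1
    for u, c in cs.items():
        total += c * ct.get(u, 0)
    return total


def mean_pairwise(
    sequences: list[str],
    metric: str = "levenshtein",
    p: int = 3,
    backend: str = "auto",
) -> float:
    """Mean over all unordered pairs of a distance or similarity.

    ``metric`` is "levenshtein" or "spectrum" (the p-spectrum kernel with
    the given ``p``).
    """
    if len(sequences) < 2:
        raise ValueError("mean_pairwise needs at least 2 sequences")
    if metric == "levenshtein":
        fn = lambda a, b: levenshtein(a, b, backend=backend)  # noqa: E731
    elif metric == "spectrum":
        fn = lambda a, b: p_spectrum_kernel(a, b, p)  # noqa: E731
    else:
        raise ValueError(f"unknown metric {metric!r}")
    total = 0
    n_pairs = 0
    for a, b in combinations(sequences, 2):
        total += fn(a, b)
        n_pairs += 1
    return total / n_pairs


@dataclass
class PairwiseSummary:
    """An observed mean pairwise statistic against a random-set null."""

    observed_mean: float
    null_means: list[float]

    @property
    def n_null(self) -> int:
        return len(self.null_means)

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_means))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_means, ddof=1))


def random_set_null(
    pool: list[str],
    set_size: int,
    n_sets: int = 100,
    metric: str = "levenshtein",
    p: int = 3,
    seed: int | None = None,
    observed: list[str] | None = None,
    backend: str = "auto",
) -> PairwiseSummary:
    """Null distribution of the mean pairwise statistic from random sets.

    Draws ``n_sets`` without-replacement samples of ``set_size`` unique
    sequences from the pooled unique sequences of all mice and records each
    sample's mean pairwise value. When ``observed`` is given, its mean
    pairwise value is stored as ``observed_mean`` (NaN otherwise).
    """
    unique_pool = sorted(set(pool))
    if set_size < 2:
        raise ValueError("set_size must be >= 2")
    if len(unique_pool) < set_size:
        raise ValueError(
            f"pool has only {len(unique_pool)} unique sequences, need {set_size}"
        )
    rng = np.random.default_rng(seed)
    arr = np.asarray(unique_pool, dtype=object)
    null_means = []
    for _ in range(n_sets):
        sample = arr[rng.choice(len(arr), size=set_size, replace=False)]
        null_means.append(mean_pairwise(list(sample), metric=metric, p=p, backend=backend))
    obs = (
        mean_pairwise(observed, metric=metric, p=p, backend=backend)
        if observed is not None
        else float("nan")
    )
    return PairwiseSummary(observed_mean=obs, null_means=null_means)


def pairwise_jaccard_table(cohort: Cohort) -> pd.DataFrame:
    """Jaccard index for every pair of labelled mice, with group annotation.

    Pairs are annotated "within_pos", "within_neg" or "between" so sharing
    inside each immunization group can be compared with sharing across
    groups.
    """
    reps = cohort.labelled()
    rows = []
    for a, b in combinations(reps, 2):
        if a.label == b.label:
            group = "within_pos" if a.label == +1 else "within_neg"
        else:
            group = "between"
        rows.append(
            {
                "mouse_a": a.mouse_id,
                "mouse_b": b.mouse_id,
                "group": group,
                "jaccard": jaccard_index(a, b),
            }
        )
    return pd.DataFrame(rows, columns=["mouse_a", "mouse_b", "group", "jaccard"])


def spectrum_gram_matrix(sequences: list[str], p: int) -> np.ndarray:
    """Gram matrix of the p-spectrum kernel (PSD: it is an inner product)."""
    vecs = [features.featurize([s], p) for s in sequences]
    mat = np.stack(vecs)
    return mat @ mat.T
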