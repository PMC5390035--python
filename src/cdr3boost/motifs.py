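"""Interpretation of the p-mer features selected by the classifier.

Because each train/test cycle (different left-out mouse, different random
subsamples) selects a slightly different sparse feature set, motifs are
summarized by the proportion of cycles in which their effective
coefficient a(+) - a(-) is non-zero; only motifs above a reporting
threshold are kept. Reported motifs are then characterized by where they
sit along the CDR3 (10 relative-position bins) and how often they occur
per 10^4 CDR3s in each class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import PositionProfile, triplet_position_profile
from .lpboost import LPBoostModel
from .repertoires import Repertoire


@dataclass
class MotifSelectionSummary:
    """Selection proportions of p-mer features across models."""

    proportions: dict[str, float]
    signs: dict[str, int]  # median sign of the effective coefficient
    threshold: float

    @property
    def reported(self) -> list[str]:
        """Motifs selected in at least ``threshold`` of the cycles."""
        return sorted(
            (m for m, f in self.proportions.items() if f >= self.threshold),
            key=lambda m: (-self.proportions[m], m),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (m, self.signs[m], self.proportions[m])
            for m in self.reported
        ]
        return pd.DataFrame(rows, columns=["pmer", "sign", "selection_proportion"])


def selection_summary(
    models: list[LPBoostModel], threshold: float = 0.5
) -> MotifSelectionSummary:
    """Fraction of models in which each p-mer has non-zero net weight.

    The sign reported per p-mer is the sign of the median of its non-zero
    effective coefficients; a positive sign means a higher frequency of the
    motif favours the +1 class.
    """
    if not models:
        raise ValueError("at least one model is required")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    coefs: dict[str, list[float]] = {}
    for model in models:
        for pmer, c in model.effective_coefficients().items():
            coefs.setdefault(pmer, []).append(c)
    n = len(models)
    proportions = {pmer: len(vals) / n for pmer, vals in coefs.items()}
    signs = {pmer: int(np.sign(np.median(vals))) for pmer, vals in coefs.items()}
    return MotifSelectionSummary(proportions=proportions, signs=signs, threshold=threshold)


def triplet_frequency_per_1e4(rep: Repertoire | list[str], triplet: str) -> float:
    """Unique CDR3s containing the triplet, per 10^4 unique CDR3s."""
    seqs = rep.sequences() if isinstance(rep, Repertoire) else list(rep)
    if not seqs:
        raise ValueError("repertoire is empty")
    hits = sum(1 for s in seqs if triplet in s)
    return hits * 1e4 / len(seqs)


def positional_report(
    summary: MotifSelectionSummary,
    cdr3_pool: list[str],
    pool_size: int = 1_000_000,
    seed: int = 0,
    n_bins: int = 10,
) -> dict[str, PositionProfile]:
    """Positional profile of each reported motif in a random CDR3 sample.

    The pool is sampled to ``pool_size`` with replacement if necessary;
    each profile gives the per-bin start frequency and its black/gray/white
    band (>= 10% / >= 1% / below).
    """
    if not cdr3_pool:
        raise ValueError("cdr3_pool is empty")
    rng = np.random.default_rng(seed)
    arr = np.asarray(cdr3_pool, dtype=object)
    if len(arr) > pool_size:
        sample = list(arr[rng.choice(len(arr), size=pool_size, replace=False)])
    elif len(arr) < pool_size:
        sample = list(arr[rng.choice(len(arr), size=pool_size, replace=True)])
    else:
        sample = list(arr)
    return {
        motif: triplet_position_profile(motif, sample, n_bins=n_bins)
        for motif in summary.reported
    }


def positional_report_frame(profiles: dict[str, PositionProfile]) -> pd.DataFrame:
    """Tabular form of positional profiles: bins then bands per motif."""
    rows = []
    for motif, prof in profiles.items():
        row: dict[str, object] = {"pmer": motif}
        for b in range(len(prof.bins)):
            row[f"bin{b + 1}"] = prof.bins[b]
        for b in range(len(prof.bins)):
            row[f"band{b + 1}"] = prof.bands[b]
        rows.append(row)
    return pd.DataFrame(rows)
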