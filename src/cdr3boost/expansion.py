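"""Expansion-index statistic and selection of antigen-associated clones.

The expansion index of a clone in an immunized repertoire is
log2(cpm in that repertoire / mean cpm across unimmunized baselines), where
a baseline mouse lacking the clone contributes 0 to the mean and a clone
absent from *all* baselines uses a pseudo-abundance of 1 per 10^6 (1 cpm).
A threshold of 6 corresponds to a minimum of six doubling divisions.

Antigen-associated clones are those with expansion index above a high
threshold in at least one repertoire of the focal class and below a low
threshold in every repertoire of the other class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .repertoires import Cohort, Repertoire, to_cpm

DEFAULT_HI = 6.0
DEFAULT_LO = 4.0
#: Pseudo-abundance (cpm) for clones absent from all unimmunized baselines.
PSEUDO_ABUNDANCE_CPM = 1.0


def _baseline_mean_cpm(
    sequences: set[str],
    baselines: list[Repertoire],
    pseudo_cpm: float,
) -> dict[str, float]:
    """Mean baseline cpm per sequence; absent-everywhere -> pseudo count."""
    if not baselines:
        raise ValueError("at least one unimmunized baseline repertoire is required")
    totals = dict.fromkeys(sequences, 0.0)
    for rep in baselines:
        cpm = to_cpm(rep)
        for seq in sequences:
            totals[seq] += cpm.get(seq, 0.0)
    n = len(baselines)
    return {seq: (tot / n if tot > 0 else pseudo_cpm) for seq, tot in totals.items()}


def expansion_index(
    seq: str,
    rep: Repertoire,
    baselines: list[Repertoire],
    pseudo_cpm: float = PSEUDO_ABUNDANCE_CPM,
) -> float:
    """log2 ratio of a clone's cpm to its mean cpm in unimmunized mice."""
    cpm = to_cpm(rep)
    if seq not in cpm:
        raise ValueError(f"sequence {seq!r} not present in repertoire {rep.mouse_id}")
    baseline = _baseline_mean_cpm({seq}, baselines, pseudo_cpm)[seq]
    return float(np.log2(cpm[seq] / baseline))


def expansion_table(
    cohort: Cohort | list[Repertoire],
    baselines: list[Repertoire],
    pseudo_cpm: float = PSEUDO_ABUNDANCE_CPM,
) -> pd.DataFrame:
    """Expansion index of every (sequence, mouse) pair in labelled repertoires.

    Columns: sequence, mouse_id, label, cpm, baseline_cpm, expansion_index.
    """
    reps = cohort.labelled() if isinstance(cohort, Cohort) else list(cohort)
    all_seqs: set[str] = set()
    for rep in reps:
        all_seqs.update(rep.sequences())
    baseline = _baseline_mean_cpm(all_seqs, baselines, pseudo_cpm)
    rows = []
    for rep in reps:
        cpm = to_cpm(rep)
        for seq, c in cpm.items():
            b = baseline[seq]
            rows.append((seq, rep.mouse_id, rep.label, c, b, np.log2(c / b)))
    return pd.DataFrame(
        rows,
        columns=["sequence", "mouse_id", "label", "cpm", "baseline_cpm", "expansion_index"],
    )


def select_expanded(
    cohort: Cohort,
    baselines: list[Repertoire],
    class_tag: int,
    threshold: float = DEFAULT_HI,
) -> set[str]:
    """Sequences with expansion index strictly above ``threshold`` in at
    least one repertoire of ``class_tag``."""
    table = expansion_table(cohort.by_class(class_tag), baselines)
    hit = table[table["expansion_index"] > threshold]
    return set(hit["sequence"])


def select_antigen_associated(
    cohort: Cohort,
    baselines: list[Repertoire],
    hi: float = DEFAULT_HI,
    lo: float = DEFAULT_LO,
    pos_class: int = +1,
) -> set[str]:
    """Clones expanded in the focal class but quiet in the other class.

    Returns sequences with expansion index > ``hi`` in at least one
    ``pos_class`` repertoire AND < ``lo`` in all repertoires of the other
    class (absence from a repertoire trivially satisfies the < lo condition
    there). Both inequalities are strict.
    """
    neg_class = -pos_class
    expanded = select_expanded(cohort, baselines, pos_class, threshold=hi)
    if not expanded:
        return set()
    neg_table = expansion_table(cohort.by_class(neg_class), baselines)
    high_in_neg = set(
        neg_table[neg_table["expansion_index"] >= lo]["sequence"]
    )
    return expanded - high_in_neg


def expansion_histogram(
    cohort: Cohort,
    baselines: list[Repertoire],
    thresholds: list[float],
) -> list[int]:
    """Number of distinct sequences whose expansion index exceeds each
    threshold in at least one labelled repertoire (monotone non-increasing
    over increasing thresholds)."""
    table = expansion_table(cohort, baselines)
    best = table.groupby("sequence")["expansion_index"].max()
    return [int((best > t).sum()) for t in thresholds]
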