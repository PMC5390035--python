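"""Per-mouse CDR3β repertoire tables and cohort metadata.

A *repertoire* is one mouse's multiset of CDR3β amino-acid sequences with
read counts. Tables are plain TSV with a header naming at least ``cdr3_aa``
and ``count`` (optionally ``v_gene`` and ``j_gene``); cohort metadata is a
TSV with columns ``mouse_id``, ``path``, ``label``, ``timepoint``.

Class labels are +1 / -1 for the two immunization groups (by convention
antigen-plus-adjuvant vs adjuvant only) or the string ``"unimmunized"`` for
baseline mice, which are excluded from classification but serve as the
reference for the expansion index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, one-letter codes, lexicographic order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

UNIMMUNIZED = "unimmunized"

#: Default serialization of class tags in metadata files.
DEFAULT_LABEL_MAP = {"OVA": +1, "CFA": -1, "naive": UNIMMUNIZED}


class RepertoireFormatError(ValueError):
    """A repertoire or metadata table is malformed (e.g. missing column)."""


class EmptyRepertoireError(ValueError):
    """No valid clones remain after filtering."""


def is_valid_cdr3(sequence: str) -> bool:
    """True if ``sequence`` is non-empty and uses only standard residues."""
    return len(sequence) >= 1 and set(sequence) <= _AA_SET


@dataclass(frozen=True)
class Cdr3:
    """One clone: a CDR3β amino-acid sequence with its read count."""

    sequence: str
    count: int
    v_gene: str | None = None
    j_gene: str | None = None

    def __post_init__(self) -> None:
        if not is_valid_cdr3(self.sequence):
            raise ValueError(f"invalid CDR3 sequence: {self.sequence!r}")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


@dataclass
class Repertoire:
    """One mouse's repertoire: unique CDR3 clones plus metadata.

    ``label`` is +1, -1 or ``"unimmunized"``; ``timepoint`` is ``"early"``,
    ``"late"`` or ``"none"``. ``n_rejected`` counts input rows dropped
    because of non-standard residues.
    """

    mouse_id: str
    label: int | str
    clones: list[Cdr3] = field(default_factory=list)
    timepoint: str = "none"
    n_rejected: int = 0

    def __post_init__(self) -> None:
        seqs = [c.sequence for c in self.clones]
        if len(seqs) != len(set(seqs)):
            raise ValueError(f"duplicate sequences in repertoire {self.mouse_id}")

    def __len__(self) -> int:
        return len(self.clones)

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.clones)

    def sequences(self) -> list[str]:
        """Unique sequences in clone-list order."""
        return [c.sequence for c in self.clones]

    def counts(self) -> dict[str, int]:
        return {c.sequence: c.count for c in self.clones}

    @property
    def is_labelled(self) -> bool:
        return self.label in (+1, -1)


@dataclass
class Cohort:
    """A set of repertoires with unique mouse ids."""

    repertoires: list[Repertoire]

    def __post_init__(self) -> None:
        ids = [r.mouse_id for r in self.repertoires]
        if len(ids) != len(set(ids)):
            raise ValueError("mouse_id values must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.repertoires)

    @property
    def m(self) -> int:
        """Number of labelled (classifiable) repertoires."""
        return sum(r.is_labelled for r in self.repertoires)

    def labelled(self) -> list[Repertoire]:
        return [r for r in self.repertoires if r.is_labelled]

    def by_class(self, class_tag: int) -> list[Repertoire]:
        return [r for r in self.repertoires if r.label == class_tag]

    def __getitem__(self, mouse_id: str) -> Repertoire:
        for r in self.repertoires:
            if r.mouse_id == mouse_id:
                return r
        raise KeyError(mouse_id)


def read_repertoire(
    path: str | Path,
    mouse_id: str,
    label: int | str,
    timepoint: str = "none",
) -> Repertoire:
    """Read a TSV clone table into a :class:`Repertoire`.

    Rows sharing a ``cdr3_aa`` are merged by summing counts (count tables
    built from multiple V-primer pools can repeat a CDR3). Rows whose
    sequence contains a non-standard character are dropped; the number of
    dropped rows is logged and recorded in ``Repertoire.n_rejected``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cdr3_aa": str})
    for col in ("cdr3_aa", "count"):
        if col not in df.columns:
            raise RepertoireFormatError(f"missing required column {col!r} in {path}")
    valid = df["cdr3_aa"].map(lambda s: isinstance(s, str) and is_valid_cdr3(s))
    n_rejected = int((~valid).sum())
    if n_rejected:
        logger.warning("%s: dropped %d rows with non-standard residues", path, n_rejected)
    df = df[valid]

    has_v = "v_gene" in df.columns
    has_j = "j_gene" in df.columns
    clones: dict[str, Cdr3] = {}
    for row in df.itertuples(index=False):
        seq = row.cdr3_aa
        count = int(row.count)
        v = getattr(row, "v_gene", None) if has_v else None
        j = getattr(row, "j_gene", None) if has_j else None
        if seq in clones:
            prev = clones[seq]
            clones[seq] = Cdr3(seq, prev.count + count, prev.v_gene, prev.j_gene)
        else:
            clones[seq] = Cdr3(seq, count, v, j)
    if not clones:
        raise EmptyRepertoireError(f"no valid clones in {path}")
    return Repertoire(
        mouse_id=mouse_id,
        label=label,
        clones=list(clones.values()),
        timepoint=timepoint,
        n_rejected=n_rejected,
    )


def write_repertoire(rep: Repertoire, path: str | Path) -> None:
    """Write a clone table in the TSV dialect read by :func:`read_repertoire`."""
    rows = {
        "cdr3_aa": [c.sequence for c in rep.clones],
        "count": [c.count for c in rep.clones],
    }
    if any(c.v_gene for c in rep.clones):
        rows["v_gene"] = [c.v_gene or "" for c in rep.clones]
    if any(c.j_gene for c in rep.clones):
        rows["j_gene"] = [c.j_gene or "" for c in rep.clones]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cohort(
    metadata_path: str | Path,
    label_map: dict[str, int | str] | None = None,
) -> Cohort:
    """Read a cohort from a metadata TSV (mouse_id, path, label, timepoint).

    Repertoire paths are resolved relative to the metadata file's directory.
    ``label_map`` translates serialized labels into class tags; by default
    "OVA" -> +1, "CFA" -> -1, "naive" -> "unimmunized".
    """
    label_map = DEFAULT_LABEL_MAP if label_map is None else label_map
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("mouse_id", "path", "label"):
        if col not in meta.columns:
            raise RepertoireFormatError(f"missing metadata column {col!r}")
    base = Path(metadata_path).parent
    reps = []
    for row in meta.itertuples(index=False):
        raw = row.label
        if raw not in label_map:
            raise RepertoireFormatError(f"unmapped label {raw!r} for mouse {row.mouse_id}")
        timepoint = getattr(row, "timepoint", "none") or "none"
        reps.append(
            read_repertoire(base / row.path, row.mouse_id, label_map[raw], timepoint)
        )
    return Cohort(reps)


def to_cpm(rep: Repertoire) -> dict[str, float]:
    """Clone frequencies in counts-per-million of the repertoire depth."""
    total = rep.total_count
    if total < 1:
        raise EmptyRepertoireError(f"repertoire {rep.mouse_id} has zero total count")
    return {c.sequence: c.count * 1e6 / total for c in rep.clones}


def filter_top_fraction(rep: Repertoire, fraction: float) -> Repertoire:
    """Keep the top ``fraction`` of unique clones ranked by count.

    Keeps ceil(fraction * n_unique) clones; ties at the cutoff are broken by
    lexicographic order of sequence so the result is deterministic.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = math.ceil(fraction * len(rep.clones))
    ranked = sorted(rep.clones, key=lambda c: (-c.count, c.sequence))
    return Repertoire(
        mouse_id=rep.mouse_id,
        label=rep.label,
        clones=ranked[:k],
        timepoint=rep.timepoint,
    )


def filter_singlets(rep: Repertoire) -> Repertoire:
    """Keep only clones observed exactly once (count == 1).

    May return an empty repertoire; downstream consumers must handle that.
    """
    clones = [c for c in rep.clones if c.count == 1]
    return Repertoire(
        mouse_id=rep.mouse_id,
        label=rep.label,
        clones=clones,
        timepoint=rep.timepoint,
    )
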