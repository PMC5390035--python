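"""p-mer string features for CDR3 sets.

A set of CDR3 sequences is mapped to a vector of term frequencies over all
20**p length-p substrings (p = 3 gives 8,000 features). These vectors are
the columns of the boosting LP's H matrix and the coordinates used by the
p-spectrum kernel. The module also provides repertoire subsampling (the
99-sample majority-vote protocol draws fixed-size random sets of unique
CDR3s) and positional profiling of triplets along the CDR3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .repertoires import AA_ALPHABET, Repertoire

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
N_AA = len(AA_ALPHABET)


def enumerate_pmers(p: int) -> list[str]:
    """All p-mers over the 20-letter alphabet in lexicographic order."""
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    pmers = [""]
    for _ in range(p):
        pmers = [s + aa for s in pmers for aa in AA_ALPHABET]
    return pmers


def pmer_to_index(pmer: str) -> int:
    """Rank of a p-mer in the lexicographic enumeration (base-20 digits)."""
    idx = 0
    for ch in pmer:
        idx = idx * N_AA + _AA_INDEX[ch]
    return idx


def index_to_pmer(idx: int, p: int) -> str:
    out = []
    for _ in range(p):
        idx, r = divmod(idx, N_AA)
        out.append(AA_ALPHABET[r])
    return "".join(reversed(out))


def kmer_indices(seq: str, p: int) -> np.ndarray:
    """Indices of all overlapping p-mers of ``seq``; empty if len(seq) < p."""
    if len(seq) < p:
        return np.empty(0, dtype=np.int64)
    codes = np.fromiter((_AA_INDEX[ch] for ch in seq), dtype=np.int64, count=len(seq))
    idx = np.zeros(len(seq) - p + 1, dtype=np.int64)
    for off in range(p):
        idx = idx * N_AA + codes[off : off + len(idx)]
    return idx


def featurize(cdr3s: list[str], p: int, normalize: bool = False) -> np.ndarray:
    """Term-frequency vector of all p-mers over a set of CDR3 sequences.

    Overlapping occurrences are counted. With ``normalize`` the counts are
    divided by the total p-mer count of the set (an all-zero vector stays
    all-zero).
    """
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    n = N_AA**p
    if not cdr3s:
        return np.zeros(n)
    idx = np.concatenate([kmer_indices(s, p) for s in cdr3s])
    vec = np.bincount(idx, minlength=n).astype(float)
    if normalize:
        total = vec.sum()
        if total > 0:
            vec /= total
    return vec


def sequence_feature_matrix(sequences: list[str], p: int) -> sparse.csr_matrix:
    """Sparse (n_sequences x 20**p) matrix of per-sequence p-mer counts.

    Row sums of subsets of this matrix give the term-frequency vector of the
    subset, which is how the evaluation pipeline featurizes many subsamples
    of one repertoire cheaply.
    """
    rows, cols = [], []
    for i, seq in enumerate(sequences):
        ki = kmer_indices(seq, p)
        rows.append(np.full(len(ki), i, dtype=np.int64))
        cols.append(ki)
    if rows:
        row = np.concatenate(rows)
        col = np.concatenate(cols)
    else:
        row = col = np.empty(0, dtype=np.int64)
    data = np.ones(len(row))
    mat = sparse.coo_matrix(
        (data, (row, col)), shape=(len(sequences), N_AA**p)
    ).tocsr()
    mat.sum_duplicates()
    return mat


def subsample_repertoire(
    rep_or_sequences: Repertoire | list[str],
    sample_size: int,
    n_samples: int = 99,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[list[str]]:
    """Draw ``n_samples`` uniform without-replacement samples of unique CDR3s.

    Sampling is over unique sequences (not count-weighted), matching the
    count-independent singlet analyses. Deterministic given ``seed``.
    """
    if isinstance(rep_or_sequences, Repertoire):
        seqs = rep_or_sequences.sequences()
        name = rep_or_sequences.mouse_id
    else:
        seqs = list(rep_or_sequences)
        name = "<sequence list>"
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if sample_size > len(seqs):
        raise ValueError(
            f"sample_size {sample_size} exceeds the {len(seqs)} eligible "
            f"unique sequences of {name}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    arr = np.asarray(seqs, dtype=object)
    return [
        list(arr[rng.choice(len(arr), size=sample_size, replace=False)])
        for _ in range(n_samples)
    ]


@dataclass
class PositionProfile:
    """Where along the CDR3 a triplet starts, in 10 relative-length bins.

    ``bins`` holds occurrence frequencies summing to 1 (all-zero if the
    triplet never occurs); ``bands`` is the coarse display category per bin:
    "black" for frequency >= 10%, "gray" for >= 1%, "white" below.
    """

    bins: np.ndarray
    bands: list[str]

    @property
    def modal_bin(self) -> int:
        """1-based bin with the highest frequency (1 if all-zero)."""
        return int(np.argmax(self.bins)) + 1


def _band(freq: float) -> str:
    if freq >= 0.10:
        return "black"
    if freq >= 0.01:
        return "gray"
    return "white"


def triplet_position_profile(
    triplet: str, cdr3s: list[str], n_bins: int = 10
) -> PositionProfile:
    """Relative start positions of a triplet across a CDR3 set.

    Each CDR3 of length L is divided into ``n_bins`` equal units of length;
    an occurrence starting at 0-based index s falls in bin
    floor(n_bins * s / L) + 1 (clamped to ``n_bins``). Frequencies are
    normalized over all occurrences.
    """
    k = len(triplet)
    counts = np.zeros(n_bins)
    for seq in cdr3s:
        L = len(seq)
        start = seq.find(triplet)
        while start != -1:
            b = min(n_bins * start // L, n_bins - 1)
            counts[b] += 1
            start = seq.find(triplet, start + 1)
    total = counts.sum()
    bins = counts / total if total > 0 else counts
    return PositionProfile(bins=bins, bands=[_band(f) for f in bins])
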