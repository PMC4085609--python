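"""K-mer occurrence landscape: strand-collapsed 20-mer counting and
low/mid/high repetitive classification of clones.

The index counts canonical k-mers (a k-mer and its reverse complement
share one key) over the whole input set; a position of a clone is deemed
repetitive when it is spanned by at least one k-mer whose dataset-wide
count reaches the frequency threshold.  Clones are classified by the
fraction of their positions that are repetitive: low [0, 0.40),
mid [0.40, 0.70), high [0.70, 1.0].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from repeatscape.io import SequenceRecord
from repeatscape.simulate import encode_sequence

#: Default k (20-mer landscape) and repetitive-count threshold.
DEFAULT_K = 20
DEFAULT_FREQ_THRESHOLD = 4

CLASS_LOW_MID = 0.40
CLASS_MID_HIGH = 0.70


def _horner_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-windows of an encoded sequence (base 4)."""
    n = arr.size - k + 1
    codes = np.zeros(n, dtype=np.uint64)
    a = arr.astype(np.uint64)
    for j in range(k):
        codes = codes * np.uint64(4) + a[j : j + n]
    return codes


def _window_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(canonical codes, validity mask) for all k-windows of a sequence.

    Windows containing N are invalid and excluded from counting.
    """
    L = arr.size
    n = L - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    is_n = (arr >= 4).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(is_n)])
    valid = (cum[k:] - cum[:-k]) == 0
    safe = np.where(arr >= 4, 0, arr).astype(np.uint8)
    fwd = _horner_codes(safe, k)
    rc = (3 - safe)[::-1]
    rev_all = _horner_codes(rc, k)
    # rc code of the window starting at i equals the code of the window
    # starting at L-k-i of the reverse-complemented sequence
    rev = rev_all[::-1]
    canonical = np.minimum(fwd, rev)
    return canonical, valid


@dataclass
class KmerIndex:
    """Canonical k-mer occurrence counts over a sequence set.

    ``codes`` are sorted unique canonical k-mer codes; ``counts`` their
    dataset-wide occurrence counts.  Every count is >= 1 and the counts
    sum to the number of valid (N-free) k-mer positions indexed.
    """

    k: int
    codes: np.ndarray
    counts: np.ndarray

    @property
    def n_positions(self) -> int:
        return int(self.counts.sum())

    def count(self, kmer: str) -> int:
        """Occurrence count of one k-mer string (canonical lookup)."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {len(kmer)} bp")
        arr = encode_sequence(kmer.upper())
        if (arr >= 4).any():
            return 0
        codes, _ = _window_codes(arr, self.k)
        i = np.searchsorted(self.codes, codes[0])
        if i < self.codes.size and self.codes[i] == codes[0]:
            return int(self.counts[i])
        return 0

    def counts_for(self, seq: str | np.ndarray) -> np.ndarray:
        """Index counts for every k-window of ``seq`` (0 where invalid or
        absent from the index)."""
        arr = seq if isinstance(seq, np.ndarray) else encode_sequence(seq)
        codes, valid = _window_codes(arr, self.k)
        if codes.size == 0:
            return np.zeros(0, dtype=np.int64)
        idx = np.searchsorted(self.codes, codes)
        idx = np.clip(idx, 0, self.codes.size - 1)
        hit = self.codes[idx] == codes
        out = np.where(hit & valid, self.counts[idx], 0)
        return out.astype(np.int64)


def build_kmer_index(
    seqs: Iterable[SequenceRecord | str], k: int = DEFAULT_K
) -> KmerIndex:
    """Count canonical k-mers across a sequence set.

    Sequences shorter than k contribute nothing (a warning is emitted).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    all_codes = []
    any_long_enough = False
    for s in seqs:
        seq = s.seq if isinstance(s, SequenceRecord) else s
        if len(seq) < k:
            warnings.warn(
                f"sequence shorter than k={k} contributes no k-mers", stacklevel=2
            )
            continue
        any_long_enough = True
        codes, valid = _window_codes(encode_sequence(seq), k)
        all_codes.append(codes[valid])
    if not any_long_enough:
        raise ValueError(f"total sequence length < k={k}")
    merged = (
        np.concatenate(all_codes) if all_codes else np.empty(0, dtype=np.uint64)
    )
    codes, counts = np.unique(merged, return_counts=True)
    return KmerIndex(k=k, codes=codes, counts=counts.astype(np.int64))


def repetitive_coverage_mask(
    seq: str | np.ndarray, index: KmerIndex, freq_threshold: int = DEFAULT_FREQ_THRESHOLD
) -> np.ndarray:
    """Boolean per-position mask: spanned by a k-mer with count >= threshold."""
    arr = seq if isinstance(seq, np.ndarray) else encode_sequence(seq)
    L = arr.size
    counts = index.counts_for(arr)
    cov = np.zeros(L, dtype=bool)
    if counts.size == 0:
        return cov
    starts = np.where(counts >= freq_threshold)[0]
    if starts.size == 0:
        return cov
    diff = np.zeros(L + 1, dtype=np.int32)
    np.add.at(diff, starts, 1)
    np.add.at(diff, starts + index.k, -1)
    return np.cumsum(diff[:-1]) > 0


def repetitive_fraction(
    seq: SequenceRecord | str,
    index: KmerIndex,
    freq_threshold: int = DEFAULT_FREQ_THRESHOLD,
) -> float:
    """Fraction of positions covered by the span of a repetitive k-mer."""
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    if len(s) < index.k:
        warnings.warn("sequence shorter than k; fraction reported as 0", stacklevel=2)
        return 0.0
    mask = repetitive_coverage_mask(s, index, freq_threshold)
    return float(mask.sum()) / len(s)


def classify_clone(fraction: float) -> str:
    """Map a repetitive fraction to low/mid/high.

    Thresholds close the upper class: [0, 0.40) low, [0.40, 0.70) mid,
    [0.70, 1.0] high.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside [0, 1]")
    if fraction < CLASS_LOW_MID:
        return "low"
    if fraction < CLASS_MID_HIGH:
        return "mid"
    return "high"


@dataclass
class CloneProfile:
    """Per-clone landscape summary."""

    clone_id: str
    track: np.ndarray  # per-window index counts
    repetitive_fraction: float
    clone_class: str


def profile_clones(
    seqs: Sequence[SequenceRecord],
    index: KmerIndex,
    freq_threshold: int = DEFAULT_FREQ_THRESHOLD,
    keep_tracks: bool = False,
) -> list[CloneProfile]:
    """Profile and classify every clone against a shared index."""
    profiles = []
    for s in seqs:
        frac = repetitive_fraction(s, index, freq_threshold)
        track = index.counts_for(s.seq) if keep_tracks else np.empty(0, dtype=np.int64)
        profiles.append(CloneProfile(s.id, track, frac, classify_clone(frac)))
    return profiles
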