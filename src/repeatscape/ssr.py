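"""Perfect microsatellite (SSR) and AT-rich low-complexity detection.

SSR motifs of length 2-4 are reported as canonical motifs: the
lexicographically smallest string among all rotations of the motif and of
its reverse complement, so e.g. TGG, GGT, GTG, CCA, CAC and ACC all
report as ACC.  Only perfect (uninterrupted) tandem arrays are called.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from repeatscape.io import GenomicInterval, SequenceRecord

#: MISA-like minimum unit counts per motif length.
DEFAULT_MIN_UNITS = {2: 6, 3: 5, 4: 5}
DEFAULT_AT_THRESHOLD = 0.90
DEFAULT_LC_MIN_LEN = 30

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SSRLocus:
    """A perfect tandem array of a 2-4 bp motif."""

    interval: GenomicInterval
    motif: str
    canonical_motif: str
    n_units: int

    def __len__(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class LowComplexityRegion:
    """An AT-rich compositionally biased tract."""

    interval: GenomicInterval
    at_fraction: float


def is_primitive(motif: str) -> bool:
    """True unless the motif is a repetition of a shorter motif."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Canonical representative of a motif's rotation/strand class."""
    if not 2 <= len(motif) <= 4:
        raise ValueError(f"motif length must be 2-4, got {motif!r}")
    if set(motif) - set("ACGT"):
        raise ValueError(f"invalid motif {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rc = motif.translate(_COMPLEMENT)[::-1]
    candidates = [
        m[i:] + m[:i] for m in (motif, rc) for i in range(len(m))
    ]
    return min(candidates)


def find_ssrs(
    seq: SequenceRecord | str,
    min_units: dict[int, int] | None = None,
    max_interrupt: int = 0,
) -> list[SSRLocus]:
    """Find maximal perfect tandem arrays of 2-4 bp motifs.

    Overlapping calls of different motif lengths are resolved to the
    longest locus; the reported interval length is exactly
    ``len(motif) * n_units`` (a trailing partial unit is not included).
    """
    if max_interrupt != 0:
        raise NotImplementedError("only perfect repeats are supported")
    min_units = dict(DEFAULT_MIN_UNITS if min_units is None else min_units)
    sid = seq.id if isinstance(seq, SequenceRecord) else "seq"
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    candidates: list[SSRLocus] = []
    for m in (2, 3, 4):
        need = min_units.get(m)
        if need is None or need < 2 or arr.size < m * 2:
            continue
        eq = arr[:-m] == arr[m:]
        # maximal runs of equality; a run of t Trues spans a t+m bp array
        edges = np.flatnonzero(np.diff(np.concatenate([[0], eq.view(np.int8), [0]])))
        for rs, re_ in zip(edges[::2], edges[1::2]):
            span = int(re_ - rs) + m
            n_units = span // m
            if n_units < need:
                continue
            motif = s[rs : rs + m]
            if "N" in motif or not is_primitive(motif):
                continue
            start = int(rs)
            candidates.append(
                SSRLocus(
                    GenomicInterval(sid, start, start + n_units * m),
                    motif,
                    canonical_motif(motif),
                    n_units,
                )
            )
    # longest-locus-wins overlap resolution
    candidates.sort(key=lambda L: (-len(L), L.interval.start, len(L.motif)))
    kept: list[SSRLocus] = []
    for loc in candidates:
        if all(not loc.interval.overlaps(k.interval) for k in kept):
            kept.append(loc)
    kept.sort(key=lambda L: L.interval.start)
    return kept


def find_low_complexity(
    seq: SequenceRecord | str,
    at_threshold: float = DEFAULT_AT_THRESHOLD,
    min_len: int = DEFAULT_LC_MIN_LEN,
) -> list[LowComplexityRegion]:
    """Find AT-rich tracts: maximal merged windows of length >= min_len
    with A+T fraction >= at_threshold."""
    if not 0 < at_threshold <= 1 or min_len < 1:
        raise ValueError("invalid thresholds")
    sid = seq.id if isinstance(seq, SequenceRecord) else "seq"
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    at = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    is_at = (at == ord("A")) | (at == ord("T"))
    n = is_at.size - min_len + 1
    if n <= 0:
        return []
    cum = np.concatenate([[0], np.cumsum(is_at)])
    winsum = cum[min_len:] - cum[:-min_len]
    ok = winsum >= at_threshold * min_len
    # union of qualifying windows
    cov = np.zeros(is_at.size + 1, dtype=np.int32)
    starts = np.flatnonzero(ok)
    if starts.size == 0:
        return []
    np.add.at(cov, starts, 1)
    np.add.at(cov, starts + min_len, -1)
    covered = np.cumsum(cov[:-1]) > 0
    edges = np.flatnonzero(np.diff(np.concatenate([[0], covered.view(np.int8), [0]])))
    out: list[LowComplexityRegion] = []
    for rs, re_ in zip(edges[::2], edges[1::2]):
        start, end = int(rs), int(re_)
        # merged union can dip slightly below threshold: trim GC ends
        frac = is_at[start:end].mean()
        while frac < at_threshold and end - start > min_len:
            if not is_at[start]:
                start += 1
            elif not is_at[end - 1]:
                end -= 1
            else:
                break
            frac = is_at[start:end].mean()
        if end - start >= min_len and frac >= at_threshold:
            out.append(
                LowComplexityRegion(GenomicInterval(sid, start, end), float(frac))
            )
    return out


def ssr_summary(loci: Sequence[SSRLocus]) -> pd.DataFrame:
    """Frequency table per canonical motif, sorted by abundance.

    Columns: canonical_motif, motif_length, n_loci, total_units,
    total_bp; sorted descending by locus count then total units.
    """
    if not loci:
        return pd.DataFrame(
            columns=["canonical_motif", "motif_length", "n_loci", "total_units", "total_bp"]
        )
    df = pd.DataFrame(
        {
            "canonical_motif": [L.canonical_motif for L in loci],
            "motif_length": [len(L.motif) for L in loci],
            "n_units": [L.n_units for L in loci],
            "bp": [len(L) for L in loci],
        }
    )
    out = (
        df.groupby(["canonical_motif", "motif_length"], as_index=False)
        .agg(n_loci=("n_units", "size"), total_units=("n_units", "sum"), total_bp=("bp", "sum"))
        .sort_values(["n_loci", "total_units", "canonical_motif"], ascending=[False, False, True])
        .reset_index(drop=True)
    )
    return out
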