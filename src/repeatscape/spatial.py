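"""Spatial randomness of repeats along scaffolds: 5-kb binning,
binarization and the one-sample (Wald-Wolfowitz) runs test.

Scaffolds with at least 50 kb of contiguous (N-free) sequence are
divided into 5-kb bins; a bin is scored 1 when at least half of it is
repeat-masked and 0 otherwise, and the number of runs in the resulting
binary series is compared with its permutation expectation through the
normal approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from repeatscape.io import RepeatAnnotation, SequenceRecord

DEFAULT_BIN_SIZE = 5000
DEFAULT_MIN_CONTIGUOUS = 50_000
DEFAULT_BINARIZE_THRESHOLD = 0.5
SMALL_SERIES = 20  # below this many bins the normal approximation is flagged


class DegenerateSeriesError(ValueError):
    """Runs test undefined: the series is constant."""


@dataclass
class BinSeries:
    """Binarized repeat occupancy of one scaffold."""

    scaffold_id: str
    bin_size: int
    values: np.ndarray  # 0/1 per bin
    occupancy_fractions: np.ndarray


@dataclass(frozen=True)
class RunsTestResult:
    """One-sample runs test under the normal approximation."""

    scaffold_id: str
    n1: int
    n0: int
    runs: int
    mu: float
    sigma: float
    z: float
    p_two_sided: float
    approximate: bool  # flagged for short series


def ungapped_length(seq: str) -> int:
    """Length of the longest N-free stretch."""
    best = cur = 0
    for ch in seq:
        if ch == "N":
            cur = 0
        else:
            cur += 1
            best = max(best, cur)
    return best


def select_scaffolds(
    seqs: Sequence[SequenceRecord], min_contiguous: int = DEFAULT_MIN_CONTIGUOUS
) -> list[str]:
    """Ids of scaffolds with >= min_contiguous bp of contiguous sequence."""
    return [s.id for s in seqs if ungapped_length(s.seq) >= min_contiguous]


def binarize(
    scaffold: SequenceRecord,
    annotations: Sequence[RepeatAnnotation],
    bin_size: int = DEFAULT_BIN_SIZE,
    binarize_threshold: float = DEFAULT_BINARIZE_THRESHOLD,
) -> BinSeries:
    """Bin a scaffold and binarize per-bin repeat occupancy.

    Annotations must be overlap-resolved.  The trailing partial bin is
    kept when it is at least half a bin wide (occupancy computed over its
    actual width), otherwise dropped.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    L = len(scaffold.seq)
    cover = np.zeros(L + 1, dtype=np.int32)
    for a in annotations:
        if a.interval.scaffold_id != scaffold.id:
            continue
        cover[a.interval.start] += 1
        cover[a.interval.end] -= 1
    mask = np.cumsum(cover[:-1]) > 0
    n_full, rem = divmod(L, bin_size)
    edges = [(i * bin_size, (i + 1) * bin_size) for i in range(n_full)]
    if rem >= bin_size / 2:
        edges.append((n_full * bin_size, L))
    occ = np.array([mask[s:e].mean() if e > s else 0.0 for s, e in edges])
    values = (occ >= binarize_threshold).astype(np.int8)
    return BinSeries(scaffold.id, bin_size, values, occ)


def count_runs(values: np.ndarray) -> int:
    """Number of maximal runs in a binary series."""
    v = np.asarray(values)
    return int(1 + (np.diff(v) != 0).sum()) if v.size else 0


def runs_test(series: BinSeries) -> RunsTestResult:
    """One-sample runs test with the normal approximation.

    mu = 2 n1 n0 / n + 1, sigma^2 = 2 n1 n0 (2 n1 n0 - n) / (n^2 (n-1)),
    z = (R - mu) / sigma, p = 2 (1 - Phi(|z|)).  Raises for constant
    series; short series (< 20 bins) are flagged approximate.
    """
    v = np.asarray(series.values)
    n1 = int((v == 1).sum())
    n0 = int((v == 0).sum())
    n = n1 + n0
    if n1 == 0 or n0 == 0:
        raise DegenerateSeriesError(
            f"{series.scaffold_id}: series is constant (n1={n1}, n0={n0})"
        )
    R = count_runs(v)
    mu = 2.0 * n1 * n0 / n + 1.0
    var = 2.0 * n1 * n0 * (2.0 * n1 * n0 - n) / (n**2 * (n - 1))
    if var <= 0:
        raise DegenerateSeriesError(
            f"{series.scaffold_id}: zero-variance runs distribution"
        )
    sigma = math.sqrt(var)
    z = (R - mu) / sigma
    p = 2.0 * (1.0 - norm.cdf(abs(z)))
    return RunsTestResult(
        scaffold_id=series.scaffold_id,
        n1=n1,
        n0=n0,
        runs=R,
        mu=mu,
        sigma=sigma,
        z=z,
        p_two_sided=min(p, 1.0),
        approximate=n < SMALL_SERIES,
    )


def randomness_report(
    series_list: Sequence[BinSeries], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-scaffold runs tests, sorted by p, with a nonrandom flag.

    No multiple-testing correction is applied to the flag (each scaffold
    is reported at its own alpha); a Bonferroni-adjusted column is
    emitted alongside for transparency.  Constant (degenerate) series
    are skipped.
    """
    rows = []
    for s in series_list:
        try:
            r = runs_test(s)
        except DegenerateSeriesError:
            continue
        rows.append(
            {
                "scaffold_id": r.scaffold_id,
                "n_bins": r.n1 + r.n0,
                "n1": r.n1,
                "n0": r.n0,
                "runs": r.runs,
                "z": r.z,
                "p": r.p_two_sided,
                "approximate": r.approximate,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["scaffold_id", "n_bins", "n1", "n0", "runs", "z", "p", "approximate"],
    )
    if not df.empty:
        df["nonrandom"] = df["p"] < alpha
        df["p_bonferroni"] = np.minimum(df["p"] * len(df), 1.0)
        df = df.sort_values(["p", "scaffold_id"]).reset_index(drop=True)
    return df
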