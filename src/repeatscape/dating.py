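"""Kimura 2-parameter divergence and TE insertion-age estimation.

Two dating routes are implemented.  For LTR retrotransposons the two
LTRs of an element are identical at insertion and diverge along two
lineages, so the insertion age is T = d / (2 r) with d the K2P distance
between the LTR pair and r the substitution rate (default 2.0e-8
subs/site/yr).  For arbitrary TE families the family consensus stands in
for the ancestral element and a single lineage separates each copy from
it, so the family age is T = k / r with k the mean K2P-corrected
divergence of the members to the consensus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from repeatscape.io import SequenceRecord
from repeatscape.simulate import DEFAULT_RATE


class SaturationError(ValueError):
    """K2P correction undefined: too many substitutions to invert."""


@dataclass(frozen=True)
class AlignedPair:
    """Two equal-length gapped sequences."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")


@dataclass(frozen=True)
class K2PResult:
    """K2P distance with its transition/transversion components."""

    d: float
    P: float  # transition proportion
    Q: float  # transversion proportion
    comparable_sites: int


@dataclass(frozen=True)
class AgeEstimate:
    """A divergence with its derived insertion age."""

    element_id: str
    d: float
    P: float
    Q: float
    rate: float
    age_years: float


@dataclass(frozen=True)
class FamilyAge:
    """Consensus-based family age: T = k / r."""

    family_id: str
    k: float
    rate: float
    age_years: float
    n_members: int


_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def count_site_patterns(pair: AlignedPair) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) for an aligned pair.

    Columns with a gap, N or other ambiguity in either row are excluded.
    Transitions are A<->G and C<->T; every other substitution is a
    transversion.
    """
    a = _ENC[np.frombuffer(pair.seq_a.upper().encode("ascii"), dtype=np.uint8)]
    b = _ENC[np.frombuffer(pair.seq_b.upper().encode("ascii"), dtype=np.uint8)]
    valid = (a >= 0) & (b >= 0)
    av, bv = a[valid], b[valid]
    diff = av != bv
    ti = diff & ((av ^ bv) == 2)
    return int(valid.sum()), int(ti.sum()), int((diff & ~ti).sum())


def k2p_distance(pair: AlignedPair | tuple[str, str]) -> K2PResult:
    """Kimura 2-parameter distance of an aligned pair.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P and Q the transition
    and transversion proportions over comparable (unambiguous, ungapped)
    sites.  Raises :class:`SaturationError` when the correction is
    undefined rather than returning NaN.
    """
    if not isinstance(pair, AlignedPair):
        pair = AlignedPair(*pair)
    n, n_ti, n_tv = count_site_patterns(pair)
    if n < 1:
        raise ValueError("no comparable sites in alignment")
    P, Q = n_ti / n, n_tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"saturated pair: P={P:.3f}, Q={Q:.3f} (log arguments "
            f"{w1:.3f}, {w2:.3f})"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(d=d, P=P, Q=Q, comparable_sites=n)


def k2p_expected_pq(d: float, ti_tv_ratio: float = 2.0) -> tuple[float, float]:
    """Expected transition/transversion proportions at K2P divergence d.

    With transition rate alpha and per-target transversion rate beta
    scaled so alpha + 2 beta = 1 and alpha / (2 beta) = ti_tv_ratio:
    P(d) = 1/4 + 1/4 e^(-4 beta d) - 1/2 e^(-2 (alpha+beta) d),
    Q(d) = 1/2 - 1/2 e^(-4 beta d).
    """
    R = ti_tv_ratio
    alpha = R / (R + 1.0)
    beta = 1.0 / (2.0 * (R + 1.0))
    P = 0.25 + 0.25 * math.exp(-4 * beta * d) - 0.5 * math.exp(-2 * (alpha + beta) * d)
    Q = 0.5 - 0.5 * math.exp(-4 * beta * d)
    return P, Q


def ltr_insertion_age(d: float, rate: float = DEFAULT_RATE) -> float:
    """Insertion age of an LTR pair: T = d / (2 r)."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if d < 0:
        raise ValueError("distance must be >= 0")
    return d / (2.0 * rate)


def date_ltr_pair(
    element_id: str, ltr5: str, ltr3: str, rate: float = DEFAULT_RATE
) -> AgeEstimate:
    """K2P distance and insertion age of one 5'/3' LTR pair."""
    res = k2p_distance((ltr5, ltr3))
    return AgeEstimate(
        element_id=element_id,
        d=res.d,
        P=res.P,
        Q=res.Q,
        rate=rate,
        age_years=ltr_insertion_age(res.d, rate),
    )


def _align_to_consensus(member: str, consensus: str) -> AlignedPair:
    """Aligned pair of a member against the family consensus.

    Equal-length sequences compare directly (the common substitution-only
    case); otherwise the shorter is placed into the longer by edlib infix
    alignment and gaps inserted from the alignment path.
    """
    if len(member) == len(consensus):
        return AlignedPair(member, consensus)
    q, t = (member, consensus) if len(member) <= len(consensus) else (consensus, member)
    res = edlib.align(q, t, mode="HW", task="path")
    start = res["locations"][0][0]
    qa, ta = [], []
    qpos, tpos = 0, start
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in ("=", "X", "M"):
            qa.append(q[qpos : qpos + n])
            ta.append(t[tpos : tpos + n])
            qpos += n
            tpos += n
        elif ch == "I":
            qa.append(q[qpos : qpos + n])
            ta.append("-" * n)
            qpos += n
        elif ch == "D":
            qa.append("-" * n)
            ta.append(t[tpos : tpos + n])
            tpos += n
    return AlignedPair("".join(qa), "".join(ta))


def family_consensus_age(
    members: Sequence[SequenceRecord | str],
    consensus: str,
    rate: float = DEFAULT_RATE,
    family_id: str = "family",
) -> FamilyAge:
    """Consensus-based family age.

    k is the mean K2P-corrected distance of the members to the consensus
    and the age is T = k / r (one lineage separates each copy from the
    ancestral element the consensus approximates).  Saturated members are
    excluded with a warning; if all members saturate an error is raised.
    """
    if len(members) < 2:
        raise ValueError("need at least 2 members to date a family")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    dists = []
    for m in members:
        seq = m.seq if isinstance(m, SequenceRecord) else m
        try:
            dists.append(k2p_distance(_align_to_consensus(seq, consensus)).d)
        except SaturationError:
            mid = m.id if isinstance(m, SequenceRecord) else "<member>"
            warnings.warn(
                f"{family_id}: member {mid} saturated, excluded from dating",
                stacklevel=2,
            )
    if not dists:
        raise SaturationError(f"{family_id}: all members saturated")
    k = float(np.mean(dists))
    return FamilyAge(
        family_id=family_id,
        k=k,
        rate=rate,
        age_years=k / rate,
        n_members=len(dists),
    )


def age_divergence_correlation(family_ages: Sequence[FamilyAge]) -> float:
    """Pearson correlation between family mean divergence k and age.

    Equals 1.0 exactly whenever the same rate maps k to age (age is
    linear in k).  Raises on zero variance.
    """
    if len(family_ages) < 2:
        raise ValueError("need at least 2 families")
    if len(family_ages) < 3:
        warnings.warn("correlation over fewer than 3 families", stacklevel=2)
    k = np.array([f.k for f in family_ages])
    t = np.array([f.age_years for f in family_ages])
    if np.std(k) == 0 or np.std(t) == 0:
        raise ValueError("correlation undefined: zero variance in k or age")
    return float(np.corrcoef(k, t)[0, 1])


def age_amplification_correlation(
    ages: Mapping[str, float], coverages: Mapping[str, float]
) -> float:
    """Pearson correlation between element insertion age and genome coverage."""
    missing = set(ages) ^ set(coverages)
    if missing:
        raise ValueError(f"mismatched element ids: {sorted(missing)}")
    ids = sorted(ages)
    if len(ids) < 3:
        raise ValueError("need at least 3 matched elements")
    a = np.array([ages[i] for i in ids])
    c = np.array([coverages[i] for i in ids])
    if np.std(a) == 0 or np.std(c) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(a, c)[0, 1])


EXPRESSION_CATEGORIES = ("silent", "flower_only", "rootstem_only", "both")

#: "zero expression" = coverage that rounds to 0.000 at 3 decimals.
DEFAULT_PRESENCE_THRESHOLD = 0.0005


def classify_expression(
    table: pd.DataFrame,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Categorize per-element expression and correlate with genome coverage.

    The table must have ``genome``, ``flower`` and ``root_stem`` columns.
    An element is silent when both transcriptome coverages fall below the
    presence threshold, exclusive when exactly one does.  Returns the
    per-element categories plus Pearson correlations of the genome column
    with each transcriptome column.
    """
    for col in ("genome", "flower", "root_stem"):
        if col not in table.columns:
            raise ValueError(f"coverage table lacks required column {col!r}")
    fl = table["flower"] >= presence_threshold
    rt = table["root_stem"] >= presence_threshold
    category = np.where(
        ~fl & ~rt,
        "silent",
        np.where(fl & ~rt, "flower_only", np.where(rt & ~fl, "rootstem_only", "both")),
    )
    out = table.copy()
    out["category"] = category
    corr = {
        "genome_vs_flower": float(
            np.corrcoef(table["genome"], table["flower"])[0, 1]
        ),
        "genome_vs_root_stem": float(
            np.corrcoef(table["genome"], table["root_stem"])[0, 1]
        ),
    }
    return out, corr
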