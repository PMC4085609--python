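"""Homology masking against a labeled repeat library, overlap resolution
and composition summaries.

Masking is a seed-and-extend search: exact 12-mer seeds anchor candidate
library/scaffold diagonals, and the maximal-scoring segment on each
diagonal (match +((1-t)), mismatch -t, so a segment scores positive only
above the identity threshold t) is reported when it reaches the minimum
identity and length.  Diagonal extension suits the substitution-dominated
divergence this package analyzes; both strands of the library are
searched.

Overlap resolution assigns contested bases to the higher-scoring
annotation (ties: longer interval, then lexicographic family), truncating
or splitting the losers, so the output is pairwise disjoint and covers
exactly the input union.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from repeatscape.io import (
    AnnotationError,
    GenomicInterval,
    RepeatAnnotation,
    SequenceRecord,
)
from repeatscape.simulate import encode_sequence

DEFAULT_GENOME_SIZE = 3.6e9
_SEED_K = 12

#: Composition-table row order (Class I, Class II, satellite/other).
CLASS_ORDER = [
    "Ty1-Copia",
    "Ty3-Gypsy",
    "LINE_SINE",
    "ClassI-unclassified",
    "ClassI-novel",
    "DNA-nonMITE",
    "MITE",
    "DNA-unclassified",
    "rDNA",
    "centromeric",
    "telomeric",
    "SSR",
    "low_complexity",
    "unclassified",
    "novel",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def parse_library_label(rec: SequenceRecord) -> tuple[str, str]:
    """Extract (repeat_class, family_id) from a library record.

    Headers must carry ``class=<label>`` in the description; family
    defaults to the record id (``family=<id>`` overrides).
    """
    klass = family = None
    for token in rec.description.split():
        if token.startswith("class="):
            klass = token[6:]
        elif token.startswith("family="):
            family = token[7:]
    if klass is None:
        raise AnnotationError(
            f"library record {rec.id!r} lacks a class=<label> annotation"
        )
    return klass, family or rec.id


def _codes(arr: np.ndarray, k: int) -> np.ndarray:
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    a = np.where(arr >= 4, 0, arr).astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + a[j : j + n]
    return codes


def _max_scoring_segment(match: np.ndarray, t: float) -> tuple[int, int, float]:
    """Kadane scan for the maximal-scoring run under +(1-t)/-t weights.

    Returns (start, end, identity of the segment); (0, 0, 0.0) when every
    segment scores non-positive.
    """
    w = np.where(match, 1.0 - t, -t)
    best = cur = 0.0
    best_s = best_e = cur_s = 0
    for i, wi in enumerate(w):
        if cur <= 0:
            cur, cur_s = 0.0, i
        cur += wi
        if cur > best:
            best, best_s, best_e = cur, cur_s, i + 1
    if best <= 0:
        return 0, 0, 0.0
    ident = float(match[best_s:best_e].mean())
    return best_s, best_e, ident


def mask_with_library(
    seqs: Sequence[SequenceRecord],
    library: Sequence[SequenceRecord],
    min_identity: float = 0.80,
    min_len: int = 50,
) -> list[RepeatAnnotation]:
    """Annotate scaffold regions homologous to a labeled repeat library."""
    lib_entries = []
    for rec in library:
        klass, family = parse_library_label(rec)
        lib_entries.append((rec.id, klass, family, rec.seq, "+"))
        lib_entries.append((rec.id, klass, family, reverse_complement(rec.seq), "-"))

    # seed table over the (small) library
    seed_map: dict[int, list[tuple[int, int]]] = {}
    for li, (_id, _k, _f, lseq, _s) in enumerate(lib_entries):
        for off, code in enumerate(_codes(encode_sequence(lseq), _SEED_K)):
            seed_map.setdefault(int(code), []).append((li, off))

    lib_code_set = np.array(sorted(seed_map), dtype=np.int64)

    annotations: list[RepeatAnnotation] = []
    for rec in seqs:
        arr = encode_sequence(rec.seq)
        codes = _codes(arr, _SEED_K)
        hit_mask = np.zeros(codes.size, dtype=bool)
        if codes.size:
            idx = np.searchsorted(lib_code_set, codes)
            idx = np.clip(idx, 0, lib_code_set.size - 1)
            hit_mask = lib_code_set[idx] == codes
        diag_hits: dict[tuple[int, int], int] = {}
        for pos in np.flatnonzero(hit_mask):
            for li, off in seed_map[int(codes[pos])]:
                key = (li, int(pos) - off)
                diag_hits[key] = diag_hits.get(key, 0) + 1
        for (li, diag), nseeds in sorted(diag_hits.items()):
            if nseeds < 2:
                continue
            _lid, klass, family, lseq, strand = lib_entries[li]
            larr = encode_sequence(lseq)
            s0 = max(0, diag)
            e0 = min(arr.size, diag + larr.size)
            if e0 - s0 < min_len:
                continue
            match = arr[s0:e0] == larr[s0 - diag : e0 - diag]
            seg_s, seg_e, ident = _max_scoring_segment(match, min_identity)
            if seg_e - seg_s >= min_len and ident >= min_identity:
                annotations.append(
                    RepeatAnnotation(
                        GenomicInterval(rec.id, s0 + seg_s, s0 + seg_e, strand),
                        klass,
                        family,
                        score=ident,
                    )
                )
    return annotations


def resolve_overlaps(
    annotations: Sequence[RepeatAnnotation],
) -> list[RepeatAnnotation]:
    """Assign contested bases to the higher-scoring annotation.

    Losers are truncated (possibly split); the output is pairwise
    disjoint and covers exactly the union of the input intervals.
    Contests are decided by score, then longer interval, then
    lexicographic family_id.
    """
    order = sorted(
        annotations,
        key=lambda a: (
            -a.score,
            -(len(a.interval)),
            a.family_id or "",
            a.repeat_class,
            a.interval.scaffold_id,
            a.interval.start,
            a.interval.end,
        ),
    )
    claimed: dict[str, list[tuple[int, int]]] = {}
    out: list[RepeatAnnotation] = []
    for a in order:
        iv = a.interval
        taken = claimed.setdefault(iv.scaffold_id, [])
        # subtract claimed intervals from [start, end)
        free: list[tuple[int, int]] = []
        cur = iv.start
        i = bisect_left(taken, (iv.start, iv.start))
        if i > 0 and taken[i - 1][1] > iv.start:
            i -= 1
        while cur < iv.end:
            if i < len(taken) and taken[i][0] < iv.end:
                ts, te = taken[i]
                if ts > cur:
                    free.append((cur, min(ts, iv.end)))
                cur = max(cur, te)
                i += 1
            else:
                free.append((cur, iv.end))
                break
        for fs, fe in free:
            if fe > fs:
                out.append(
                    RepeatAnnotation(
                        GenomicInterval(iv.scaffold_id, fs, fe, iv.strand),
                        a.repeat_class,
                        a.family_id,
                        a.score,
                    )
                )
                insort(taken, (fs, fe))
    out.sort(key=lambda a: (a.interval.scaffold_id, a.interval.start, a.interval.end))
    return out


@dataclass
class CompositionSummary:
    """Per-class repeat composition with genome extrapolation."""

    table: pd.DataFrame
    dataset_bp: int
    genome_size: float
    total_repetitive_bp: int

    @property
    def pct_repetitive_of_dataset(self) -> float:
        return 100.0 * self.total_repetitive_bp / self.dataset_bp


def summarize_composition(
    annotations: Sequence[RepeatAnnotation],
    dataset_bp: int,
    genome_size: float = DEFAULT_GENOME_SIZE,
) -> CompositionSummary:
    """Composition-table summary of overlap-resolved annotations.

    ``pct_of_genome`` = 100 * class_bp / dataset_bp (the surveyed
    fraction extrapolated to the genome), ``genome_bp`` = that fraction
    of ``genome_size``, ``pct_of_repetitive`` = class share of all
    repetitive bp.
    """
    if dataset_bp <= 0:
        raise ValueError("dataset_bp must be > 0")
    bp: dict[str, int] = {}
    for a in annotations:
        bp[a.repeat_class] = bp.get(a.repeat_class, 0) + len(a.interval)
    total = sum(bp.values())
    rows = []
    for klass in CLASS_ORDER:
        class_bp = bp.get(klass, 0)
        rows.append(
            {
                "repeat_class": klass,
                "bac_bp": class_bp,
                "genome_bp": (class_bp / dataset_bp) * genome_size,
                "pct_of_genome": 100.0 * class_bp / dataset_bp,
                "pct_of_repetitive": (
                    100.0 * class_bp / total if total else 0.0
                ),
            }
        )
    rows.append(
        {
            "repeat_class": "Total Repetitive",
            "bac_bp": total,
            "genome_bp": (total / dataset_bp) * genome_size,
            "pct_of_genome": 100.0 * total / dataset_bp,
            "pct_of_repetitive": 100.0 if total else 0.0,
        }
    )
    return CompositionSummary(
        table=pd.DataFrame(rows),
        dataset_bp=dataset_bp,
        genome_size=genome_size,
        total_repetitive_bp=total,
    )


@dataclass
class DensityReport:
    """bp of sequence per repeat copy, by window class."""

    bp_per_repeat_dense: float | None
    bp_per_repeat_poor: float | None
    bp_per_repeat_avg: float | None


def repeat_density(
    annotations: Sequence[RepeatAnnotation],
    regions: Sequence[tuple[GenomicInterval, str]],
) -> DensityReport:
    """Repeat density per region class.

    A copy belongs to the region containing its interval midpoint;
    density for a class = total region bp / number of copies there.
    Region classes with no copies report ``None`` (absent), not zero.
    """
    region_bp = {"dense": 0, "poor": 0}
    for iv, label in regions:
        if label not in region_bp:
            raise ValueError(f"unknown region class {label!r}")
        region_bp[label] += len(iv)
    counts = {"dense": 0, "poor": 0}
    for a in annotations:
        mid = (a.interval.start + a.interval.end) // 2
        for iv, label in regions:
            if iv.scaffold_id == a.interval.scaffold_id and iv.start <= mid < iv.end:
                counts[label] += 1
                break

    def density(bp: int, n: int) -> float | None:
        return bp / n if n else None

    total_bp = region_bp["dense"] + region_bp["poor"]
    total_n = counts["dense"] + counts["poor"]
    return DensityReport(
        bp_per_repeat_dense=density(region_bp["dense"], counts["dense"]),
        bp_per_repeat_poor=density(region_bp["poor"], counts["poor"]),
        bp_per_repeat_avg=density(total_bp, total_n),
    )


def mask_sequence(seq: SequenceRecord, annotations: Sequence[RepeatAnnotation]) -> str:
    """Lowercase the repeat bases of one scaffold (soft masking)."""
    s = list(seq.seq)
    for a in annotations:
        if a.interval.scaffold_id != seq.id:
            continue
        for p in range(a.interval.start, a.interval.end):
            s[p] = s[p].lower()
    return "".join(s)
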