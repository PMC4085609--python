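"""De novo repeat family detection, clustering and consensus building.

Repeat copies are called as maximal runs of positions supported by
high-frequency k-mers (the index from :mod:`repeatscape.kmers`), merged
across short gaps and filtered at a minimum length of 50 bp.  Copies are
then clustered by single linkage: two copies link when their best
alignment reaches 80% identity over at least 51% of the shorter
sequence's length (blastclust-style L/S semantics), and connected
components with at least five members are emitted as repeat families
with a star-alignment majority consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np
import pandas as pd

from repeatscape.io import GenomicInterval, SequenceRecord
from repeatscape.kmers import KmerIndex, repetitive_coverage_mask

DEFAULT_MIN_LEN = 50
DEFAULT_MERGE_GAP = 50
DEFAULT_MIN_COPIES = 5
DEFAULT_IDENTITY = 0.80
DEFAULT_COVERAGE = 0.51

_SEED_K = 14
_SEED_STRIDE = 5


@dataclass(frozen=True)
class RepeatCopy:
    """One repeat occurrence on a scaffold."""

    copy_id: str
    interval: GenomicInterval
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class RepeatFamily:
    """A set of member copies plus a consensus model."""

    family_id: str
    members: list[RepeatCopy]
    consensus: str = ""

    @property
    def copy_number(self) -> int:
        return len(self.members)

    @property
    def total_bp(self) -> int:
        return sum(len(m) for m in self.members)


@dataclass
class ClusterReport:
    """Cluster-size accounting in the layout of a blastclust summary."""

    n_sequences: int
    n_unclustered: int
    n_clusters: int
    clusters_gt5: int
    clusters_gt20: int
    clusters_gt50: int
    clusters_gt100: int
    largest_cluster_size: int
    cluster_sizes: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Total number of sequences", self.n_sequences),
            ("Number of sequences not clustered", self.n_unclustered),
            ("Number of clusters", self.n_clusters),
            ("Clusters with >5 sequences", self.clusters_gt5),
            ("Clusters with >20 sequences", self.clusters_gt20),
            ("Clusters with >50 sequences", self.clusters_gt50),
            ("Clusters with >100 sequences", self.clusters_gt100),
            ("Number of sequences in the largest cluster", self.largest_cluster_size),
        ]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def find_repeat_intervals(
    seqs: Sequence[SequenceRecord],
    index: KmerIndex,
    freq_threshold: int = 4,
    min_len: int = DEFAULT_MIN_LEN,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> list[RepeatCopy]:
    """Call repeat copies as k-mer-supported intervals.

    Maximal runs of positions spanned by k-mers with index count >=
    ``freq_threshold`` are merged when separated by at most ``merge_gap``
    bp and emitted when at least ``min_len`` bp long.
    """
    copies: list[RepeatCopy] = []
    for rec in seqs:
        if len(rec.seq) < index.k:
            continue
        mask = repetitive_coverage_mask(rec.seq, index, freq_threshold)
        if not mask.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
        starts, ends = edges[::2], edges[1::2]
        merged: list[list[int]] = []
        for s, e in zip(starts, ends):
            if merged and s - merged[-1][1] <= merge_gap:
                merged[-1][1] = e
            else:
                merged.append([int(s), int(e)])
        for s, e in merged:
            if e - s >= min_len:
                cid = f"{rec.id}:{s}-{e}"
                copies.append(
                    RepeatCopy(cid, GenomicInterval(rec.id, s, e), rec.seq[s:e])
                )
    return copies


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _pair_links(
    copies: Sequence[RepeatCopy], identity_threshold: float, coverage_threshold: float
) -> _UnionFind:
    """Single-linkage union of copies sharing sufficient alignment identity.

    Candidate pairs are pre-screened by shared sampled k-mer seeds (exact
    14-mers every 5 positions) and verified by edlib infix alignment of
    the shorter copy against the longer.  The infix alignment places the
    entire shorter sequence, so the aligned coverage of the shorter copy
    is complete and the 0.51 length criterion is met whenever a
    qualifying alignment exists.
    """
    uf = _UnionFind(len(copies))
    seeds: dict[str, list[int]] = {}
    for i, c in enumerate(copies):
        for p in range(0, len(c.seq) - _SEED_K + 1, _SEED_STRIDE):
            seeds.setdefault(c.seq[p : p + _SEED_K], []).append(i)
    candidates: set[tuple[int, int]] = set()
    for ids in seeds.values():
        if len(ids) < 2:
            continue
        uniq = sorted(set(ids))
        for a in range(len(uniq)):
            for b in range(a + 1, len(uniq)):
                candidates.add((uniq[a], uniq[b]))
    for i, j in sorted(candidates):
        if uf.find(i) == uf.find(j):
            continue
        a, b = copies[i].seq, copies[j].seq
        if len(a) > len(b):
            a, b = b, a
        max_dist = int(len(a) * (1.0 - identity_threshold))
        res = edlib.align(a, b, mode="HW", task="distance", k=max_dist)
        if res["editDistance"] != -1:
            identity = 1.0 - res["editDistance"] / len(a)
            if identity >= identity_threshold:
                uf.union(i, j)
    return uf


def cluster_copies(
    copies: Sequence[RepeatCopy],
    identity_threshold: float = DEFAULT_IDENTITY,
    coverage_threshold: float = DEFAULT_COVERAGE,
    min_copies: int = DEFAULT_MIN_COPIES,
    build_consensi: bool = True,
) -> tuple[list[RepeatFamily], ClusterReport]:
    """Cluster copies into families and tally a cluster report.

    Families are single-linkage connected components with at least
    ``min_copies`` members; smaller components stay visible in the report
    (singletons count as unclustered) but are not emitted as families.
    """
    if not copies:
        raise ValueError("need at least one copy to cluster")
    uf = _pair_links(copies, identity_threshold, coverage_threshold)
    groups: dict[int, list[int]] = {}
    for i in range(len(copies)):
        groups.setdefault(uf.find(i), []).append(i)

    comps = sorted(
        groups.values(), key=lambda g: (-len(g), min(copies[i].copy_id for i in g))
    )
    sizes = [len(g) for g in comps]
    n_unclustered = sum(1 for s in sizes if s == 1)
    clusters = [s for s in sizes if s >= 2]
    report = ClusterReport(
        n_sequences=len(copies),
        n_unclustered=n_unclustered,
        n_clusters=len(clusters),
        clusters_gt5=sum(1 for s in clusters if s > 5),
        clusters_gt20=sum(1 for s in clusters if s > 20),
        clusters_gt50=sum(1 for s in clusters if s > 50),
        clusters_gt100=sum(1 for s in clusters if s > 100),
        largest_cluster_size=max(sizes),
        cluster_sizes=clusters,
    )
    families = []
    n = 0
    for g in comps:
        if len(g) < min_copies:
            continue
        members = sorted((copies[i] for i in g), key=lambda c: c.copy_id)
        fam = RepeatFamily(f"FAM{n:04d}", members)
        if build_consensi:
            fam.consensus = build_consensus(fam)
        families.append(fam)
        n += 1
    return families, report


def build_consensus(family: RepeatFamily) -> str:
    """Star-alignment majority consensus of a family.

    Members are aligned to the longest member (edlib infix alignment);
    each column takes the majority base over the aligned members, ties
    broken alphabetically.  The consensus has the longest member's length.
    """
    members = family.members
    if not members:
        raise ValueError("family has no members")
    if len(members) == 1:
        warnings.warn(
            f"{family.family_id}: single member, returning it as consensus",
            stacklevel=2,
        )
        return members[0].seq
    ref = max(members, key=lambda m: (len(m), m.copy_id)).seq
    votes = np.zeros((5, len(ref)), dtype=np.int32)  # ACGTN columns
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    for m in members:
        if m.seq == ref:
            for p, b in enumerate(ref):
                votes[base_idx[b], p] += 1
            continue
        res = edlib.align(m.seq, ref, mode="HW", task="path")
        start = res["locations"][0][0]
        qpos, rpos = 0, start
        for n_ops, op in _parse_cigar(res["cigar"]):
            if op in ("=", "X", "M"):
                for t in range(n_ops):
                    votes[base_idx[m.seq[qpos + t]], rpos + t] += 1
                qpos += n_ops
                rpos += n_ops
            elif op == "I":  # insertion in member relative to ref
                qpos += n_ops
            elif op == "D":  # deletion in member: ref columns unvoted
                rpos += n_ops
    out = []
    order = "ACGT"
    for p in range(len(ref)):
        col = votes[:4, p]
        if col.sum() == 0:
            out.append(ref[p])
        else:
            out.append(order[int(np.argmax(col))])  # argmax ties -> lowest = alphabetical
    return "".join(out)


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


@dataclass
class AbundanceCurve:
    """Cumulative family-abundance summary."""

    families_for_50pct_bp: int
    families_for_50pct_copies: int
    table: pd.DataFrame


def family_abundance_curve(families: Sequence[RepeatFamily]) -> AbundanceCurve:
    """How few families account for half the repetitive content.

    Families are ranked by total bp (resp. copy number); the reported
    count is the smallest prefix whose cumulative share reaches 50%.
    """
    if not families:
        raise ValueError("need at least one family")
    df = pd.DataFrame(
        {
            "family_id": [f.family_id for f in families],
            "total_bp": [f.total_bp for f in families],
            "copy_number": [f.copy_number for f in families],
        }
    )

    def prefix_for_half(col: str) -> int:
        s = df.sort_values([col, "family_id"], ascending=[False, True])[col]
        cum = s.cumsum() / s.sum()
        return int(np.searchsorted(cum.to_numpy(), 0.5) + 1)

    by_bp = df.sort_values(["total_bp", "family_id"], ascending=[False, True]).reset_index(
        drop=True
    )
    by_bp["cum_bp_share"] = by_bp["total_bp"].cumsum() / by_bp["total_bp"].sum()
    return AbundanceCurve(
        families_for_50pct_bp=prefix_for_half("total_bp"),
        families_for_50pct_copies=prefix_for_half("copy_number"),
        table=by_bp,
    )
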