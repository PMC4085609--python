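"""Poisson-corrected amino-acid distances and neighbor-joining trees
with bootstrap supports, for reverse-transcriptase domain phylogenies.

Distances use the Poisson correction d = -ln(1 - p) with p the
mismatch proportion over pairwise-deleted (unambiguous) columns;
complete deletion is available to emulate a fixed final dataset.  The
neighbor-joining implementation is the classic Q-criterion algorithm
with deterministic lexicographic tie-breaks and negative branch lengths
clamped to zero (the deficit moved to the sister edge).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from repeatscape.io import SequenceRecord

_AA = set("ACDEFGHIKLMNPQRSTVWY")


class SaturationError(ValueError):
    """Poisson correction undefined (mismatch proportion >= 1)."""


@dataclass
class AlignedAAMatrix:
    """An aligned set of amino-acid sequences."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_positions(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord]) -> "AlignedAAMatrix":
        return cls([r.id for r in records], [r.seq.upper() for r in records])

    def resample_columns(self, rng: np.random.Generator) -> "AlignedAAMatrix":
        """Bootstrap replicate: columns resampled with replacement."""
        n = self.n_positions
        cols = rng.integers(0, n, size=n)
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return AlignedAAMatrix(list(self.taxa), rows)


def poisson_distance(a: str, b: str) -> float:
    """Poisson-corrected distance: d = -ln(1 - p), pairwise deletion.

    Columns where either row has a gap or ambiguous character are
    excluded from p's denominator.
    """
    if len(a) != len(b):
        raise ValueError("rows must be aligned (equal length)")
    n = mism = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _AA and y in _AA:
            n += 1
            if x != y:
                mism += 1
    if n < 1:
        raise ValueError("no pairwise-complete positions")
    p = mism / n
    if p >= 1.0:
        raise SaturationError(f"saturated pair (p = {p:.3f})")
    return -np.log1p(-p)


def distance_matrix(
    alignment: AlignedAAMatrix, deletion: str = "pairwise"
) -> tuple[list[str], np.ndarray]:
    """Poisson distance matrix over all taxon pairs.

    ``deletion='complete'`` first drops every column with any gap or
    ambiguity across all rows, fixing a single set of positions.
    """
    rows = alignment.rows
    if deletion == "complete":
        keep = [
            c
            for c in range(alignment.n_positions)
            if all(r[c] in _AA for r in rows)
        ]
        rows = ["".join(r[c] for c in keep) for r in rows]
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    n = len(rows)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = poisson_distance(rows[i], rows[j])
    return list(alignment.taxa), dm


@dataclass
class TreeNode:
    """A node of an (un)rooted tree; the NJ result has a trifurcating root."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name or ""]
        out: list[str] = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def sum_branch_lengths(self) -> float:
        total = 0.0
        for c, bl in self.children:
            total += bl + c.sum_branch_lengths()
        return total

    def newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(f"{c._newick()}:{bl:.6g}" for c, bl in self.children)
        label = (
            f"{self.support:.3g}"
            if self.support is not None
            else (self.name or "")
        )
        return f"({inner}){label}"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the leaf set of one side."""
        all_leaves = frozenset(self.leaves())
        parts: set[frozenset[str]] = set()

        def visit(node: "TreeNode") -> frozenset[str]:
            if not node.children:
                return frozenset([node.name or ""])
            below = frozenset().union(*(visit(c) for c, _ in node.children))
            if node is not self and 1 < len(below) < len(all_leaves) - 1:
                # canonical side: the one not containing the reference leaf
                ref = min(all_leaves)
                parts.add(below if ref not in below else all_leaves - below)
            return below

        visit(self)
        return parts


def neighbor_joining(taxa: Sequence[str], dm: np.ndarray) -> TreeNode:
    """Classic neighbor joining with deterministic tie-breaks.

    Joins minimize the Q criterion; ties go to the lexicographically
    smallest taxon-name pair.  Negative branch lengths are clamped to
    zero with the deficit moved to the sister edge.  The returned tree
    has a trifurcating root (unrooted semantics).
    """
    n = len(taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dm.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in taxa]
    labels: list[str] = list(taxa)  # lexicographic tie-break keys
    D = dm.astype(float).copy()

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, *sorted((labels[i], labels[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = clamp(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_label = min(labels[i], labels[j])
        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = du[keep]
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [new_label]
        D = D2

    # final trifurcation: closed-form star branch lengths
    (a, b, c) = range(3)
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    return TreeNode(
        children=[
            (nodes[a], max(la, 0.0)),
            (nodes[b], max(lb, 0.0)),
            (nodes[c], max(lc, 0.0)),
        ]
    )


def nj_from_alignment(
    alignment: AlignedAAMatrix, deletion: str = "pairwise"
) -> TreeNode:
    taxa, dm = distance_matrix(alignment, deletion)
    return neighbor_joining(taxa, dm)


def bootstrap_support(
    alignment: AlignedAAMatrix,
    n_replicates: int = 1000,
    seed: int = 0,
    deletion: str = "pairwise",
) -> TreeNode:
    """NJ tree of the full data with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_replicates`` times; the
    support of each internal bipartition of the full-data tree is the
    fraction of replicate trees containing it.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tree = nj_from_alignment(alignment, deletion)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        rep = alignment.resample_columns(rng)
        try:
            parts = nj_from_alignment(rep, deletion).bipartitions()
        except (SaturationError, ValueError):
            continue
        for bp in target:
            if bp in parts:
                counts[bp] += 1

    all_leaves = frozenset(tree.leaves())
    ref = min(all_leaves)

    def annotate(node: TreeNode) -> frozenset[str]:
        if not node.children:
            return frozenset([node.name or ""])
        below = frozenset().union(*(annotate(c) for c, _ in node.children))
        if node is not tree and 1 < len(below) < len(all_leaves) - 1:
            side = below if ref not in below else all_leaves - below
            node.support = counts[side] / n_replicates
        return below

    annotate(tree)
    return tree
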