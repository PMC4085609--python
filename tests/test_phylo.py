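"""Phylogenetics: Poisson distances, neighbor joining (checked against
scikit-bio), Newick emission and bootstrap supports."""

import numpy as np
import pytest

from repeatscape import phylo


class TestPoissonDistance:
    def test_known_value(self):
        # 2 mismatches over 10 compared sites
        a = "MKVLWAALLV"
        b = "MKVLWAALAA"
        assert phylo.poisson_distance(a, b) == pytest.approx(-np.log(0.8))

    def test_pairwise_deletion(self):
        # gap and X columns excluded from the denominator
        a = "MK-LXAAL"
        b = "MKVLWAAL"
        assert phylo.poisson_distance(a, b) == 0.0

    def test_identical(self):
        assert phylo.poisson_distance("MKVLW", "MKVLW") == 0.0

    def test_saturation(self):
        with pytest.raises(phylo.SaturationError):
            phylo.poisson_distance("AAAA", "CCCC")

    def test_unequal_length(self):
        with pytest.raises(ValueError):
            phylo.poisson_distance("MK", "MKV")


class TestDistanceMatrix:
    ALN = phylo.AlignedAAMatrix(
        ["a", "b", "c"],
        ["MKVLWAALLV", "MKVLWAALAA", "MKV-WAALAA"],
    )

    def test_pairwise_vs_complete(self):
        _, dm_p = phylo.distance_matrix(self.ALN, "pairwise")
        _, dm_c = phylo.distance_matrix(self.ALN, "complete")
        # complete deletion drops the gapped column for all pairs
        assert dm_c[0, 1] == pytest.approx(-np.log(1 - 2 / 9))
        assert dm_p[0, 1] == pytest.approx(-np.log(1 - 2 / 10))
        assert (dm_p.diagonal() == 0).all()
        np.testing.assert_allclose(dm_p, dm_p.T)

    def test_invalid_deletion(self):
        with pytest.raises(ValueError):
            phylo.distance_matrix(self.ALN, "jackknife")


def _skbio_nj(taxa, dm):
    """scikit-bio's NJ tree as an independent oracle."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    return nj(DistanceMatrix(dm, ids=taxa))


def _skbio_patristic(tree, taxa):
    n = len(taxa)
    out = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                d = tree.find(a).distance(tree.find(b))
                out[i, j] = out[j, i] = d
    return out


def _skbio_bipartitions(tree, taxa):
    """Non-trivial bipartitions of a scikit-bio tree, canonicalized to the
    side not containing the lexicographically smallest taxon."""
    all_leaves = frozenset(taxa)
    ref = min(all_leaves)
    parts = set()
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        if 1 < len(below) < len(all_leaves) - 1:
            parts.add(below if ref not in below else all_leaves - below)
    return parts


def _random_additive(n, rng):
    """A random binary tree over n taxa and its exact patristic matrix."""
    pool = [phylo.TreeNode(name=f"t{i}") for i in range(n)]
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), 2, replace=False))
        a, b = pool[int(i)], pool[int(j)]
        parent = phylo.TreeNode(
            children=[
                (a, float(rng.uniform(0.1, 2.0))),
                (b, float(rng.uniform(0.1, 2.0))),
            ]
        )
        pool = [p for k, p in enumerate(pool) if k not in (int(i), int(j))]
        pool.append(parent)
    root = pool[0]
    taxa = sorted(root.leaves())
    return taxa, _patristic(root, taxa)


def _patristic(tree, taxa):
    n = len(taxa)
    out = np.zeros((n, n))

    def walk(node):
        if not node.children:
            return {node.name: 0.0}
        below = {}
        subs = []
        for child, bl in node.children:
            d = walk(child)
            subs.append({k: v + bl for k, v in d.items()})
        for s in subs:
            below.update(s)
        for x in range(len(subs)):
            for y in range(x + 1, len(subs)):
                for ka, va in subs[x].items():
                    for kb, vb in subs[y].items():
                        i, j = taxa.index(ka), taxa.index(kb)
                        out[i, j] = out[j, i] = va + vb
        return below

    walk(tree)
    return out


class TestNeighborJoining:
    def test_four_taxon_additive_example(self):
        """Classic additive matrix: ((A:1,B:2):1,C:3,D:4) up to rooting."""
        taxa = ["A", "B", "C", "D"]
        dm = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 5],
                [6, 7, 5, 0],
            ],
            dtype=float,
        )
        tree = phylo.neighbor_joining(taxa, dm)
        np.testing.assert_allclose(_patristic(tree, taxa), dm, atol=1e-9)
        assert tree.bipartitions() == {frozenset({"C", "D"})}

    def test_matches_scikit_bio_on_additive_matrices(self):
        """On exactly additive inputs (no negative-branch clamping in
        either implementation) both NJ implementations reproduce the
        generating patristic distances."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            n = int(rng.integers(4, 9))
            taxa, dm = _random_additive(n, rng)
            ours = _patristic(phylo.neighbor_joining(taxa, dm), taxa)
            theirs = _skbio_patristic(_skbio_nj(taxa, dm), taxa)
            np.testing.assert_allclose(ours, dm, atol=1e-9)
            np.testing.assert_allclose(theirs, dm, atol=1e-9)

    def test_matches_scikit_bio_topology_on_noisy_matrices(self):
        """On noisy (non-additive) matrices the joined topology agrees
        with scikit-bio (branch-length clamping policies differ, so only
        bipartitions are compared)."""
        rng = np.random.default_rng(4242)
        for _ in range(5):
            n = int(rng.integers(5, 9))
            taxa, dm = _random_additive(n, rng)
            noise = rng.normal(0, 0.01, size=dm.shape)
            dm = dm + (noise + noise.T) / 2
            np.fill_diagonal(dm, 0.0)
            ours = phylo.neighbor_joining(taxa, dm).bipartitions()
            theirs = _skbio_bipartitions(_skbio_nj(taxa, dm), taxa)
            assert ours == theirs

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            phylo.neighbor_joining(["a", "b"], np.zeros((2, 2)))

    def test_deterministic_tie_break(self):
        taxa = ["a", "b", "c", "d"]
        dm = np.ones((4, 4)) - np.eye(4)
        t1 = phylo.neighbor_joining(taxa, dm).newick()
        t2 = phylo.neighbor_joining(taxa, dm).newick()
        assert t1 == t2

    def test_no_negative_branch_lengths(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            base = rng.uniform(0.1, 1.0, size=(n, n))
            dm = (base + base.T) / 2
            np.fill_diagonal(dm, 0.0)
            tree = phylo.neighbor_joining([f"t{i}" for i in range(n)], dm)

            def check(node):
                for child, bl in node.children:
                    assert bl >= 0.0
                    check(child)

            check(tree)


class TestNewick:
    def test_format(self):
        leaf_a = phylo.TreeNode(name="A")
        leaf_b = phylo.TreeNode(name="B")
        root = phylo.TreeNode(children=[(leaf_a, 1.0), (leaf_b, 2.5)])
        assert root.newick() == "(A:1,B:2.5);"

    def test_supports_as_internal_labels(self):
        inner = phylo.TreeNode(
            children=[(phylo.TreeNode(name="A"), 1.0), (phylo.TreeNode(name="B"), 1.0)],
            support=0.97,
        )
        root = phylo.TreeNode(children=[(inner, 0.5), (phylo.TreeNode(name="C"), 1.0)])
        assert root.newick() == "((A:1,B:1)0.97:0.5,C:1);"


class TestBootstrap:
    def _alignment(self, rng, n_cols=120):
        """Two clearly distinct clades of 3 taxa each."""
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        anc1 = rng.choice(aa, size=n_cols)
        anc2 = anc1.copy()
        flip = rng.random(n_cols) < 0.5
        anc2[flip] = rng.choice(aa, size=int(flip.sum()))

        def derive(anc):
            row = anc.copy()
            mut = rng.random(n_cols) < 0.05
            row[mut] = rng.choice(aa, size=int(mut.sum()))
            return "".join(row)

        taxa = ["a1", "a2", "a3", "b1", "b2", "b3"]
        rows = [derive(anc1) for _ in range(3)] + [derive(anc2) for _ in range(3)]
        return phylo.AlignedAAMatrix(taxa, rows)

    def test_clean_split_has_high_support(self, rng):
        aln = self._alignment(rng)
        tree = phylo.bootstrap_support(aln, n_replicates=100, seed=1)

        supports = []

        def collect(node):
            if node.support is not None:
                supports.append((frozenset(node.leaves()), node.support))
            for child, _ in node.children:
                collect(child)

        collect(tree)
        clade = {s for leaves, s in supports if leaves in
                 ({"a1", "a2", "a3"}, {"b1", "b2", "b3"})}
        assert clade and min(clade) >= 0.9

    def test_supports_in_unit_interval(self, rng):
        aln = self._alignment(rng)
        tree = phylo.bootstrap_support(aln, n_replicates=20, seed=2)

        def check(node):
            if node.support is not None:
                assert 0.0 <= node.support <= 1.0
            for child, _ in node.children:
                check(child)

        check(tree)

    def test_invalid_replicates(self):
        aln = phylo.AlignedAAMatrix(["a", "b", "c"], ["MK", "MK", "MV"])
        with pytest.raises(ValueError):
            phylo.bootstrap_support(aln, n_replicates=0)
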