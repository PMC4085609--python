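"""De novo discovery: interval calling, blastclust-style clustering,
consensus building and the abundance curve."""

import numpy as np
import pytest

from repeatscape import discovery, kmers
from repeatscape import simulate as sim
from repeatscape.io import GenomicInterval, SequenceRecord
from tests.conftest import random_dna


def _plant(rng, families, n_clones=6, clone_len=20_000, copies_per_clone=3):
    """Clones with planted, well-separated family copies; returns
    (clones, truth spans {clone_id: [(start, end, family_idx)]})."""
    clones, spans = [], {}
    for ci in range(n_clones):
        pieces, pos, rows = [], 0, []
        gap = clone_len // (copies_per_clone + 1)
        for j in range(copies_per_clone):
            bg = random_dna(rng, gap)
            pieces.append(bg)
            pos += len(bg)
            fi = (ci + j) % len(families)
            copy = sim.mutate_sequence(families[fi], 1.0e6, seed=rng.integers(2**31))
            pieces.append(copy)
            rows.append((pos, pos + len(copy), fi))
            pos += len(copy)
        pieces.append(random_dna(rng, gap))
        clones.append(SequenceRecord(f"c{ci}", "".join(pieces)))
        spans[f"c{ci}"] = rows
    return clones, spans


class TestFindRepeatIntervals:
    def test_planted_copies_recovered(self, rng):
        families = [random_dna(rng, 1500), random_dna(rng, 900)]
        clones, spans = _plant(rng, families)
        index = kmers.build_kmer_index(clones, 20)
        copies = discovery.find_repeat_intervals(clones, index, 4)
        by_clone = {}
        for c in copies:
            by_clone.setdefault(c.interval.scaffold_id, []).append(c)
        for cid, truth_rows in spans.items():
            found = by_clone.get(cid, [])
            assert len(found) == len(truth_rows)
            for (ts, te, _), copy in zip(truth_rows, sorted(
                    found, key=lambda c: c.interval.start)):
                # edge mutations can erode the ends (geometric tail) and
                # junction k-mers sharing k-1 copy bases can collide across
                # clones, so allow k-1 spillover per side; the interval must
                # still cover most of the planted copy
                assert copy.interval.start >= ts - 19
                assert copy.interval.end <= te + 19
                overlap = min(copy.interval.end, te) - max(copy.interval.start, ts)
                assert overlap >= 0.9 * (te - ts)

    def test_min_len_filter(self, rng):
        """A repeated 49-bp block is excluded by min_len = 50."""
        block = random_dna(rng, 49)
        bg = [random_dna(rng, 800) for _ in range(6)]
        s = bg[0] + block + bg[1] + block + bg[2] + block + bg[3] + block + bg[4]
        index = kmers.build_kmer_index([s], 20)
        copies = discovery.find_repeat_intervals(
            [SequenceRecord("s", s)], index, 4, min_len=50, merge_gap=0
        )
        assert copies == []
        copies = discovery.find_repeat_intervals(
            [SequenceRecord("s", s)], index, 4, min_len=49, merge_gap=0
        )
        assert len(copies) == 4

    def test_merge_gap(self, rng):
        """Two runs separated by <= merge_gap bp merge into one copy."""
        block = random_dna(rng, 400)
        spacer = random_dna(rng, 30)
        # block-spacer-block repeated 4 times; spacers all differ
        parts = []
        for _ in range(4):
            parts += [block, random_dna(rng, 30), block, random_dna(rng, 3000)]
        s = "".join(parts)
        index = kmers.build_kmer_index([s], 20)
        merged = discovery.find_repeat_intervals(
            [SequenceRecord("s", s)], index, 4, merge_gap=50
        )
        split = discovery.find_repeat_intervals(
            [SequenceRecord("s", s)], index, 4, merge_gap=10
        )
        assert len(merged) == 4
        assert len(split) == 8


class TestClustering:
    def _copies(self, rng, n_families=3, per_family=6, length=1200):
        ancestors = [random_dna(rng, length) for _ in range(n_families)]
        copies = []
        for fi, anc in enumerate(ancestors):
            for j in range(per_family):
                seq = sim.mutate_sequence(anc, 1.5e6, seed=rng.integers(2**31))
                copies.append(
                    discovery.RepeatCopy(
                        f"f{fi}m{j}", GenomicInterval("x", 1 + j, 1 + j + length), seq
                    )
                )
        return copies, ancestors

    def test_families_recovered(self, rng):
        copies, _ = self._copies(rng)
        families, report = discovery.cluster_copies(copies, min_copies=5)
        assert len(families) == 3
        for fam in families:
            # every family is pure: all members from one planted family
            prefixes = {m.copy_id[:2] for m in fam.members}
            assert len(prefixes) == 1
            assert fam.copy_number == 6
        assert report.n_sequences == 18
        assert report.n_unclustered == 0
        assert report.n_clusters == 3

    def test_report_conservation_identity(self, rng):
        copies, _ = self._copies(rng, per_family=3)
        singles = [
            discovery.RepeatCopy(
                f"s{i}", GenomicInterval("y", i + 1, i + 1300),
                random_dna(rng, 1200),
            )
            for i in range(4)
        ]
        _, report = discovery.cluster_copies(copies + singles, min_copies=5)
        assert report.n_unclustered + sum(report.cluster_sizes) == report.n_sequences

    def test_min_copies_threshold(self, rng):
        copies, _ = self._copies(rng, n_families=1, per_family=4)
        families, report = discovery.cluster_copies(copies, min_copies=5)
        assert families == []  # visible in the report, below the family bar
        assert report.n_clusters == 1
        families, _ = discovery.cluster_copies(copies, min_copies=4)
        assert len(families) == 1

    def test_truncated_copy_links_by_shorter_coverage(self, rng):
        """A half-length fragment still joins its family (coverage is
        measured on the shorter sequence)."""
        anc = random_dna(rng, 2000)
        full = [
            discovery.RepeatCopy(
                f"m{j}", GenomicInterval("x", j + 1, j + 2001),
                sim.mutate_sequence(anc, 1.0e6, seed=j),
            )
            for j in range(5)
        ]
        frag = discovery.RepeatCopy(
            "zfrag", GenomicInterval("x", 50, 1050),
            sim.mutate_sequence(anc[400:1400], 1.0e6, seed=99),
        )
        families, _ = discovery.cluster_copies(full + [frag], min_copies=5)
        assert len(families) == 1
        assert families[0].copy_number == 6

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            discovery.cluster_copies([])

    def test_report_to_frame_layout(self, rng):
        copies, _ = self._copies(rng)
        _, report = discovery.cluster_copies(copies)
        frame = report.to_frame()
        assert list(frame.columns) == ["statistic", "value"]
        assert frame.iloc[0].statistic == "Total number of sequences"
        assert frame.iloc[0].value == 18


class TestConsensus:
    def test_substitution_only_majority_recovers_ancestor(self, rng):
        """With equal-length diverged members the majority consensus
        converges to the ancestor (few multi-member errors at d = 0.03)."""
        anc = random_dna(rng, 1500)
        members = [
            discovery.RepeatCopy(
                f"m{j}", GenomicInterval("x", j + 1, j + 1501),
                sim.mutate_sequence(anc, 1.5e6, seed=j),
            )
            for j in range(15)
        ]
        fam = discovery.RepeatFamily("f", members)
        cons = discovery.build_consensus(fam)
        mismatch = sum(a != b for a, b in zip(cons, anc))
        assert mismatch / len(anc) < 0.005

    def test_single_member_warns(self):
        fam = discovery.RepeatFamily(
            "f",
            [discovery.RepeatCopy("m", GenomicInterval("x", 1, 9), "ACGTACGT")],
        )
        with pytest.warns(UserWarning, match="single member"):
            assert discovery.build_consensus(fam) == "ACGTACGT"

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            discovery.build_consensus(discovery.RepeatFamily("f", []))


class TestAbundanceCurve:
    def _fam(self, fid, n, length):
        members = [
            discovery.RepeatCopy(
                f"{fid}m{j}", GenomicInterval("x", j + 1, j + 1 + length), "A" * length
            )
            for j in range(n)
        ]
        return discovery.RepeatFamily(fid, members)

    def test_half_share_counts(self):
        fams = [
            self._fam("big", 10, 1000),   # 10,000 bp
            self._fam("mid", 5, 1000),    # 5,000 bp
            self._fam("sml", 2, 1000),    # 2,000 bp
        ]
        curve = discovery.family_abundance_curve(fams)
        # 10,000 of 17,000 bp > 50% with the first family alone
        assert curve.families_for_50pct_bp == 1
        assert curve.families_for_50pct_copies == 1
        assert curve.table.iloc[0].family_id == "big"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            discovery.family_abundance_curve([])
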