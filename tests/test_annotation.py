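"""Homology masking, overlap resolution (including a per-base oracle),
composition summaries and repeat density."""

import numpy as np
import pytest

from repeatscape import annotation as ann
from repeatscape import simulate as sim
from repeatscape.io import (
    AnnotationError,
    GenomicInterval,
    RepeatAnnotation,
    SequenceRecord,
)
from tests.conftest import random_dna


class TestLibraryLabels:
    def test_parse(self):
        rec = SequenceRecord("lib1", "ACGT", description="class=Ty1-Copia family=HaC1")
        assert ann.parse_library_label(rec) == ("Ty1-Copia", "HaC1")

    def test_family_defaults_to_id(self):
        rec = SequenceRecord("lib1", "ACGT", description="class=MITE")
        assert ann.parse_library_label(rec) == ("MITE", "lib1")

    def test_missing_class_names_record(self):
        rec = SequenceRecord("lib1", "ACGT")
        with pytest.raises(AnnotationError, match="lib1"):
            ann.parse_library_label(rec)


class TestReverseComplement:
    def test_basic(self):
        assert ann.reverse_complement("ACGTN") == "NACGT"
        s = "GATTACA"
        assert ann.reverse_complement(ann.reverse_complement(s)) == s


class TestMasking:
    def _library(self, seq, klass="Ty1-Copia", family="fam1"):
        return [
            SequenceRecord("L", seq, description=f"class={klass} family={family}")
        ]

    def test_planted_copy_found_with_boundaries(self, rng):
        lib = random_dna(rng, 1000)
        copy = sim.mutate_sequence(lib, 2.0e6, seed=5)  # ~4% diverged
        left, right = random_dna(rng, 700), random_dna(rng, 700)
        scaffold = SequenceRecord("s", left + copy + right)
        hits = ann.mask_with_library([scaffold], self._library(lib))
        assert len(hits) == 1
        h = hits[0]
        assert h.repeat_class == "Ty1-Copia" and h.family_id == "fam1"
        assert abs(h.interval.start - 700) <= 15
        assert abs(h.interval.end - 1700) <= 15
        assert h.score >= 0.9

    def test_reverse_strand_found(self, rng):
        lib = random_dna(rng, 800)
        copy = ann.reverse_complement(sim.mutate_sequence(lib, 1.0e6, seed=6))
        scaffold = SequenceRecord("s", random_dna(rng, 500) + copy + random_dna(rng, 500))
        hits = ann.mask_with_library([scaffold], self._library(lib))
        assert len(hits) >= 1
        assert any(h.interval.strand == "-" for h in hits)

    def test_diverged_beyond_threshold_not_found(self, rng):
        lib = random_dna(rng, 800)
        scaffold = SequenceRecord(
            "s", random_dna(rng, 500) + random_dna(rng, 800) + random_dna(rng, 500)
        )
        assert ann.mask_with_library([scaffold], self._library(lib)) == []

    def test_min_len(self, rng):
        lib = random_dna(rng, 45)
        scaffold = SequenceRecord("s", random_dna(rng, 300) + lib + random_dna(rng, 300))
        assert (
            ann.mask_with_library([scaffold], self._library(lib), min_len=50) == []
        )
        hits = ann.mask_with_library([scaffold], self._library(lib), min_len=40)
        assert len(hits) == 1


def per_base_oracle(annotations):
    """Reference overlap resolver: every base goes to the best annotation
    covering it (score, then length, then family), then maximal runs of
    one owner become intervals."""
    def key(a):
        return (
            -a.score,
            -len(a.interval),
            a.family_id or "",
            a.repeat_class,
            a.interval.scaffold_id,
            a.interval.start,
            a.interval.end,
        )

    ranked = sorted(annotations, key=key)
    by_scaffold = {}
    for rank, a in enumerate(ranked):
        by_scaffold.setdefault(a.interval.scaffold_id, []).append((rank, a))
    out = []
    for scaf, items in by_scaffold.items():
        end = max(a.interval.end for _, a in items)
        owner = np.full(end, -1, dtype=int)
        for rank, a in sorted(items, reverse=True):
            owner[a.interval.start : a.interval.end] = rank
        pos = 0
        while pos < end:
            if owner[pos] == -1:
                pos += 1
                continue
            run_start, rank = pos, owner[pos]
            while pos < end and owner[pos] == rank:
                pos += 1
            a = ranked[rank]
            out.append(
                RepeatAnnotation(
                    GenomicInterval(scaf, run_start, pos, a.interval.strand),
                    a.repeat_class,
                    a.family_id,
                    a.score,
                )
            )
    out.sort(key=lambda a: (a.interval.scaffold_id, a.interval.start, a.interval.end))
    return out


def _assert_matches_oracle(annotations):
    got = ann.resolve_overlaps(annotations)
    expect = per_base_oracle(annotations)
    assert [
        (a.interval, a.repeat_class, a.family_id, a.score) for a in got
    ] == [(a.interval, a.repeat_class, a.family_id, a.score) for a in expect]


class TestResolveOverlaps:
    def test_nested_lower_score_split(self):
        outer = RepeatAnnotation(
            GenomicInterval("s", 0, 100), "Ty1-Copia", "low", 0.8
        )
        inner = RepeatAnnotation(GenomicInterval("s", 40, 60), "SSR", "hi", 1.1)
        res = ann.resolve_overlaps([outer, inner])
        spans = [(a.interval.start, a.interval.end, a.family_id) for a in res]
        assert spans == [(0, 40, "low"), (40, 60, "hi"), (60, 100, "low")]

    def test_union_preserved_and_disjoint(self, rng):
        anns = [
            RepeatAnnotation(
                GenomicInterval("s", int(s), int(s) + int(w)),
                "novel",
                f"f{i}",
                float(rng.random()),
            )
            for i, (s, w) in enumerate(
                zip(rng.integers(0, 5000, 60), rng.integers(1, 400, 60))
            )
        ]
        res = ann.resolve_overlaps(anns)
        cover_in = np.zeros(6000, dtype=bool)
        cover_out = np.zeros(6000, dtype=bool)
        for a in anns:
            cover_in[a.interval.start : a.interval.end] = True
        for a in res:
            assert not cover_out[a.interval.start : a.interval.end].any()  # disjoint
            cover_out[a.interval.start : a.interval.end] = True
        np.testing.assert_array_equal(cover_in, cover_out)

    def test_matches_per_base_oracle_small(self):
        anns = [
            RepeatAnnotation(GenomicInterval("s", 0, 50), "novel", "a", 0.9),
            RepeatAnnotation(GenomicInterval("s", 30, 80), "novel", "b", 0.95),
            RepeatAnnotation(GenomicInterval("s", 70, 120), "novel", "c", 0.9),
            RepeatAnnotation(GenomicInterval("t", 10, 40), "SSR", None, 1.1),
        ]
        _assert_matches_oracle(anns)

    def test_tie_break_is_deterministic(self):
        a = RepeatAnnotation(GenomicInterval("s", 0, 60), "novel", "aaa", 0.9)
        b = RepeatAnnotation(GenomicInterval("s", 40, 100), "novel", "bbb", 0.9)
        res1 = ann.resolve_overlaps([a, b])
        res2 = ann.resolve_overlaps([b, a])
        assert [x.interval for x in res1] == [x.interval for x in res2]
        # equal score and length: lexicographic family wins the contest
        assert res1[0].family_id == "aaa"
        assert res1[0].interval == GenomicInterval("s", 0, 60)


class TestComposition:
    def test_table_percentages(self):
        anns = [
            RepeatAnnotation(GenomicInterval("s", 0, 700), "Ty1-Copia", "a"),
            RepeatAnnotation(GenomicInterval("s", 800, 1100), "Ty3-Gypsy", "b"),
        ]
        summ = ann.summarize_composition(anns, dataset_bp=2000, genome_size=1e6)
        t = summ.table.set_index("repeat_class")
        assert t.loc["Ty1-Copia", "pct_of_genome"] == pytest.approx(35.0)
        assert t.loc["Ty1-Copia", "pct_of_repetitive"] == pytest.approx(70.0)
        assert t.loc["Ty1-Copia", "genome_bp"] == pytest.approx(350_000)
        assert t.loc["Total Repetitive", "bac_bp"] == 1000
        assert summ.pct_repetitive_of_dataset == pytest.approx(50.0)

    def test_conservation_identities(self, rng):
        """Class bp sums to the total row; percentages of repetitive sum
        to 100 over represented classes."""
        anns = [
            RepeatAnnotation(
                GenomicInterval("s", int(i * 100), int(i * 100 + 50)),
                klass,
            )
            for i, klass in enumerate(
                ["SSR", "MITE", "novel", "rDNA", "Ty3-Gypsy", "SSR"]
            )
        ]
        summ = ann.summarize_composition(anns, dataset_bp=10_000)
        t = summ.table
        body = t[t.repeat_class != "Total Repetitive"]
        assert body.bac_bp.sum() == summ.total_repetitive_bp
        assert body.pct_of_repetitive.sum() == pytest.approx(100.0)

    def test_zero_annotations(self):
        summ = ann.summarize_composition([], dataset_bp=1000)
        assert summ.total_repetitive_bp == 0
        assert (summ.table.bac_bp == 0).all()

    def test_zero_dataset_rejected(self):
        with pytest.raises(ValueError):
            ann.summarize_composition([], dataset_bp=0)


class TestDensity:
    def test_midpoint_assignment(self):
        regions = [
            (GenomicInterval("s", 0, 10_000), "dense"),
            (GenomicInterval("s", 10_000, 20_000), "poor"),
        ]
        anns = [
            RepeatAnnotation(GenomicInterval("s", 0, 500), "novel"),
            RepeatAnnotation(GenomicInterval("s", 2000, 2400), "novel"),
            RepeatAnnotation(GenomicInterval("s", 15_000, 15_100), "novel"),
        ]
        rep = ann.repeat_density(anns, regions)
        assert rep.bp_per_repeat_dense == pytest.approx(5000)
        assert rep.bp_per_repeat_poor == pytest.approx(10_000)
        assert rep.bp_per_repeat_avg == pytest.approx(20_000 / 3)

    def test_empty_class_reports_none(self):
        regions = [(GenomicInterval("s", 0, 1000), "dense")]
        rep = ann.repeat_density([], regions)
        assert rep.bp_per_repeat_dense is None

    def test_unknown_region_class(self):
        with pytest.raises(ValueError):
            ann.repeat_density([], [(GenomicInterval("s", 0, 10), "weird")])


class TestMaskSequence:
    def test_soft_masking(self):
        rec = SequenceRecord("s", "ACGTACGTAC")
        anns = [RepeatAnnotation(GenomicInterval("s", 2, 5), "SSR")]
        assert ann.mask_sequence(rec, anns) == "ACgtaCGTAC"
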