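import random

import pytest

from compoundalign.compound_matcher import CompoundAlignment, CompoundMapping
from compoundalign.config import MatchConfig
from compoundalign.evaluation import (
    agreement,
    categorize,
    f_measure,
    score,
    suggest_logical_definitions,
    threshold_sweep,
)
from compoundalign.obo_io import IntersectionElement, OntologyModel, Term
from compoundalign.reference_builder import ReferenceAlignment


def _mapping(x, y, z, sim=1.0):
    return CompoundMapping(x=x, y=y, z=z, sim1=sim, sim2=sim, similarity=sim)


def _ref(pairs):
    ref = ReferenceAlignment(prefix1="Y", prefix2="Z")
    for x, y, z in pairs:
        ref.mappings[x] = frozenset((y, z))
    return ref


class TestScore:
    def test_identical_alignment_scores_one(self):
        rows = [("S:1", "Y:1", "Z:1"), ("S:2", "Y:2", "Z:2")]
        aln = CompoundAlignment(mappings=[_mapping(*r) for r in rows])
        rep = score(aln, _ref(rows))
        assert (rep.precision, rep.recall, rep.f_measure) == (1.0, 1.0, 1.0)

    def test_hand_counts(self):
        # |A| = 5, |R| = 6, 3 matched: P = 0.6, Rec = 0.5, F = 6/11
        ref_rows = [(f"S:{i}", f"Y:{i}", f"Z:{i}") for i in range(6)]
        aln_rows = ref_rows[:3] + [("S:7", "Y:7", "Z:7"), ("S:8", "Y:8", "Z:8")]
        rep = score(CompoundAlignment(mappings=[_mapping(*r) for r in aln_rows]),
                    _ref(ref_rows))
        assert rep.precision == pytest.approx(0.6)
        assert rep.recall == pytest.approx(0.5)
        assert rep.f_measure == pytest.approx(6 / 11)
        assert (rep.n_alignment, rep.n_reference, rep.n_intersection) == (5, 6, 3)

    def test_swapped_targets_still_count_as_matched(self):
        aln = CompoundAlignment(mappings=[_mapping("S:1", "Z:1", "Y:1")])
        rep = score(aln, _ref([("S:1", "Y:1", "Z:1")]))
        assert rep.precision == 1.0 and rep.recall == 1.0

    def test_empty_alignment_reports_zero_with_warning(self, caplog):
        rep = score(CompoundAlignment(), _ref([("S:1", "Y:1", "Z:1")]))
        assert rep.precision == 0.0 and rep.recall == 0.0 and rep.f_measure == 0.0

    def test_matched_counts_are_integers_times_denominators(self):
        rng = random.Random(3)
        ref_rows = [(f"S:{i}", f"Y:{i}", f"Z:{i}") for i in range(10)]
        aln_rows = rng.sample(ref_rows, 4) + [("S:90", "Y:9", "Z:1")]
        rep = score(CompoundAlignment(mappings=[_mapping(*r) for r in aln_rows]),
                    _ref(ref_rows))
        assert rep.precision * rep.n_alignment == pytest.approx(round(
            rep.precision * rep.n_alignment))
        assert rep.recall * rep.n_reference == pytest.approx(round(
            rep.recall * rep.n_reference))

    def test_f_measure_equals_independent_harmonic_formula(self):
        rng = random.Random(0)
        for _ in range(100):
            p, r = rng.random(), rng.random()
            expected = 0.0 if p + r == 0 else (2 * p * r) / (p + r)
            assert f_measure(p, r) == pytest.approx(expected, abs=1e-15)


class TestCategorize:
    REF = [("S:1", "Y:1", "Z:1"), ("S:2", "Y:2", "Z:2")]

    def test_three_way_split(self):
        aln = CompoundAlignment(mappings=[
            _mapping("S:1", "Y:1", "Z:1"),   # correct
            _mapping("S:2", "Y:9", "Z:2"),   # conflict: source in ref, pair differs
            _mapping("S:3", "Y:3", "Z:3"),   # missing: source not in ref
        ])
        cat = categorize(aln, _ref(self.REF))
        assert [m.x for m in cat.correct] == ["S:1"]
        assert [m.x for m in cat.conflict] == ["S:2"]
        assert [m.x for m in cat.missing] == ["S:3"]

    def test_partition_conserves_alignment_size(self, small_triple):
        from compoundalign.compound_matcher import match_compound
        src, anat, qual, truth = small_triple
        aln = match_compound(src, anat, qual, MatchConfig(t1=0.2, t2=0.6))
        cat = categorize(aln, truth)
        assert len(cat.correct) + len(cat.missing) + len(cat.conflict) == len(aln)


class TestSuggestLogicalDefinitions:
    @pytest.fixture
    def source(self):
        m = OntologyModel(ontology_id="mp")
        m.add(Term(id="MP:1", label="undefined class"))
        m.add(Term(id="MP:2", label="agreeing definition", intersection_of=[
            IntersectionElement(filler="Z:2"),
            IntersectionElement(relation="inheres_in", filler="Y:2")]))
        m.add(Term(id="MP:3", label="differing definition", intersection_of=[
            IntersectionElement(filler="Z:9"),
            IntersectionElement(relation="inheres_in", filler="Y:3")]))
        m.add(Term(id="MP:4", label="long definition", intersection_of=[
            IntersectionElement(filler="Z:4"),
            IntersectionElement(relation="inheres_in", filler="Y:4"),
            IntersectionElement(relation="towards", filler="Y:5")]))
        return m

    def test_new_conflict_and_agreeing_classification(self, source):
        aln = CompoundAlignment(mappings=[
            _mapping("MP:1", "Y:1", "Z:1"),
            _mapping("MP:2", "Y:2", "Z:2"),
            _mapping("MP:3", "Y:3", "Z:3"),
            _mapping("MP:4", "Y:4", "Z:4"),
        ])
        rep = suggest_logical_definitions(aln, source)
        assert [m.x for m in rep.new_definitions] == ["MP:1"]
        by_x = {c.mapping.x: c.non_ternary for c in rep.conflicts}
        # MP:2 agrees with its definition: in neither list
        assert by_x == {"MP:3": False, "MP:4": True}


class TestThresholdSweep:
    def test_recall_non_increasing_and_normalization_bounds(self, small_triple):
        src, anat, qual, truth = small_triple
        sweep = threshold_sweep(src, anat, qual,
                                [0.1, 0.2, 0.3, 0.4, 0.5, 0.6], [0.7, 0.9], truth)
        recalls = list(sweep.step1["recall"])
        assert recalls == sorted(recalls, reverse=True)
        normed = list(sweep.step1["n_mappings_norm"])
        assert max(normed) == 1.0 and min(normed) == 0.0
        counts = list(sweep.step1["n_mappings"])
        assert counts == sorted(counts, reverse=True)

    def test_full_grid_has_scores_for_every_combination(self, small_triple):
        src, anat, qual, truth = small_triple
        sweep = threshold_sweep(src, anat, qual, [0.2, 0.4], [0.7, 0.9], truth)
        assert len(sweep.full) == 4
        assert set(sweep.full.columns) >= {"t1", "t2", "precision", "recall", "f_measure"}

    def test_single_point_grid_normalization_is_degenerate(self, small_triple):
        src, anat, qual, truth = small_triple
        sweep = threshold_sweep(src, anat, qual, [0.4], [0.9], truth)
        assert list(sweep.step1["n_mappings_norm"]) == [0.0]
        assert bool(sweep.step1["norm_degenerate"].iloc[0])


def test_agreement_is_the_proportion_of_identical_labels():
    assert agreement(["a", "b", "c", "a"], ["a", "b", "x", "a"]) == 0.75
    with pytest.raises(ValueError):
        agreement(["a"], [])
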