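import pytest

from compoundalign.compound_matcher import (
    match_compound,
    reduce_search_space,
    similarity_step1,
    similarity_step3,
    step1_recall_selection,
    step3_precision_selection,
)
from compoundalign.config import MatchConfig
from compoundalign.lexicon import build_lexicon
from compoundalign.obo_io import OntologyModel, Term
from compoundalign.synthetic_data import SynthSpec, generate_models

from oracle import brute_force_match


def _model(oid, terms):
    m = OntologyModel(ontology_id=oid)
    for tid, label, *syns in terms:
        m.add(Term(id=tid, label=label, synonyms=list(syns[0]) if syns else []))
    return m


class TestSimilarityFormulas:
    def test_recall_similarity_hand_example(self):
        # shared {a} over target words {a, d} with EC(a)=0.5, EC(d)=0.8
        ec = {"a": 0.5, "b": 0.3, "c": 0.2, "d": 0.8}
        sim = similarity_step1(frozenset("abc"), frozenset("ad"), ec)
        assert sim == pytest.approx(0.5 / 1.3, abs=1e-12)

    def test_target_fully_contained_scores_one(self):
        ec = {"aortic": 0.9, "valve": 0.8, "stenosis": 1.0}
        assert similarity_step1(
            frozenset(["aortic", "valve", "stenosis"]),
            frozenset(["aortic", "valve"]), ec) == pytest.approx(1.0)

    def test_disjoint_labels_score_zero(self):
        assert similarity_step1(frozenset("ab"), frozenset("cd"), {}) == 0.0

    def test_precision_similarity_hand_example(self):
        # residual {c} vs target {c, d}: target is longer, EC(c)=0.6, EC(d)=0.4
        ec_t2 = {"c": 0.6, "d": 0.4}
        sim = similarity_step3(frozenset("c"), frozenset("cd"), {}, ec_t2)
        assert sim == pytest.approx(0.6 / 1.0, abs=1e-12)

    def test_longer_residual_uses_source_index(self):
        ec_src = {"a": 1.0, "b": 0.5, "c": 0.25}
        ec_t2 = {"a": 0.1}
        sim = similarity_step3(frozenset("abc"), frozenset("a"), ec_src, ec_t2)
        assert sim == pytest.approx(1.0 / 1.75)

    def test_tie_in_length_uses_target_index(self):
        ec_src = {"a": 0.2, "x": 0.2}
        ec_t2 = {"a": 0.5, "b": 0.5}
        sim = similarity_step3(frozenset("ax"), frozenset("ab"), ec_src, ec_t2)
        assert sim == pytest.approx(0.5)


class TestSteps:
    @pytest.fixture
    def hp_fma(self, hp_fma_pato):
        hp, fma, _ = hp_fma_pato
        cfg = MatchConfig()
        return build_lexicon(hp, cfg), build_lexicon(fma, cfg)

    def test_step1_keeps_best_name_pair_above_threshold(self, hp_fma):
        hp_lex, fma_lex = hp_fma
        mappings = step1_recall_selection(hp_lex, fma_lex, 0.4)
        by_pair = {(m.source, m.target): m for m in mappings}
        m = by_pair[("HP:0001650", "FMA:7236")]
        assert m.sim1 == pytest.approx(1.0)

    def test_reduction_leaves_residual_words(self, hp_fma):
        hp_lex, fma_lex = hp_fma
        reduced = reduce_search_space(step1_recall_selection(hp_lex, fma_lex, 0.4))
        residuals = {m.source: m.residual for m in reduced}
        assert residuals["HP:0001650"].raw_tokens == ("stenosis",)

    def test_fully_consumed_source_label_dropped(self):
        src = _model("s", [("S:1", "forehead")])
        t1 = _model("t", [("T:1", "forehead")])
        cfg = MatchConfig()
        reduced = reduce_search_space(
            step1_recall_selection(build_lexicon(src, cfg), build_lexicon(t1, cfg), 0.4))
        assert reduced == []

    def test_unmapped_source_class_absent_downstream(self, hp_fma):
        hp_lex, fma_lex = hp_fma
        reduced = reduce_search_space(step1_recall_selection(hp_lex, fma_lex, 0.4))
        # "Aplasia of the hallux" maps only via FMA's synonym; no PATO partner later,
        # but here: a source with no step-1 mapping at a high threshold disappears
        high = reduce_search_space(step1_recall_selection(hp_lex, fma_lex, 1.0))
        assert {m.source for m in high} <= {m.source for m in reduced}

    def test_final_threshold_filters_on_average(self):
        # sim1 = 1.0 and sim2 = 0.5 average to 0.75: kept at T2 0.7, cut at 0.9
        src = _model("s", [("S:1", "alpha beta")])
        t1 = _model("t", [("T:1", "alpha")])
        t2 = _model("u", [("U:1", "beta gamma")])
        cfg = MatchConfig()
        s_lex, t1_lex, t2_lex = (build_lexicon(m, cfg) for m in (src, t1, t2))
        reduced = reduce_search_space(step1_recall_selection(s_lex, t1_lex, 0.4))
        kept = step3_precision_selection(reduced, s_lex, t2_lex, 0.7)
        cut = step3_precision_selection(reduced, s_lex, t2_lex, 0.9)
        assert len(kept) == 1 and kept.mappings[0].similarity == pytest.approx(0.75)
        assert len(cut) == 0


class TestMatchCompound:
    def test_requires_three_distinct_prefixes(self, hp_fma_pato):
        hp, fma, _ = hp_fma_pato
        with pytest.raises(ValueError, match="distinct prefixes"):
            match_compound(hp, fma, fma)

    def test_empty_source_is_an_error(self, hp_fma_pato):
        _, fma, pato = hp_fma_pato
        with pytest.raises(ValueError):
            match_compound(OntologyModel(ontology_id="empty"), fma, pato)

    def test_similarities_lie_in_unit_interval(self, small_triple):
        src, anat, qual, _ = small_triple
        aln = match_compound(src, anat, qual, MatchConfig(t1=0.1, t2=0.1))
        for m in aln.mappings:
            assert 0.0 <= m.sim1 <= 1.0 + 1e-12
            assert 0.0 <= m.sim2 <= 1.0 + 1e-12
            assert m.similarity == pytest.approx((m.sim1 + m.sim2) / 2, abs=1e-12)

    def test_deterministic_across_runs(self, small_triple):
        src, anat, qual, _ = small_triple
        a = match_compound(src, anat, qual)
        b = match_compound(src, anat, qual)
        assert a.mappings == b.mappings

    def test_invariant_to_term_order(self, small_triple):
        src, anat, qual, _ = small_triple
        shuffled = OntologyModel(ontology_id=src.ontology_id)
        for t in sorted(src.terms.values(), key=lambda t: t.label):
            shuffled.add(t)
        assert match_compound(src, anat, qual).mappings == \
            match_compound(shuffled, anat, qual).mappings

    def test_provenance_records_order_and_thresholds(self, hp_fma_pato):
        hp, fma, pato = hp_fma_pato
        prov = match_compound(hp, fma, pato).provenance
        assert (prov.source_id, prov.target1_id, prov.target2_id) == ("hp", "fma", "pato")
        assert (prov.t1, prov.t2) == (0.4, 0.9)

    @pytest.mark.parametrize("grids", [
        ("t1", [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]),
        ("t2", [0.7, 0.8, 0.9]),
    ])
    def test_mapping_count_non_increasing_in_thresholds(self, small_triple, grids):
        src, anat, qual, _ = small_triple
        which, grid = grids
        counts = []
        for t in grid:
            cfg = MatchConfig(t1=t, t2=0.5) if which == "t1" else MatchConfig(t1=0.2, t2=t)
            counts.append(len(match_compound(src, anat, qual, cfg)))
        assert counts == sorted(counts, reverse=True)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_indexed_matcher_equals_brute_force(self, seed):
        spec = SynthSpec(n_source=25, anatomy_vocab_size=25, quality_vocab_size=8,
                         p_add=0.4, p_var=0.3, p_syn=0.3, seed=seed)
        src, anat, qual, _ = generate_models(spec)
        cfg = MatchConfig(t1=0.3, t2=0.7)
        fast = {(m.x, m.y, m.z): (m.sim1, m.sim2, m.similarity)
                for m in match_compound(src, anat, qual, cfg).mappings}
        slow = {(x, y, z): (s1, s2, sim)
                for x, y, z, s1, s2, sim in brute_force_match(src, anat, qual, cfg)}
        assert fast.keys() == slow.keys()
        for key, (s1, s2, sim) in fast.items():
            assert slow[key][0] == pytest.approx(s1, abs=1e-12)
            assert slow[key][1] == pytest.approx(s2, abs=1e-12)
            assert slow[key][2] == pytest.approx(sim, abs=1e-12)
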