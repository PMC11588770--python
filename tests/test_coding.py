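"""Transcript scoring, category coding, ARC, and span-composite rules."""

import numpy as np
import pandas as pd
import pytest

from mptrecall.coding import (
    ArcResult,
    ScoredRecall,
    SpanRecord,
    StudyList,
    Transcript,
    arc_score,
    code_free_then_cued,
    code_pair_clustering,
    cronbach_alpha,
    match_response,
    score_transcript,
    wmc_composite,
)

from .oracles import arc_reference


@pytest.fixture
def exp1_list():
    return StudyList(
        pairs=(("knife", "fork", "utensils"), ("salt", "pepper", "spices")),
        singletons=(("chair", "furniture"), ("piano", "instruments")),
    )


@pytest.fixture
def exp2_list():
    return StudyList(
        pairs=(("ocean", "wave", "p0"), ("bread", "butter", "p1"),
               ("night", "star", "p2")),
        singletons=(),
    )


class TestMatchResponse:
    def test_exact_match(self):
        assert match_response("fork", {"knife", "fork", "salt"}) == "fork"

    def test_one_typo(self):
        assert match_response("knif", {"knife", "fork"}) == "knife"

    def test_beyond_one_typo(self):
        assert match_response("spoon", {"knife", "fork"}) is None

    def test_case_fold_and_trim(self):
        assert match_response("  Fork ", {"fork"}) == "fork"

    def test_ambiguous_tie_prefers_unrecalled(self):
        # "cot" is distance 1 from both; only "cat" is still unrecalled
        assert match_response("cot", {"cat", "cut"}, already_matched=["cut"]) == "cat"

    def test_unresolvable_tie_is_no_match(self):
        assert match_response("cot", {"cat", "cut"}) is None

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            match_response("x", set())


class TestScoreTranscript:
    def test_clean_recall(self, exp1_list):
        s = score_transcript(Transcript("p", ("knife", "fork")), exp1_list)
        assert s.matched == ("knife", "fork")
        assert s.intrusions == () and s.duplicates == ()

    def test_duplicates_and_intrusions(self, exp1_list):
        s = score_transcript(
            Transcript("p", ("knife", "knife", "xyzzy")), exp1_list
        )
        assert s.matched == ("knife",)
        assert s.duplicates == ("knife",)
        assert s.intrusions == ("xyzzy",)

    def test_empty_transcript_is_zero_recall(self, exp1_list):
        s = score_transcript(Transcript("p", ()), exp1_list)
        assert s.matched == ()


class TestPairClusteringCoding:
    def test_worked_example(self, exp1_list):
        s = ScoredRecall(("knife", "fork", "pepper", "chair"))
        c = code_pair_clustering(s, exp1_list)
        np.testing.assert_array_equal(c["pairs"], [1, 0, 1, 0])
        np.testing.assert_array_equal(c["singletons"], [1, 1])

    def test_separated_pair_is_e2(self, exp1_list):
        s = ScoredRecall(("knife", "chair", "fork"))
        c = code_pair_clustering(s, exp1_list)
        np.testing.assert_array_equal(c["pairs"], [0, 1, 0, 1])

    def test_empty_recall_all_e4_f2(self, exp1_list):
        c = code_pair_clustering(ScoredRecall(()), exp1_list)
        np.testing.assert_array_equal(c["pairs"], [0, 0, 0, 2])
        np.testing.assert_array_equal(c["singletons"], [0, 2])

    def test_counts_partition_item_set(self, exp1_list):
        rng = np.random.default_rng(0)
        words = list(exp1_list.all_words())
        for _ in range(50):
            k = int(rng.integers(0, len(words) + 1))
            s = ScoredRecall(tuple(rng.permutation(words)[:k]))
            c = code_pair_clustering(s, exp1_list)
            assert c["pairs"].sum() == len(exp1_list.pairs)
            assert c["singletons"].sum() == len(exp1_list.singletons)

    def test_intrusions_do_not_break_adjacency_in_matched_mode(self, exp1_list):
        t = Transcript("p", ("knife", "xyzzyqq", "fork"))
        s = score_transcript(t, exp1_list)
        c = code_pair_clustering(s, exp1_list, adjacency="matched_only")
        np.testing.assert_array_equal(c["pairs"], [1, 0, 0, 1])
        c_raw = code_pair_clustering(s, exp1_list, adjacency="raw_output")
        np.testing.assert_array_equal(c_raw["pairs"], [0, 1, 0, 1])


class TestFreeThenCuedCoding:
    def test_enumerated_statuses(self, exp2_list):
        free = ScoredRecall(("ocean", "wave", "butter"))
        cued = {"ocean": "wave", "bread": "", "night": "star"}
        c = code_free_then_cued(free, cued, exp2_list)
        # P0 both+correct=C1, P1 one+fail=C4, P2 none+correct=C5
        np.testing.assert_array_equal(c["pairs"], [1, 0, 0, 1, 1, 0])

    def test_cued_match_allows_one_typo(self, exp2_list):
        c = code_free_then_cued(
            ScoredRecall(()), {"ocean": "wsve"}, exp2_list
        )
        assert c["pairs"][4] == 1  # none freely recalled, cued correct

    def test_unknown_cue_rejected(self, exp2_list):
        with pytest.raises(ValueError):
            code_free_then_cued(ScoredRecall(()), {"wave": "x"}, exp2_list)

    def test_counts_sum_to_n_pairs(self, exp2_list):
        c = code_free_then_cued(ScoredRecall(("night",)), {}, exp2_list)
        assert c["pairs"].sum() == 3


class TestArc:
    def test_perfect_clustering(self, exp1_list):
        res = arc_score(ScoredRecall(("knife", "fork", "salt", "pepper")), exp1_list)
        assert (res.R, res.expected_R, res.max_R, res.arc) == (2, 1.0, 2, 1.0)

    def test_perfect_anticlustering(self, exp1_list):
        res = arc_score(ScoredRecall(("knife", "salt", "fork", "pepper")), exp1_list)
        assert res.arc == -1.0

    def test_one_word_per_category_undefined(self, exp1_list):
        res = arc_score(ScoredRecall(("knife", "salt", "chair")), exp1_list)
        assert res.arc is None and not res.defined

    def test_matches_direct_formula_on_random_sequences(self, exp1_list):
        rng = np.random.default_rng(1)
        words = list(exp1_list.all_words())
        for _ in range(200):
            k = int(rng.integers(2, len(words) + 1))
            seq = tuple(rng.permutation(words)[:k])
            res = arc_score(ScoredRecall(seq), exp1_list)
            ref = arc_reference([exp1_list.category_of(w) for w in seq])
            if ref is None:
                assert res.arc is None
            else:
                assert res.arc == pytest.approx(ref)

    def test_chance_level_under_random_order(self, exp1_list):
        # the chance correction: mean ARC over random shuffles ~ 0
        rng = np.random.default_rng(2)
        words = ["knife", "fork", "salt", "pepper", "chair"]
        vals = []
        for _ in range(10_000):
            res = arc_score(ScoredRecall(tuple(rng.permutation(words))), exp1_list)
            if res.arc is not None:
                vals.append(res.arc)
        assert abs(np.mean(vals)) < 0.02


class TestWmcComposite:
    def test_mean_of_two_z_scores(self):
        records = [
            SpanRecord("a", 10.0, 20.0),
            SpanRecord("b", 20.0, 30.0),
            SpanRecord("c", 30.0, 40.0),
        ]
        out = wmc_composite(records)
        # b is at the mean of both tasks
        assert out.loc["b", "wmc_z"] == pytest.approx(0.0)
        assert out.loc["a", "wmc_z"] == pytest.approx(-1.0)

    def test_single_valid_score_is_proxy(self):
        records = [
            SpanRecord("a", 10.0, None),
            SpanRecord("b", 20.0, 5.0),
            SpanRecord("c", 30.0, 15.0),
        ]
        out = wmc_composite(records)
        z_a = (10.0 - 20.0) / 10.0
        assert out.loc["a", "wmc_z"] == pytest.approx(z_a)

    def test_no_valid_scores_excluded(self):
        out = wmc_composite([SpanRecord("a", 1.0, 2.0), SpanRecord("b", 2.0, 1.0),
                             SpanRecord("c", None, None)])
        assert "c" not in out.index

    def test_zero_variance_task_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            wmc_composite([SpanRecord("a", 5.0, 1.0), SpanRecord("b", 5.0, 2.0)])


class TestCronbachAlpha:
    def test_parallel_items_alpha_one(self):
        x = np.array([[1, 2, 3], [2, 3, 4], [3, 4, 5], [4, 5, 6]], dtype=float)
        assert cronbach_alpha(x) == pytest.approx(1.0)

    def test_independent_items_alpha_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((20_000, 2))
        assert abs(cronbach_alpha(x)) < 0.05

    def test_perfectly_correlated_pair(self):
        x = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
        # two items proportional: alpha = 2(1 - (v1+v2)/var(total))
        assert cronbach_alpha(x) == pytest.approx(
            2 * (1 - (x[:, 0].var(ddof=1) + x[:, 1].var(ddof=1))
                 / x.sum(axis=1).var(ddof=1))
        )

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((4, 3)))
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((1, 3)))


def test_study_list_lag_constraint_enforced():
    with pytest.raises(ValueError, match="1-4"):
        StudyList(
            pairs=(("a", "b", "c1"),),
            singletons=(("x", "s1"),),
            presentation_order=("a", "b", "x"),  # adjacent: lag 0
        )
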