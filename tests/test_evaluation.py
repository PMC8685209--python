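import random

import numpy as np
import pytest

from ppsim.corpus import Stratum
from ppsim.evaluation import (
    LocalRanking,
    evaluate_stratum,
    global_auc,
    implied_case_difference,
    label_pairs,
    local_rankings,
    mrr,
    rank_shift_from_ranks,
    rank_shift_test,
    top_k_accuracy,
    PairLabel,
)
from ppsim.similarity import SimilarityMatrix

from ._oracles import brute_auc, exact_mwu_two_sided
from .conftest import profile_set


def matrix_from_scores(visits, pair_scores, stratum=Stratum.ALL):
    n = len(visits)
    idx = {v: i for i, v in enumerate(visits)}
    scores = np.zeros((n, n))
    for (a, b), s in pair_scores.items():
        scores[idx[a], idx[b]] = scores[idx[b], idx[a]] = s
    return SimilarityMatrix(visits=list(visits), scores=scores, stratum=stratum)


def ranking_with_first_true(focal, first_true_rank, length):
    ordered = [
        (f"o{i:03d}", float(length - i), i + 1 == first_true_rank)
        for i in range(length)
    ]
    return LocalRanking(focal=focal, ordered=ordered)


class TestLabelPairs:
    def test_three_visit_enumeration(self):
        ps = profile_set(
            {"v1": set(), "v2": set(), "v3": set()},
            {"v1": "d1", "v2": "d1", "v3": "d2"},
        )
        labels = {(l.visit_a, l.visit_b): l.shared for l in label_pairs(ps)}
        assert labels == {
            ("v1", "v2"): True, ("v1", "v3"): False, ("v2", "v3"): False
        }

    def test_all_distinct_diagnoses_give_no_true_pairs(self):
        ps = profile_set(
            {f"v{i}": set() for i in range(4)},
            {f"v{i}": f"d{i}" for i in range(4)},
        )
        assert not any(l.shared for l in label_pairs(ps))

    def test_pair_count_is_n_choose_2(self):
        n = 40
        ps = profile_set(
            {f"v{i}": set() for i in range(n)},
            {f"v{i}": "d" for i in range(n)},
        )
        assert len(label_pairs(ps)) == n * (n - 1) // 2


class TestGlobalAUC:
    def test_perfect_separation(self):
        m = matrix_from_scores(
            ["a", "b", "c"], {("a", "b"): 0.9, ("a", "c"): 0.2, ("b", "c"): 0.1}
        )
        labels = [PairLabel("a", "b", True), PairLabel("a", "c", False),
                  PairLabel("b", "c", False)]
        auc, lo, hi = global_auc(m, labels)
        assert auc == 1.0
        assert lo <= auc <= hi

    def test_full_ties_give_half(self):
        m = matrix_from_scores(
            ["a", "b", "c"], {("a", "b"): 0.5, ("a", "c"): 0.5, ("b", "c"): 0.5}
        )
        labels = [PairLabel("a", "b", True), PairLabel("a", "c", False),
                  PairLabel("b", "c", False)]
        assert global_auc(m, labels)[0] == 0.5

    def test_hand_counted_example(self):
        # true pair scores 0.9, 0.4; false pair scores 0.5, 0.1
        m = matrix_from_scores(
            ["a", "b", "c", "d"],
            {("a", "b"): 0.9, ("a", "c"): 0.4, ("a", "d"): 0.5, ("b", "c"): 0.1},
        )
        labels = [
            PairLabel("a", "b", True), PairLabel("a", "c", True),
            PairLabel("a", "d", False), PairLabel("b", "c", False),
        ]
        auc, _, _ = global_auc(m, labels)
        assert auc == pytest.approx(0.75)
        assert auc == pytest.approx(brute_auc([0.9, 0.4], [0.5, 0.1]))

    def test_degenerate_labels_are_hard_errors(self):
        m = matrix_from_scores(["a", "b"], {("a", "b"): 0.5})
        with pytest.raises(ValueError, match="no non-shared"):
            global_auc(m, [PairLabel("a", "b", True)])
        with pytest.raises(ValueError, match="no shared"):
            global_auc(m, [PairLabel("a", "b", False)])

    @pytest.mark.parametrize("seed", range(10))
    def test_reversal_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        visits = [f"v{i}" for i in range(8)]
        scores = {}
        for i, a in enumerate(visits):
            for b in visits[i + 1:]:
                scores[(a, b)] = float(rng.choice([0.1, 0.3, 0.3, 0.7, 0.9]))
        labels = [
            PairLabel(a, b, bool(rng.random() < 0.4)) for (a, b) in scores
        ]
        if not any(l.shared for l in labels) or all(l.shared for l in labels):
            pytest.skip("degenerate label draw")
        m = matrix_from_scores(visits, scores)
        m_neg = matrix_from_scores(visits, {k: -v for k, v in scores.items()})
        assert global_auc(m, labels)[0] == pytest.approx(
            1.0 - global_auc(m_neg, labels)[0]
        )


class TestLocalRankings:
    @pytest.fixture
    def cohort(self):
        ps = profile_set(
            {"v1": set(), "v2": set(), "v3": set()},
            {"v1": "d1", "v2": "d1", "v3": "d2"},
        )
        m = matrix_from_scores(
            ["v1", "v2", "v3"],
            {("v1", "v2"): 0.9, ("v1", "v3"): 0.3, ("v2", "v3"): 0.6},
        )
        return m, ps

    def test_orderings_match_hand_sort(self, cohort):
        m, ps = cohort
        rankings = {r.focal: [v for v, _, _ in r.ordered] for r in local_rankings(m, ps)}
        assert rankings == {
            "v1": ["v2", "v3"],
            "v2": ["v1", "v3"],
            "v3": ["v2", "v1"],
        }

    def test_each_ranking_excludes_focal_and_has_n_minus_1(self, cohort):
        m, ps = cohort
        for r in local_rankings(m, ps):
            assert len(r.ordered) == 2
            assert r.focal not in [v for v, _, _ in r.ordered]

    def test_ties_break_by_ascending_visit_id(self):
        ps = profile_set(
            {"v1": set(), "v2": set(), "v3": set()},
            {"v1": "d1", "v2": "d1", "v3": "d1"},
        )
        m = matrix_from_scores(
            ["v1", "v2", "v3"],
            {("v1", "v2"): 0.5, ("v1", "v3"): 0.5, ("v2", "v3"): 0.1},
        )
        (r1,) = [r for r in local_rankings(m, ps) if r.focal == "v1"]
        assert [v for v, _, _ in r1.ordered] == ["v2", "v3"]


class TestMRRAndTopK:
    def test_all_top1_hits_give_ceiling(self):
        rankings = [ranking_with_first_true(f"f{i}", 1, 20) for i in range(5)]
        val, n = mrr(rankings)
        assert (val, n) == (1.0, 5)

    def test_rank_four_contributes_quarter(self):
        val, n = mrr([ranking_with_first_true("f", 4, 20)])
        assert val == pytest.approx(0.25)
        assert n == 1

    def test_visits_without_possible_match_are_excluded(self):
        ps = profile_set(
            {"v1": set(), "v2": set(), "v3": set()},
            {"v1": "d1", "v2": "d1", "v3": "d2"},
        )
        m = matrix_from_scores(
            ["v1", "v2", "v3"],
            {("v1", "v2"): 0.9, ("v1", "v3"): 0.3, ("v2", "v3"): 0.6},
        )
        rankings = local_rankings(m, ps)
        val, n = mrr(rankings)
        assert n == 2  # v3 has no same-diagnosis partner
        assert val == pytest.approx(1.0)  # v1 and v2 rank each other first

    def test_saturating_k_hits_everything_evaluable(self):
        rankings = [ranking_with_first_true(f"f{i}", i + 3, 20) for i in range(6)]
        assert top_k_accuracy(rankings, k=20) == 1.0

    def test_k1_is_nearest_neighbour_accuracy(self):
        rankings = [
            ranking_with_first_true("a", 1, 10),
            ranking_with_first_true("b", 2, 10),
        ]
        assert top_k_accuracy(rankings, k=1) == pytest.approx(0.5)

    def test_accuracy_non_decreasing_in_k_and_mrr_lower_bound(self):
        rng = random.Random(7)
        rankings = [
            ranking_with_first_true(f"f{i}", rng.randint(1, 15), 15)
            for i in range(30)
        ]
        accs = [top_k_accuracy(rankings, k=k) for k in range(1, 16)]
        assert all(a <= b + 1e-12 for a, b in zip(accs, accs[1:]))
        assert mrr(rankings)[0] >= accs[0] - 1e-12
        assert top_k_accuracy(rankings, k=10) >= accs[0]

    def test_implied_case_difference_at_cohort_scale(self):
        assert implied_case_difference(0.606, 0.619, 1000) == 13


class TestRankShift:
    def test_identical_rankings_give_p_one(self):
        rankings = [ranking_with_first_true(f"f{i}", i + 1, 30) for i in range(6)]
        assert rank_shift_test(rankings, rankings) == 1.0

    def test_full_separation_is_significant(self):
        x = [ranking_with_first_true(f"x{i}", 1, 100) for i in range(30)]
        base = [ranking_with_first_true(f"b{i}", 50 + i, 100) for i in range(30)]
        assert rank_shift_test(x, base) < 0.01

    def test_small_samples_match_exact_permutation_oracle(self):
        xs, bs = [1, 2, 3, 10], [4, 5, 6, 20]
        x = [ranking_with_first_true(f"x{i}", r, 25) for i, r in enumerate(xs)]
        base = [ranking_with_first_true(f"b{i}", r, 25) for i, r in enumerate(bs)]
        assert rank_shift_test(x, base) == pytest.approx(
            exact_mwu_two_sided(xs, bs), rel=1e-9
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_samples_match_enumeration(self, seed):
        rng = random.Random(seed)
        xs = [rng.randint(1, 30) for _ in range(rng.randint(3, 6))]
        bs = [rng.randint(1, 30) for _ in range(rng.randint(3, 6))]
        if len(set(xs) | set(bs)) < len(xs) + len(bs):
            pytest.skip("tied draw; exact enumeration convention differs")
        assert rank_shift_from_ranks(xs, bs) == pytest.approx(
            exact_mwu_two_sided(xs, bs), rel=1e-9
        )

    def test_too_few_evaluable_is_hard_error(self):
        x = [ranking_with_first_true("x", 1, 5)]
        with pytest.raises(ValueError, match=">= 2 evaluable"):
            rank_shift_test(x, x)

    def test_pooled_mode_uses_all_true_ranks(self):
        ordered = [("a", 3.0, True), ("b", 2.0, False), ("c", 1.0, True)]
        r = LocalRanking(focal="f", ordered=ordered)
        assert r.true_ranks() == [1, 3]
        p = rank_shift_test([r, r], [r, r], mode="pooled")
        assert p == 1.0


class TestEvaluateStratum:
    @pytest.fixture
    def cohort(self):
        visits = [f"v{i}" for i in range(6)]
        dx = {"v0": "a", "v1": "a", "v2": "b", "v3": "b", "v4": "c", "v5": "c"}
        rng = np.random.default_rng(42)
        scores = {}
        for i, a in enumerate(visits):
            for b in visits[i + 1:]:
                base = 0.8 if dx[a] == dx[b] else 0.3
                scores[(a, b)] = base + 0.1 * float(rng.random())
        ps = profile_set({v: {"t"} for v in visits}, dx)
        return matrix_from_scores(visits, scores), ps

    def test_report_equals_componentwise_recomputation(self, cohort):
        m, ps = cohort
        report = evaluate_stratum(m, ps)
        auc, lo, hi = global_auc(m, label_pairs(ps))
        rankings = local_rankings(m, ps)
        assert report.auc == auc
        assert (report.auc_ci_low, report.auc_ci_high) == (lo, hi)
        assert (report.mrr, report.n_evaluable) == mrr(rankings)
        assert report.a_at_10 == top_k_accuracy(rankings, k=10)
        assert report.rank_shift_p is None

    def test_baseline_comparison_populates_p(self, cohort):
        m, ps = cohort
        baseline = local_rankings(m, ps)
        report = evaluate_stratum(m, ps, baseline_rankings=baseline)
        assert report.rank_shift_p == 1.0
        assert report.significant is False

    def test_tsv_row_blank_p_for_baseline(self, cohort):
        m, ps = cohort
        report = evaluate_stratum(m, ps)
        fields = report.tsv_row().split("\t")
        assert fields[6] == ""
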