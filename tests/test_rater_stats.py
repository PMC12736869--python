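import numpy as np
import pytest
from scipy import stats

from segqc.rater_stats import (
    ConfusionCounts,
    RatingTable,
    clopper_pearson,
    cochran_q,
    cohen_kappa,
    compare_methods,
    confusion,
    delong_ci,
    diagnostic_summary,
    fleiss_kappa,
    kappa_interpretation,
    majority_rating,
    mcnemar_pairwise,
    roc_over_rating_sums,
    stratified_summary,
    subgroup_sensitivity,
)


def _table(reference, ratings, case_ids=None):
    ratings = np.asarray(ratings)
    ids = case_ids or [f"c{i:03d}" for i in range(len(reference))]
    return RatingTable(case_ids=ids, reference=np.asarray(reference), ratings=ratings)


def _random_table(rng, n=300, n_raters=5, sens=0.8, spec=0.9, prevalence=0.25):
    ref = (rng.random(n) < prevalence).astype(int)
    if ref.min() == ref.max():  # ensure both classes
        ref[0], ref[1] = 0, 1
    p = np.where(ref[:, None] == 1, sens, 1 - spec)
    ratings = (rng.random((n, n_raters)) < p).astype(int)
    return _table(ref, ratings)


class TestMajorityRating:
    def test_threshold_above_half_of_five(self):
        # sums 5,3,2,0 with R=5 -> flags 1,1,0,0 (cutoff > 2.5)
        ratings = [[1] * 5, [1, 1, 1, 0, 0], [1, 1, 0, 0, 0], [0] * 5]
        t = _table([1, 1, 0, 0], ratings)
        np.testing.assert_array_equal(majority_rating(t), [1, 1, 0, 0])

    def test_unanimous_table_reproduces_any_rater(self, rng):
        col = (rng.random(20) < 0.5).astype(int)
        t = _table(col, np.tile(col[:, None], (1, 5)))
        np.testing.assert_array_equal(majority_rating(t), col)

    def test_single_rater_identity(self, rng):
        col = (rng.random(20) < 0.5).astype(int)
        t = _table(col, col[:, None])
        np.testing.assert_array_equal(majority_rating(t), col)

    def test_even_rater_count_needs_tie_rule(self):
        t = _table([1, 0], [[1, 1, 0, 0], [0, 0, 1, 1]])
        with pytest.raises(ValueError, match="tie_rule"):
            majority_rating(t)
        np.testing.assert_array_equal(majority_rating(t, tie_rule="positive"), [1, 1])
        np.testing.assert_array_equal(majority_rating(t, tie_rule="negative"), [0, 0])


class TestConfusion:
    def test_perfect_prediction(self):
        ref = np.r_[np.ones(10, int), np.zeros(20, int)]
        c = confusion(ref, ref)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 20, 0, 0)

    def test_inverted_prediction(self):
        ref = np.r_[np.ones(5, int), np.zeros(5, int)]
        c = confusion(1 - ref, ref)
        assert c.tp == 0 and c.tn == 0 and c.fp == 5 and c.fn == 5

    def test_matches_loop_oracle(self, rng):
        pred = (rng.random(30) < 0.5).astype(int)
        ref = (rng.random(30) < 0.5).astype(int)
        c = confusion(pred, ref)
        tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for p, r in zip(pred, ref):
            key = ("t" if p == r else "f") + ("p" if p == 1 else "n")
            tally[key] += 1
        assert (c.tp, c.fp, c.fn, c.tn) == tuple(tally[k] for k in ("tp", "fp", "fn", "tn"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1, 0, 1])


class TestClopperPearson:
    def test_reproduces_published_intervals(self):
        # 68/76 -> [80.3%, 95.3%]; 221/224 -> [96.1%, 99.7%]
        lo, hi = clopper_pearson(68, 76)
        assert (round(lo, 3), round(hi, 3)) == (0.803, 0.953)
        lo, hi = clopper_pearson(221, 224)
        assert (round(lo, 3), round(hi, 3)) == (0.961, 0.997)

    def test_boundaries(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_contains_point_estimate(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 200))
            k = int(rng.integers(0, n + 1))
            lo, hi = clopper_pearson(k, n)
            assert lo <= k / n <= hi

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)


class TestDiagnosticSummary:
    def test_pooled_study_counts(self):
        s = diagnostic_summary(ConfusionCounts(tp=67, fp=3, fn=9, tn=221))
        assert round(100 * s.sensitivity.value, 1) == 88.2
        assert round(100 * s.specificity.value, 1) == 98.7
        assert round(100 * s.accuracy.value, 1) == 96.0
        assert round(100 * s.ppv.value, 1) == 95.7
        assert round(100 * s.npv.value, 1) == 96.1
        assert round(s.f1, 3) == 0.918

    def test_perfect_prediction_all_ones(self):
        s = diagnostic_summary(ConfusionCounts(tp=10, fp=0, fn=0, tn=20))
        for m in (s.sensitivity, s.specificity, s.accuracy, s.ppv, s.npv):
            assert m.value == 1.0
        assert s.f1 == 1.0

    def test_balanced_half(self):
        s = diagnostic_summary(ConfusionCounts(tp=1, fp=1, fn=1, tn=1))
        for m in (s.sensitivity, s.specificity, s.accuracy, s.ppv, s.npv):
            assert m.value == 0.5
        assert s.f1 == 0.5

    def test_point_estimates_inside_cis(self, rng):
        c = ConfusionCounts(tp=58, fp=12, fn=9, tn=121)
        s = diagnostic_summary(c)
        for m in (s.sensitivity, s.specificity, s.accuracy, s.ppv, s.npv):
            assert m.ci[0] <= m.value <= m.ci[1]

    def test_zero_denominator_reported_as_undefined(self):
        s = diagnostic_summary(ConfusionCounts(tp=0, fp=0, fn=0, tn=5))
        assert s.sensitivity is None and s.ppv is None
        assert s.specificity.value == 1.0


def rank_auc(scores, ref):
    """Mann–Whitney probability-of-correct-ranking oracle."""
    pos = scores[ref == 1]
    neg = scores[ref == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


class TestROC:
    def test_perfect_ratings_give_auc_one(self):
        ref = np.r_[np.ones(10, int), np.zeros(20, int)]
        t = _table(ref, np.tile(ref[:, None], (1, 5)))
        roc = roc_over_rating_sums(t)
        assert roc.auc == pytest.approx(1.0)

    def test_constant_ratings_give_chance_auc(self):
        ref = np.r_[np.ones(10, int), np.zeros(20, int)]
        t = _table(ref, np.ones((30, 5), int))
        assert roc_over_rating_sums(t).auc == pytest.approx(0.5)

    def test_auc_equals_rank_oracle(self, rng):
        for _ in range(25):
            t = _random_table(rng, n=120)
            roc = roc_over_rating_sums(t)
            expected = rank_auc(t.rating_sums.astype(float), t.reference)
            assert roc.auc == pytest.approx(expected, abs=1e-10)

    def test_monotone_staircase(self, rng):
        roc = roc_over_rating_sums(_random_table(rng))
        assert (np.diff(roc.sensitivity) <= 1e-12).all()
        assert (np.diff(roc.specificity) >= -1e-12).all()

    def test_youden_scales_agree_on_best_threshold(self, rng):
        roc = roc_over_rating_sums(_random_table(rng))
        assert np.argmax(roc.youden) == np.argmax(roc.youden_pct)
        j_best = roc.youden[np.argmax(roc.youden)]
        assert roc.youden_pct[np.argmax(roc.youden)] == pytest.approx(100 * (j_best + 1))

    def test_degenerate_reference_rejected(self):
        t = _table([1, 1, 1], np.ones((3, 5), int))
        with pytest.raises(ValueError):
            roc_over_rating_sums(t)


class TestDeLong:
    def test_perfect_separation_collapses_ci(self):
        scores = np.r_[np.ones(10), np.zeros(10)]
        ref = np.r_[np.ones(10, int), np.zeros(10, int)]
        auc, lo, hi = delong_ci(scores, ref)
        assert (auc, lo, hi) == (1.0, 1.0, 1.0)

    def test_class_swap_symmetry(self, rng):
        scores = rng.random(100)
        ref = (rng.random(100) < 0.4).astype(int)
        auc, _, _ = delong_ci(scores, ref)
        auc_sw, _, _ = delong_ci(scores, 1 - ref)
        assert auc_sw == pytest.approx(1.0 - auc)

    def test_ci_contains_auc_and_is_truncated(self, rng):
        t = _random_table(rng)
        auc, lo, hi = delong_ci(t.rating_sums.astype(float), t.reference)
        assert 0.0 <= lo <= auc <= hi <= 1.0


class TestCochranQ:
    def test_identical_columns(self):
        m = np.tile(np.array([1, 0, 1, 1])[:, None], (1, 3))
        q, p = cochran_q(m)
        assert q == 0.0 and p == 1.0

    def test_two_methods_reduce_to_mcnemar_chi2(self, rng):
        m = (rng.random((40, 2)) < 0.6).astype(int)
        b = int(((m[:, 0] == 1) & (m[:, 1] == 0)).sum())
        c = int(((m[:, 0] == 0) & (m[:, 1] == 1)).sum())
        if b + c == 0:
            pytest.skip("no discordance in draw")
        q, _ = cochran_q(m)
        assert q == pytest.approx((b - c) ** 2 / (b + c))

    def test_matches_textbook_formula(self, rng):
        for _ in range(10):
            m = (rng.random((20, 3)) < 0.5).astype(int)
            k = 3
            col = m.sum(axis=0)
            row = m.sum(axis=1)
            denom = k * row.sum() - (row**2).sum()
            if denom == 0:
                continue
            expected = k * (k - 1) * ((col - col.mean()) ** 2).sum() / denom
            q, p = cochran_q(m)
            assert q == pytest.approx(expected)
            assert p == pytest.approx(stats.chi2.sf(expected, k - 1))

    def test_single_method_rejected(self):
        with pytest.raises(ValueError):
            cochran_q(np.ones((5, 1), int))


class TestMcNemar:
    def test_identical_methods_give_p_one(self):
        m = np.tile(np.array([1, 0, 1])[:, None], (1, 2))
        (pair,) = mcnemar_pairwise(m)
        assert pair.p_raw == 1.0 and pair.p_adjusted == 1.0

    def test_exact_binomial_tail(self):
        # discordant b=10, c=0 -> two-sided exact p = 2 * 0.5^10
        col_i = np.r_[np.ones(10, int), np.ones(10, int)]
        col_j = np.r_[np.zeros(10, int), np.ones(10, int)]
        (pair,) = mcnemar_pairwise(np.column_stack([col_i, col_j]), adjust="none")
        assert pair.b == 10 and pair.c == 0
        assert pair.p_raw == pytest.approx(2 * 0.5**10)

    def test_bonferroni_multiplies_by_pair_count(self, rng):
        m = (rng.random((30, 3)) < 0.5).astype(int)
        pairs = mcnemar_pairwise(m)
        raw = mcnemar_pairwise(m, adjust="none")
        assert len(pairs) == 3
        for a, b in zip(pairs, raw):
            assert a.p_adjusted == pytest.approx(min(1.0, 3 * b.p_raw))


def brute_force_fleiss(ratings):
    """Direct textbook evaluation of Fleiss' kappa for 2 categories."""
    n, r = ratings.shape
    counts = np.column_stack([r - ratings.sum(axis=1), ratings.sum(axis=1)])
    p_i = ((counts * (counts - 1)).sum(axis=1)) / (r * (r - 1))
    p_bar = p_i.mean()
    p_j = counts.sum(axis=0) / (n * r)
    p_e = (p_j**2).sum()
    return (p_bar - p_e) / (1 - p_e)


class TestKappa:
    def test_fleiss_perfect_agreement_both_categories(self):
        ratings = np.r_[np.ones((5, 4), int), np.zeros((5, 4), int)]
        res = fleiss_kappa(ratings)
        assert res.kappa == pytest.approx(1.0)
        assert res.interpretation == "almost perfect"

    def test_fleiss_negative_on_systematic_disagreement(self):
        # every case splits the raters 2-2: observed agreement far below chance
        ratings = np.tile([1, 1, 0, 0], (12, 1))
        res = fleiss_kappa(ratings)
        assert res.kappa < 0
        assert res.interpretation == "poor"

    def test_fleiss_matches_brute_force(self, rng):
        for _ in range(15):
            ratings = (rng.random((10, 5)) < rng.random()).astype(int)
            if ratings.sum() in (0, ratings.size):
                continue
            assert fleiss_kappa(ratings).kappa == pytest.approx(brute_force_fleiss(ratings))

    def test_fleiss_undefined_when_single_category(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.ones((4, 3), int))

    def test_cohen_identical_vectors(self):
        v = np.array([1, 0, 1, 1, 0])
        res = cohen_kappa(v, v)
        assert res.kappa == pytest.approx(1.0)

    def test_cohen_matches_brute_force(self, rng):
        for _ in range(15):
            r1 = (rng.random(40) < 0.5).astype(int)
            r2 = (rng.random(40) < 0.5).astype(int)
            p_o = (r1 == r2).mean()
            p1, p2 = r1.mean(), r2.mean()
            p_e = p1 * p2 + (1 - p1) * (1 - p2)
            if p_e == 1:
                continue
            expected = (p_o - p_e) / (1 - p_e)
            assert cohen_kappa(r1, r2).kappa == pytest.approx(expected)

    def test_cohen_near_zero_for_independent_raters(self):
        # chance-corrected agreement of independent ratings averages ~0
        rng = np.random.default_rng(11)
        kappas = []
        for _ in range(1000):
            r1 = (rng.random(300) < 0.5).astype(int)
            r2 = (rng.random(300) < 0.5).astype(int)
            kappas.append(cohen_kappa(r1, r2).kappa)
        assert abs(np.mean(kappas)) < 0.05

    def test_cohen_undefined_when_constant(self):
        with pytest.raises(ValueError):
            cohen_kappa(np.ones(5, int), np.ones(5, int))

    @pytest.mark.parametrize(
        "kappa,band",
        [(-0.2, "poor"), (0.1, "slight"), (0.3, "fair"), (0.5, "moderate"),
         (0.7, "substantial"), (0.9, "almost perfect"), (1.0, "almost perfect")],
    )
    def test_interpretation_bands(self, kappa, band):
        assert kappa_interpretation(kappa) == band


class TestStudyLevel:
    def test_stratum_counts_pool_to_overall(self, rng):
        t = _random_table(rng, n=120)
        strata = {cid: ["min", "median", "max"][i % 3] for i, cid in enumerate(t.case_ids)}
        per = stratified_summary(t, strata)
        pooled_tp = sum(per[s]["confusion"]["tp"] for s in per)
        pooled_fn = sum(per[s]["confusion"]["fn"] for s in per)
        overall = confusion(majority_rating(t), t.reference)
        assert pooled_tp == overall.tp and pooled_fn == overall.fn

    def test_subgroup_sensitivity_counts(self):
        ref = [1, 1, 1, 0]
        ratings = [[1] * 5, [0] * 5, [1] * 5, [0] * 5]
        t = _table(ref, ratings)
        cats = {t.case_ids[0]: ["a"], t.case_ids[1]: ["a"], t.case_ids[2]: ["b"]}
        out = subgroup_sensitivity(t, cats)
        assert out["a"]["numerator"] == 1 and out["a"]["denominator"] == 2
        assert out["b"]["value"] == 1.0

    def test_compare_methods_identical_tables(self, rng):
        t = _random_table(rng, n=80)
        out = compare_methods({"m1": t, "m2": t})
        assert out["sensitivity"]["cochran_q"] == 0.0
        assert out["sensitivity"]["pairwise_mcnemar"][0]["p_adjusted"] == 1.0
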