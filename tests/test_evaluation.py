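"""Evaluation statistics against independent oracles and published 2x2s."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from obcmi import evaluation as ev


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


def grid_search_logistic(x, y, half_width=8.0, points=41, rounds=13):
    """Likelihood maximisation by nested grid refinement; independent of
    the IRLS/Newton path under test.  The window shrinks by 5x per round
    while the grid spacing is window/20, so the maximum stays inside the
    next window even along a correlated (intercept, slope) ridge."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    c0, c1 = 0.0, 0.0
    w = half_width
    for _ in range(rounds):
        b0 = np.linspace(c0 - w, c0 + w, points)
        b1 = np.linspace(c1 - w, c1 + w, points)
        eta = b0[:, None, None] + b1[None, :, None] * x[None, None, :]
        ll = (y * eta - np.logaddexp(0.0, eta)).sum(axis=2)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        c0, c1 = b0[i], b1[j]
        w = w / 5
    return c0, c1


class TestLogisticFit:
    def test_symmetric_four_points_gives_unit_or(self):
        fit = ev.fit_per_unit_logistic([0, 0, 1, 1], [0, 1, 0, 1])
        assert fit.or_per_unit == pytest.approx(1.0, abs=1e-8)
        assert fit.ci_low <= 1.0 <= fit.ci_high

    def test_independent_outcome_gives_unit_or(self, rng):
        n = 5000
        scores = rng.integers(0, 8, n)
        y = rng.random(n) < 0.3
        fit = ev.fit_per_unit_logistic(scores, y)
        assert fit.converged
        assert abs(fit.beta1) < 4 * fit.se_beta1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        x = rng.integers(0, 10, n).astype(float)
        y = (rng.random(n) < expit(-1.5 + 0.35 * x)).astype(float)
        if y.sum() in (0, n):  # pragma: no cover
            pytest.skip("degenerate draw")
        fit = ev.fit_per_unit_logistic(x, y)
        b0, b1 = grid_search_logistic(x, y)
        assert fit.beta0 == pytest.approx(b0, abs=1e-6)
        assert fit.beta1 == pytest.approx(b1, abs=1e-6)

    def test_known_slope_recovered(self, rng):
        n = 20000
        x = rng.integers(0, 11, n).astype(float)
        beta0, beta1 = -2.5, math.log(1.44)
        y = rng.random(n) < expit(beta0 + beta1 * x)
        fit = ev.fit_per_unit_logistic(x, y)
        assert fit.ci_low < 1.44 < fit.ci_high
        assert fit.wald_p < 1e-10

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            ev.fit_per_unit_logistic([0, 1, 2], [1, 1, 1])

    def test_complete_separation_flagged_not_raised(self):
        fit = ev.fit_per_unit_logistic([0, 0, 0, 5, 5, 5], [0, 0, 0, 1, 1, 1])
        assert not fit.converged


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def scipy_exact_permutation_p(a, b):
    pooled = np.concatenate([a, b])

    def statistic(x, y):
        ranks = stats.rankdata(np.concatenate([x, y]))
        return ranks[: len(x)].sum()

    res = stats.permutation_test(
        (a, b),
        statistic,
        permutation_type="independent",
        alternative="two-sided",
        n_resamples=np.inf,
    )
    return float(res.pvalue)


class TestWilcoxon:
    def test_identical_groups_p_is_one(self):
        cmp = ev.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert cmp.rank_sum_p == pytest.approx(1.0)

    def test_identical_large_groups_p_near_one(self, rng):
        x = rng.integers(0, 6, 60)
        cmp = ev.wilcoxon_rank_sum(x, x)
        assert cmp.rank_sum_p > 0.9

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_matches_scipy_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 8, 2)
        a = rng.integers(0, 5, n1)
        b = rng.integers(0, 5, n2)
        cmp = ev.wilcoxon_rank_sum(a, b)
        assert cmp.exact
        assert cmp.rank_sum_p == pytest.approx(scipy_exact_permutation_p(a, b), abs=1e-12)

    def test_fully_separated_tiny_groups_attain_minimal_p(self):
        """{0,0,0} vs {5,5,5}: the observed rank sum is the most extreme of
        the C(6,3)=20 assignments, so the two-sided exact p is 2/20."""
        cmp = ev.wilcoxon_rank_sum([0, 0, 0], [5, 5, 5])
        assert cmp.rank_sum_p == pytest.approx(0.1)

    def test_group_summaries(self):
        cmp = ev.wilcoxon_rank_sum([0, 0, 2, 4], [1, 1, 1, 1])
        assert cmp.group_a.median == 1.0
        assert cmp.group_a.mean == 1.5
        assert cmp.group_b.sd == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            ev.wilcoxon_rank_sum([], [1, 2])

    def test_shifted_large_groups_significant(self, rng):
        a = rng.integers(0, 4, 80)
        b = rng.integers(2, 8, 80)
        assert ev.wilcoxon_rank_sum(a, b).rank_sum_p < 1e-6


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def pairwise_auc_oracle(scores, y):
    """O(n^2) Mann-Whitney probability with ties counted 1/2."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, bool)
    pos, neg = scores[y], scores[~y]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_constant_scores_auc_half(self):
        roc = ev.roc_auc([3, 3, 3, 3], [0, 1, 0, 1])
        assert roc.auc == pytest.approx(0.5)

    def test_curve_endpoints(self, rng):
        s = rng.integers(0, 10, 50)
        y = rng.random(50) < 0.3
        if y.all() or not y.any():
            pytest.skip("degenerate draw")
        roc = ev.roc_auc(s, y)
        assert (roc.sens[0], roc.one_minus_spec[0]) == (0.0, 0.0)
        assert (roc.sens[-1], roc.one_minus_spec[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.sens) >= 0)

    def test_lowest_threshold_classifies_everyone_positive(self):
        """The sentinel cutoff reproduces the 100% sensitivity / 0%
        specificity row of a cutoff table at the minimum score."""
        s = np.array([0] * 8 + [2] * 2)
        y = np.array([0] * 7 + [1] * 3)
        roc = ev.roc_auc(s, y)
        assert roc.sens[-1] == 1.0 and roc.one_minus_spec[-1] == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_trapezoid_auc_equals_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        s = rng.integers(0, 8, n)
        y = rng.random(n) < 0.4
        if y.all() or not y.any():
            pytest.skip("degenerate draw")
        roc = ev.roc_auc(s, y)
        assert roc.auc == pytest.approx(pairwise_auc_oracle(s, y), abs=1e-12)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        s = rng.integers(0, 11, 500)
        y = rng.random(500) < 0.2
        roc = ev.roc_auc(s, y)
        assert roc.auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_ci_covers_auc_and_stays_in_unit_interval(self, rng):
        s = rng.integers(0, 11, 300)
        y = rng.random(300) < expit(-2 + 0.3 * s)
        if y.all() or not y.any():
            pytest.skip("degenerate draw")
        roc = ev.roc_auc(s, y)
        assert 0 <= roc.auc_ci_low <= roc.auc <= roc.auc_ci_high <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            ev.roc_auc([1, 2, 3], [0, 0, 0])


class TestPairedAUCComparison:
    def test_identical_scores_give_p_one(self, rng):
        s = rng.integers(0, 9, 100)
        y = rng.random(100) < 0.3
        assert ev.compare_auc_paired(s, s, y) == 1.0

    def test_null_type_one_error_near_nominal(self):
        """Two independent uninformative scores on the same subjects reject
        at roughly the 5% nominal rate."""
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 400
        for _ in range(reps):
            y = np.zeros(120, dtype=bool)
            y[:40] = True
            s1 = rng.normal(size=120)
            s2 = rng.normal(size=120)
            if ev.compare_auc_paired(s1, s2, y) < 0.05:
                rejections += 1
        rate = rejections / reps
        assert 0.02 <= rate <= 0.09  # ~3 MC SDs around 0.05

    def test_agrees_with_stratified_bootstrap(self):
        rng = np.random.default_rng(7)
        n = 150
        y = rng.random(n) < 0.35
        if y.all() or not y.any():  # pragma: no cover
            pytest.skip("degenerate draw")
        latent = y.astype(float)
        s1 = latent + rng.normal(0, 1.2, n)
        s2 = latent + rng.normal(0, 1.6, n)
        p_delong = ev.compare_auc_paired(s1, s2, y)

        # stratified bootstrap of the AUC difference
        pos_idx = np.flatnonzero(y)
        neg_idx = np.flatnonzero(~y)
        diffs = []
        for _ in range(600):
            pi = rng.choice(pos_idx, pos_idx.size)
            ni = rng.choice(neg_idx, neg_idx.size)
            idx = np.concatenate([pi, ni])
            yy = y[idx]
            d = ev.roc_auc(s1[idx], yy).auc - ev.roc_auc(s2[idx], yy).auc
            diffs.append(d)
        diffs = np.asarray(diffs)
        observed = ev.roc_auc(s1, y).auc - ev.roc_auc(s2, y).auc
        p_boot = float(2 * stats.norm.sf(abs(observed) / diffs.std(ddof=1)))
        assert p_delong == pytest.approx(p_boot, abs=0.12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            ev.compare_auc_paired([1, 2], [1, 2, 3], [0, 1, 0])


# ---------------------------------------------------------------------------
# cutoff tables and 2x2 statistics
# ---------------------------------------------------------------------------


def table4_cohort(n_below, events_below, n_above, events_above, above_score=4):
    scores = np.concatenate(
        [np.zeros(n_below, int), np.full(n_above, above_score, int)]
    )
    y = np.concatenate(
        [
            np.r_[np.ones(events_below, bool), np.zeros(n_below - events_below, bool)],
            np.r_[np.ones(events_above, bool), np.zeros(n_above - events_above, bool)],
        ]
    )
    return scores, y


class TestTwoByTwo:
    def test_published_validated_smm_cutoff4(self):
        r = ev.two_by_two_stats(921, 100, 78, 30)
        assert ev.round_percent(r.rr) == 3.5
        assert ev.round_percent(r.rd) == 27.6
        assert ev.round_percent(r.nnh) == 3.6
        assert r.nnh_whole == 4
        assert ev.round_percent(r.rr_ci_low) == 2.5
        assert ev.round_percent(r.rr_ci_high) == 5.0

    def test_symmetric_groups_null(self):
        r = ev.two_by_two_stats(100, 10, 100, 10)
        assert r.rr == 1.0 and r.rd == 0.0
        assert not r.nnh_defined and r.nnh is None

    def test_published_modified_smm_cutoff4(self):
        r = ev.two_by_two_stats(909, 99, 90, 31)
        assert ev.round_percent(r.rr) == 3.2
        assert ev.round_percent(r.rd) == 23.6

    def test_zero_events_below_flags_rr_undefined(self):
        r = ev.two_by_two_stats(50, 0, 50, 10)
        assert not r.rr_defined and r.rr is None
        assert r.nnh_defined

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            ev.two_by_two_stats(0, 0, 50, 10)

    def test_nnh_times_rd_is_100(self):
        r = ev.two_by_two_stats(200, 10, 100, 30)
        assert r.nnh * r.rd == pytest.approx(100.0)


class TestCutoffTable:
    def test_minimum_cutoff_row(self):
        s, y = table4_cohort(921, 100, 78, 30)
        rows = ev.cutoff_table(s, y)
        first = rows[0]
        assert first.sensitivity == 100.0
        assert first.specificity == 0.0
        assert ev.round_percent(first.correctly_classified) == 13.0

    def test_published_validated_smm_row_at_cutoff4(self):
        s, y = table4_cohort(921, 100, 78, 30)
        row = [r for r in ev.cutoff_table(s, y) if r.cutoff == 4.0][0]
        assert ev.round_percent(row.sensitivity) == 23.1
        assert ev.round_percent(row.specificity) == 94.5
        assert ev.round_percent(row.correctly_classified) == 85.2

    def test_rows_consistent_with_two_by_two(self, rng):
        s = rng.integers(0, 9, 400)
        y = rng.random(400) < expit(-2.2 + 0.3 * s)
        if y.all() or not y.any():
            pytest.skip("degenerate draw")
        for row in ev.cutoff_table(s, y)[1:]:
            below = s < row.cutoff
            ref = ev.two_by_two_stats(
                int(below.sum()),
                int(y[below].sum()),
                int((~below).sum()),
                int(y[~below].sum()),
                cutoff=row.cutoff,
            )
            assert row == ref

    def test_perfect_classifier_has_perfect_cutoff(self):
        s = np.array([0] * 30 + [9] * 10)
        y = np.array([0] * 30 + [1] * 10)
        rows = ev.cutoff_table(s, y)
        best = [r for r in rows if r.cutoff == 9.0][0]
        assert best.sensitivity == 100.0 and best.specificity == 100.0

    def test_counts_conserved(self, rng):
        s = rng.integers(0, 7, 200)
        y = rng.random(200) < 0.2
        if y.all() or not y.any():
            pytest.skip("degenerate draw")
        for row in ev.cutoff_table(s, y):
            assert row.tp + row.fn == int(y.sum())
            assert row.tp + row.fp + row.tn + row.fn == 200


# ---------------------------------------------------------------------------
# power and cumulative frequency
# ---------------------------------------------------------------------------


class TestPower:
    def test_equal_proportions_power_is_alpha(self):
        assert ev.power_two_proportions(0.2, 0.2, 200, 200) == pytest.approx(
            0.05, abs=1e-9
        )

    def test_power_increases_with_n(self):
        powers = [
            ev.power_two_proportions(0.10, 0.25, n, n) for n in (30, 60, 120, 240)
        ]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    @pytest.mark.parametrize(
        "p1,p2,n1,n2", [(0.109, 0.385, 921, 78), (0.1, 0.2, 150, 150)]
    )
    def test_matches_simulated_rejection_rate(self, p1, p2, n1, n2):
        """Analytic power within 2 Monte-Carlo SEs of the rejection rate of
        the pooled two-proportion z-test over 20000 simulated trials."""
        rng = np.random.default_rng(12345)
        reps = 20000
        x1 = rng.binomial(n1, p1, reps)
        x2 = rng.binomial(n2, p2, reps)
        ph1, ph2 = x1 / n1, x2 / n2
        pbar = (x1 + x2) / (n1 + n2)
        se0 = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (ph1 - ph2) / se0
        reject = np.abs(z) > stats.norm.ppf(0.975)
        rate = reject.mean()
        power = ev.power_two_proportions(p1, p2, n1, n2)
        mc_se = math.sqrt(rate * (1 - rate) / reps) if 0 < rate < 1 else 1 / reps
        # the analytic value is a continuous approximation to a discrete
        # test, so allow a small systematic margin beyond Monte-Carlo noise
        assert abs(power - rate) <= 2 * mc_se + 0.01

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ev.power_two_proportions(0.0, 0.2, 50, 50)
        with pytest.raises(ValueError):
            ev.power_two_proportions(0.1, 0.2, 1, 50)


class TestCumulativeFrequency:
    def test_all_zero_scores(self):
        table = ev.cumulative_frequency([0, 0, 0])
        assert list(table["score"]) == [0]
        assert list(table["percent"]) == [100.0]
        assert list(table["cumulative_percent"]) == [100.0]

    def test_small_example(self):
        table = ev.cumulative_frequency([0, 0, 1, 3])
        assert list(table["score"]) == [0, 1, 3]
        assert list(table["percent"]) == [50.0, 25.0, 25.0]
        assert list(table["cumulative_percent"]) == [50.0, 75.0, 100.0]

    def test_percentages_sum_to_100_and_monotone(self, rng):
        table = ev.cumulative_frequency(rng.integers(0, 12, 500))
        assert table["percent"].sum() == pytest.approx(100.0)
        assert np.all(np.diff(table["cumulative_percent"]) >= 0)
        assert table["cumulative_percent"].iloc[-1] == pytest.approx(100.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            ev.cumulative_frequency([])


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(23.05, 23.1), (23.04, 23.0), (-0.05, -0.1), (3.55, 3.6)]
    )
    def test_round_half_away_from_zero(self, x, expected):
        assert ev.round_percent(x) == expected

    def test_none_passthrough(self):
        assert ev.round_percent(None) is None
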