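"""Cox screening machinery: quartiles, partial likelihood, LRT, spline curves."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metscreen.cohorts import SurvivalTable
from metscreen.survival import (cox_fit, hazard_q1_vs_q4, lrt,
                                natural_spline_basis, quartile_stratify,
                                smooth_hr_curve)


def surv(time, event, cid="c") -> SurvivalTable:
    time = np.asarray(time, float)
    return SurvivalTable(cid, pd.DataFrame(
        {"time": time, "event": np.asarray(event, int)},
        index=[f"s{i}" for i in range(time.size)]))


def grid_maximize_partial_likelihood(time, event, x, lo=-8.0, hi=8.0):
    """Independent oracle: dense grid search of the hand-written tie-free
    Cox partial log-likelihood (Breslow form; equals Efron without ties)."""
    time, event, x = (np.asarray(v, float) for v in (time, event, x))

    def loglik(beta):
        ll = 0.0
        for i in np.flatnonzero(event):
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
        return ll

    grid = np.linspace(lo, hi, 4001)
    best = grid[np.argmax([loglik(b) for b in grid])]
    fine = np.linspace(best - 0.01, best + 0.01, 2001)
    return fine[np.argmax([loglik(b) for b in fine])]


class TestQuartileStratify:
    def test_inverted_naming_q1_is_top_quarter(self):
        labels = quartile_stratify(np.arange(1.0, 9.0))
        assert set(np.where(labels == "Q1")[0]) == {6, 7}     # values 7, 8
        assert set(np.where(labels == "Q4")[0]) == {0, 1}     # values 1, 2

    def test_partition_sizes(self):
        for n in (8, 9, 10, 11, 15):
            labels = quartile_stratify(np.random.default_rng(n).normal(size=n))
            sizes = pd.Series(labels).value_counts()
            assert set(sizes.index) == {"Q1", "Q2", "Q3", "Q4"}
            assert sizes.isin([n // 4, -(-n // 4)]).all()

    def test_sign_reversal_swaps_extreme_quartiles(self):
        x = np.random.default_rng(1).normal(size=12)          # distinct, n % 4 == 0
        a, b = quartile_stratify(x), quartile_stratify(-x)
        assert set(np.where(a == "Q1")[0]) == set(np.where(b == "Q4")[0])
        assert set(np.where(a == "Q4")[0]) == set(np.where(b == "Q1")[0])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            quartile_stratify(np.full(10, 2.0))


class TestCoxFit:
    def test_hand_derived_score_equation(self):
        # 4 subjects, alternating covariate: beta solves
        # 2 = 2u/(u+1) + u/(u+2), u = exp(beta) -> beta ~ 0.9406
        fit = cox_fit((np.array([1.0, 2, 3, 4]), np.ones(4, int)), np.array([1.0, 0, 1, 0]))
        assert fit.converged
        assert fit.beta[0] == pytest.approx(0.9406, abs=1e-3)
        u = np.exp(fit.beta[0])
        assert 2 * u / (u + 1) + u / (u + 2) == pytest.approx(2.0, abs=1e-6)

    def test_mirror_symmetric_groups_give_beta_zero(self):
        time = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        event = np.ones(6, int)
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        fit = cox_fit((time, event), x)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_grid_oracle_on_small_tiefree_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        time = rng.exponential(1.0, n)                        # continuous: tie-free
        event = (rng.uniform(size=n) < 0.8).astype(int)
        event[:2] = 1
        x = rng.normal(size=n)
        fit = cox_fit((time, event), x)
        if not fit.converged:
            pytest.skip("separated instance; covered by the divergence test")
        ref = grid_maximize_partial_likelihood(time, event, x)
        assert fit.beta[0] == pytest.approx(ref, abs=1e-4)

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(5)
        n = 40
        time = rng.exponential(1.0, n)
        event = (rng.uniform(size=n) < 0.7).astype(int)
        x = rng.normal(size=n)
        fe = cox_fit((time, event), x, ties="efron")
        fb = cox_fit((time, event), x, ties="breslow")
        assert fe.beta[0] == pytest.approx(fb.beta[0], abs=1e-8)
        assert fe.loglik == pytest.approx(fb.loglik, abs=1e-8)

    def test_matches_lifelines_on_tied_data(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(7)
        n = 120
        x = rng.standard_normal(n)
        time = np.round(rng.exponential(np.exp(-0.6 * x)) * 20, 1) + 0.1
        event = (rng.uniform(size=n) < 0.7).astype(int)
        fit = cox_fit((time, event), x)
        ref = CoxPHFitter().fit(pd.DataFrame({"t": time, "e": event, "x": x}), "t", "e")
        assert fit.beta[0] == pytest.approx(ref.params_["x"], abs=1e-5)
        assert fit.se[0] == pytest.approx(ref.standard_errors_["x"], abs=1e-5)
        assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-6)

    def test_monotone_likelihood_flagged_not_raised(self):
        # all events in the x=1 arm precede every x=0 event: separation
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 0, 1, 1])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        fit = cox_fit((time, event), x)
        assert not fit.converged

    def test_requires_two_events(self):
        with pytest.raises(ValueError):
            cox_fit((np.array([1.0, 2.0, 3.0]), np.array([1, 0, 0])), np.array([1.0, 0, 1]))


class TestLrt:
    def test_equal_logliks_give_p_one(self):
        assert lrt(-10.0, -10.0, df=1) == 1.0

    def test_chi2_critical_value(self):
        assert lrt(-8.0795, -10.0, df=1) == pytest.approx(0.05, abs=1e-3)

    def test_monotone_decreasing_in_statistic(self):
        ps = [lrt(-10.0 + d, -10.0, df=1) for d in (0.1, 0.5, 1.0, 3.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            lrt(-11.0, -10.0, df=1)


class TestHazardQ1VsQ4:
    def _planted(self, seed, beta=1.0, n=200):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        t = np.round(rng.exponential(np.exp(-beta * x)) * 40, 1) + 0.1
        c = rng.uniform(0, 120, n)
        return x, surv(np.minimum(t, c), (t <= c).astype(int))

    def test_planted_positive_effect_gives_hr_above_one(self):
        hits = 0
        for seed in range(40):
            x, s = self._planted(seed)
            r = hazard_q1_vs_q4(x, s)
            hits += r.converged and r.hr > 1
        assert hits >= 38                                     # >= 95% of replicates

    def test_null_pvalues_uniform_across_replicates(self):
        ps = []
        for seed in range(150):
            rng = np.random.default_rng(10_000 + seed)
            x = rng.standard_normal(120)
            t = np.round(rng.exponential(30.0, 120), 1) + 0.1
            c = rng.uniform(0, 90, 120)
            r = hazard_q1_vs_q4(x, surv(np.minimum(t, c), (t <= c).astype(int)))
            ps.append(r.lrt_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_negating_expression_inverts_hazard_ratio(self):
        x, s = self._planted(3)
        a = hazard_q1_vs_q4(x, s)
        b = hazard_q1_vs_q4(-x, s)
        assert a.hr == pytest.approx(1.0 / b.hr, rel=1e-5)

    def test_invariant_to_monotone_transform(self):
        x, s = self._planted(4)
        a = hazard_q1_vs_q4(x, s)
        b = hazard_q1_vs_q4(np.exp(x), s)                     # rank-preserving
        assert a.beta == pytest.approx(b.beta, abs=1e-10)
        assert a.lrt_p == pytest.approx(b.lrt_p, abs=1e-10)


class TestSmoothHRCurve:
    def _sim(self, seed, shape="lin", n=300):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        eta = 0.8 * x if shape == "lin" else 0.8 * (x ** 2 - 1)
        t = np.round(rng.exponential(np.exp(-eta)) * 30, 1) + 0.1
        c = rng.uniform(0, 60, n)
        return x, surv(np.maximum(np.minimum(t, c), 0.1), (t <= c).astype(int))

    def test_single_candidate_reduces_to_straight_line(self):
        x, s = self._sim(0)
        curve = smooth_hr_curve(x, s, df_candidates=(1,))
        assert curve.df_selected == 1
        resid = np.polyfit(curve.grid, curve.log_hr, 1, full=True)[1]
        assert float(resid[0]) < 1e-18

    def test_curve_anchored_at_mean_expression(self):
        x, s = self._sim(1)
        curve = smooth_hr_curve(x, s)
        anchored = np.interp(x.mean(), curve.grid, curve.log_hr)
        assert anchored == pytest.approx(0.0, abs=0.02)       # grid interpolation slack

    def test_quadratic_hazard_selects_flexible_df(self):
        hits = sum(smooth_hr_curve(*self._sim(100 + s, "quad")).df_selected >= 2
                   for s in range(10))
        assert hits >= 8

    def test_spline_basis_shapes_and_linearity(self):
        x = np.linspace(-2, 2, 50)
        assert natural_spline_basis(x, 1).shape == (50, 1)
        for df in (2, 3, 4):
            assert natural_spline_basis(x, df).shape == (50, df)
        # natural constraint: linear (zero second difference) beyond boundaries
        pts = np.array([-6.0, -5.0, -4.0, 4.0, 5.0, 6.0])
        b = natural_spline_basis(pts, 3, boundary=(-2.0, 2.0), knots=(0.0, 1.0))
        for col in b.T:
            assert np.diff(col[:3], 2)[0] == pytest.approx(0.0, abs=1e-9)
            assert np.diff(col[3:], 2)[0] == pytest.approx(0.0, abs=1e-9)

    def test_preconditions_enforced(self):
        x, s = self._sim(2, n=20)
        with pytest.raises(ValueError):
            smooth_hr_curve(x, s)
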