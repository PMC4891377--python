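"""Pairwise fits, subject t map, Welch test, bad-run exclusion, reliability."""

import numpy as np
import pytest
from scipy import ndimage, stats

import unbiased as ub
from unbiased.core import T_CLAMP

from conftest import tiny_session, voxel_run


def closed_form_slope(x, y):
    """Independent oracle: simple-regression formulas computed directly."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    T = x.size
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    beta = sxy / sxx
    resid = y - (y.mean() - beta * x.mean()) - beta * x
    se = np.sqrt((resid ** 2).sum() / (T - 2) / sxx)
    r2 = 1.0 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
    return beta, beta / se, r2


class TestPairFit:
    def test_hand_computed_fixture(self):
        # Sxy/Sxx = 6.5/5, SE from SSres = 0.3 with dof 2
        rj = voxel_run([0, 1, 2, 3], run_id=0)
        rk = voxel_run([0, 1, 2, 4], run_id=1)
        fit = ub.pair_fit(rj, rk, np.ones((1, 1, 1), bool))
        assert fit.beta[0, 0, 0] == pytest.approx(1.3)
        assert fit.t[0, 0, 0] == pytest.approx(7.505553499, rel=1e-9)
        assert fit.r2[0, 0, 0] == pytest.approx(1 - 0.30 / 8.75, rel=1e-9)
        assert fit.dof == 2

    def test_perfect_fit_clamps_t(self):
        r = voxel_run([0, 1, 2, 3], run_id=0)
        fit = ub.pair_fit(r, voxel_run([0, 1, 2, 3], run_id=1),
                          np.ones((1, 1, 1), bool))
        assert fit.beta[0, 0, 0] == pytest.approx(1.0)
        assert fit.t[0, 0, 0] == T_CLAMP

    def test_constant_response_gives_zero(self):
        r = voxel_run([0, 1, 2, 3], run_id=0)
        fit = ub.pair_fit(r, voxel_run([5, 5, 5, 5], run_id=1),
                          np.ones((1, 1, 1), bool))
        assert fit.beta[0, 0, 0] == 0.0 and fit.t[0, 0, 0] == 0.0

    def test_matches_closed_form_on_random_series(self, rng):
        x = rng.standard_normal((200, 56))
        y = 0.4 * x + rng.standard_normal((200, 56))
        rj = ub.RunSeries(data=x.reshape(200, 1, 1, 56), tr=1.0, run_id=0)
        rk = ub.RunSeries(data=y.reshape(200, 1, 1, 56), tr=1.0, run_id=1)
        fit = ub.pair_fit(rj, rk, np.ones((200, 1, 1), bool))
        for i in range(0, 200, 7):
            b, t, r2 = closed_form_slope(x[i], y[i])
            assert fit.beta[i, 0, 0] == pytest.approx(b, rel=1e-8)
            assert fit.t[i, 0, 0] == pytest.approx(t, rel=1e-8)
            assert fit.r2[i, 0, 0] == pytest.approx(r2, rel=1e-8)

    def test_t_symmetric_in_pair_order_and_equals_correlation_form(self, rng):
        x = rng.standard_normal((50, 30))
        y = 0.5 * x + rng.standard_normal((50, 30))
        mask = np.ones((50, 1, 1), bool)
        rj = ub.RunSeries(data=x.reshape(50, 1, 1, 30), tr=1.0, run_id=0)
        rk = ub.RunSeries(data=y.reshape(50, 1, 1, 30), tr=1.0, run_id=1)
        f_jk = ub.pair_fit(rj, rk, mask)
        f_kj = ub.pair_fit(rk, rj, mask)
        np.testing.assert_allclose(f_jk.t, f_kj.t, rtol=1e-6)
        r = np.array([np.corrcoef(x[i], y[i])[0, 1] for i in range(50)])
        t_corr = r * np.sqrt(28) / np.sqrt(1 - r ** 2)
        np.testing.assert_allclose(f_jk.t[:, 0, 0], t_corr, rtol=1e-6)

    def test_same_run_rejected(self):
        r = voxel_run([0, 1, 2, 3], run_id=0)
        with pytest.raises(ValueError):
            ub.pair_fit(r, r, np.ones((1, 1, 1), bool))


class TestAllPairFits:
    @pytest.mark.parametrize("n,expected", [(2, 1), (8, 28), (20, 190)])
    def test_pair_count_is_n_choose_2(self, n, expected):
        s = tiny_session(n_runs=n, grid=(3, 3, 1), T=8)
        ps = ub.all_pair_fits(s)
        assert len(ps.pairs) == expected
        assert all(p.j < p.k for p in ps.pairs)


class TestSubjectTMap:
    def _pairs_with_betas(self, betas):
        """PairStatSet over 3 runs with prescribed single-voxel betas."""
        mask = np.ones((1, 1, 1), bool)
        pairs = []
        for (j, k), b in zip([(0, 1), (0, 2), (1, 2)], betas):
            z = np.zeros((1, 1, 1))
            pairs.append(ub.PairFit(j=j, k=k, beta=z + b, t=z.copy(),
                                    r2=z.copy(), ss_tot=z.copy(), dof=6))
        return ub.PairStatSet(pairs=pairs, n_runs=3, mask=mask)

    def test_one_sample_t_closed_form(self):
        ps = self._pairs_with_betas([1.0, 2.0, 3.0])
        t = ub.subject_t_map(ps, [0, 1, 2])
        assert t[0, 0, 0] == pytest.approx(2 * np.sqrt(3), rel=1e-9)

    def test_zero_betas_give_zero_t(self):
        ps = self._pairs_with_betas([0.0, 0.0, 0.0])
        assert ub.subject_t_map(ps, [0, 1, 2])[0, 0, 0] == 0.0

    def test_equal_positive_betas_clamp(self):
        ps = self._pairs_with_betas([0.5, 0.5, 0.5])
        assert ub.subject_t_map(ps, [0, 1, 2])[0, 0, 0] == T_CLAMP

    def test_single_pair_rejected(self):
        ps = self._pairs_with_betas([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            ub.subject_t_map(ps, [0, 1])


class TestWelch:
    def test_hand_computed_fixture(self):
        t, dof, p = ub.welch_one_sided([1, 2, 3, 4], [3, 4, 5, 6])
        assert t == pytest.approx(2.190890230, rel=1e-8)
        assert dof == pytest.approx(6.0, rel=1e-9)
        assert p == pytest.approx(0.035493827, rel=1e-6)

    def test_identical_samples_are_null(self):
        t, _, p = ub.welch_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 0.5

    def test_matches_scipy_oracle(self, rng):
        a = rng.standard_normal(40)
        b = rng.standard_normal(35) + 0.3
        t, dof, p = ub.welch_one_sided(a, b)
        ref = stats.ttest_ind(b, a, equal_var=False, alternative="greater")
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert dof == pytest.approx(ref.df, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_equal_variance_limit_matches_pooled_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a + 2.0
        t, dof, _ = ub.welch_one_sided(a, b)
        pooled = 2.0 / np.sqrt(2 * a.var(ddof=1) / a.size)
        assert t == pytest.approx(pooled, rel=1e-12)
        assert dof == pytest.approx(2 * a.size - 2, rel=1e-9)


class TestActivationMask:
    def test_block_survives_smoothing_and_contains_center(self, rng):
        t_map = rng.standard_normal((20, 20, 10)) * 0.1
        t_map[8:11, 8:11, 4:7] = 10.0
        brain = np.ones((20, 20, 10), bool)
        mask = ub.activation_mask(t_map, brain)
        assert mask[9, 9, 5]
        assert mask.sum() <= 40 and (mask[8:11, 8:11, 4:7]).sum() >= 7
        # oracle: percentile cut + gaussian smoothing computed directly
        thr = np.quantile(t_map, 0.99)
        sm = ndimage.gaussian_filter(((t_map > thr)).astype(float),
                                     2.0 / (2 * np.sqrt(2 * np.log(2))))
        np.testing.assert_array_equal(mask, sm > 0.5)

    def test_constant_map_falls_back_to_tie_set(self):
        t_map = np.full((6, 6, 4), 3.0)
        brain = np.ones((6, 6, 4), bool)
        mask = ub.activation_mask(t_map, brain)
        assert mask.any()

    def test_zero_fwhm_returns_raw_percentile_set(self, rng):
        t_map = rng.standard_normal((12, 12, 6))
        brain = np.ones((12, 12, 6), bool)
        mask = ub.activation_mask(t_map, brain, smooth_fwhm_vox=0.0)
        thr = np.quantile(t_map, 0.99)
        np.testing.assert_array_equal(mask, t_map > thr)


class TestReliabilityAndBeta:
    def _pairs(self, t_values, n_runs=4, dof=54):
        import itertools
        mask = np.ones((1, 1, 1), bool)
        pairs = []
        combos = list(itertools.combinations(range(n_runs), 2))
        for (j, k), tv in zip(combos, t_values):
            z = np.zeros((1, 1, 1))
            pairs.append(ub.PairFit(j=j, k=k, beta=z + tv / 10, t=z + tv,
                                    r2=z.copy(), ss_tot=z.copy(), dof=dof))
        return ub.PairStatSet(pairs=pairs, n_runs=n_runs, mask=mask)

    def test_supra_threshold_fraction_arithmetic(self):
        thr = stats.t.isf(0.001, 54)
        ps = self._pairs([thr + 1, thr + 2, thr + 3, 0.0, 0.0, 0.0])
        rel = ub.reliability_map(ps, range(4))
        assert rel.values[0, 0, 0] == pytest.approx(50.0)
        assert rel.n_pairs == 6

    def test_all_zero_t_gives_zero(self):
        ps = self._pairs([0.0] * 6)
        assert ub.reliability_map(ps, range(4)).values[0, 0, 0] == 0.0

    def test_mean_beta_matches_brute_force(self, rng):
        tv = rng.standard_normal(6) * 5
        ps = self._pairs(list(tv))
        assert ub.mean_beta_map(ps, range(4))[0, 0, 0] == pytest.approx(
            np.mean(tv / 10), rel=1e-9)
        # restriction to a good subset {0,1,2} keeps only its 3 pairs
        sub = [p for p in ps.pairs if p.k <= 2]
        assert ub.mean_beta_map(ps, [0, 1, 2])[0, 0, 0] == pytest.approx(
            np.mean([p.beta[0, 0, 0] for p in sub]), rel=1e-9)


class TestBadRunDetection:
    def test_identical_runs_are_exchangeable(self, rng):
        data = 1000 + rng.standard_normal((6, 6, 4, 20))
        runs = [ub.RunSeries(data=data.copy(), tr=1.0, run_id=i)
                for i in range(5)]
        s = ub.Session(runs=runs, mask=np.ones((6, 6, 4), bool),
                       design=ub.DesignSpec((5.0,), (5.0,), 20.0))
        ps = ub.all_pair_fits(s)
        rep = ub.detect_bad_runs(ps)
        assert rep.excluded == []
        assert all(r.welch_t == 0.0 for r in rep.passes)

    def test_two_run_session_skips_testing(self):
        s = tiny_session(n_runs=2, T=12)
        rep = ub.detect_bad_runs(ub.all_pair_fits(s))
        assert rep.excluded == [] and rep.passes == []
        assert rep.good_runs == [0, 1]

    def test_zero_amplitude_run_is_excluded(self):
        """A run generated without any task response is singled out."""
        session, truth = ub.generate_session(ub.preset("one_bad_run", seed=3))
        res = ub.run_unbiased(session)
        assert res.report.excluded == truth.bad_runs == [6]
        assert sorted(res.report.good_runs + res.report.excluded) == list(range(10))

    def test_selection_rule_variants_agree_on_clear_case(self):
        session, truth = ub.generate_session(ub.preset("one_bad_run", seed=9))
        sd = ub.detrend_session(session)
        pairs = ub.all_pair_fits(sd)
        for sel in ("run_mean_t", "welch"):
            rep = ub.detect_bad_runs(pairs, selection=sel)
            assert rep.excluded == [6]


class TestInvariances:
    def test_sign_flip_of_all_runs_changes_nothing(self, motor_session):
        session, _ = motor_session
        sd = ub.detrend_session(session)
        flipped = ub.Session(runs=[r.copy_with(-r.data) for r in sd.runs],
                             mask=sd.mask, design=sd.design)
        p1 = ub.all_pair_fits(sd)
        p2 = ub.all_pair_fits(flipped)
        for a, b in zip(p1.pairs, p2.pairs):
            np.testing.assert_array_equal(a.beta, b.beta)
            np.testing.assert_array_equal(a.t, b.t)
        r1 = ub.reliability_map(p1, range(10))
        r2 = ub.reliability_map(p2, range(10))
        np.testing.assert_array_equal(r1.values, r2.values)

    def test_global_circular_shift_preserves_pair_stats(self, motor_session):
        session, _ = motor_session
        sd = ub.detrend_session(session)
        shifted = ub.shift_session(sd, 2)
        p1 = ub.all_pair_fits(sd)
        p2 = ub.all_pair_fits(shifted)
        for a, b in zip(p1.pairs, p2.pairs):
            np.testing.assert_allclose(a.t, b.t, rtol=1e-9, atol=1e-9)
        np.testing.assert_array_equal(
            ub.reliability_map(p1, range(10)).values,
            ub.reliability_map(p2, range(10)).values)

    def test_null_reliability_matches_nominal_rate(self):
        """Independent noise across runs exceeds the p<0.001 cut ~0.1% of
        the time, so mean null reliability sits near 0.1%."""
        session, _ = ub.generate_session(ub.preset("pure_noise", seed=17))
        res = ub.run_unbiased(session, exclude_bad=False)
        mean_rel = res.reliability.values[session.mask].mean()
        assert mean_rel == pytest.approx(0.1, abs=0.1)

    def test_active_voxels_recover_high_reliability(self):
        """At 1% signal change and high temporal SNR nearly every active
        voxel reaches reliability >= 90; detrending barely matters once
        drift is absent."""
        cfg = ub.preset("recovery", seed=21)
        session, truth = ub.generate_session(cfg)
        res = ub.run_unbiased(session, exclude_bad=False)
        frac = (res.reliability.values[truth.active_mask] >= 90).mean()
        assert frac >= 0.95
        cfg_flat = ub.preset("recovery", seed=21,
                             drift_coeff_sd=(0.0, 0.0, 0.0))
        s2, t2 = ub.generate_session(cfg_flat)
        f_det = (ub.run_unbiased(s2, exclude_bad=False)
                 .reliability.values[t2.active_mask] >= 90).mean()
        f_raw = (ub.run_unbiased(s2, detrend=False, exclude_bad=False)
                 .reliability.values[t2.active_mask] >= 90).mean()
        assert abs(f_det - f_raw) <= 0.02
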