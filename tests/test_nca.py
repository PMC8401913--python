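import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_profile
from pkquant import nca, synthetic
from pkquant.errors import (
    ConfigurationError,
    InsufficientDataError,
    NotApplicableError,
    WindowError,
)
from pkquant.nca import (
    aumc_trapezoid,
    auc_trapezoid,
    bioavailability,
    cmax_tmax,
    fit_lambda_z,
    half_life,
    mrt,
    run_nca,
    summarize,
    vd_cl,
)
from pkquant.stats import round_half_up


class TestCmaxTmax:
    def test_interior_maximum(self):
        p = make_profile([15, 30, 60], [20, 50, 40], route="oral")
        assert cmax_tmax(p) == (50.0, 30.0)

    def test_monotone_iv_peaks_first(self):
        p = make_profile([5, 15, 30], [100, 60, 30])
        assert cmax_tmax(p) == (100.0, 5.0)

    def test_tie_broken_earliest(self):
        p = make_profile([15, 30, 60, 90], [20, 50, 50, 10], route="oral")
        assert cmax_tmax(p)[1] == 30.0

    def test_all_blq_rejected(self):
        p = make_profile([5, 15], [1, 1], blq=[True, True])
        with pytest.raises(InsufficientDataError):
            cmax_tmax(p)


def lambda_z_oracle(profile):
    """Brute-force best-adjusted-R^2 suffix search, independent implementation."""
    t, c = profile.observed()
    tmax = t[int(np.argmax(c))]
    if profile.route == "oral":
        mask = t > tmax
    else:
        mask = np.ones(t.size, dtype=bool)
    mask &= c > 0
    t, c = t[mask], c[mask]
    best = None
    for s in range(t.size - 2):
        tt, lc = t[s:], np.log(c[s:])
        n = tt.size
        slope, intercept = np.polyfit(tt, lc, 1)
        if slope >= 0:
            continue
        pred = slope * tt + intercept
        ss_res = ((lc - pred) ** 2).sum()
        ss_tot = ((lc - lc.mean()) ** 2).sum()
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if best is None or adj > best[0] + 1e-12:
            best = (adj, -slope, n)
    return best


class TestFitLambdaZ:
    def test_exact_log_linear(self):
        t = np.array([60.0, 90.0, 120.0])
        p = make_profile(t, 100.0 * np.exp(-0.0693 * t))
        fit = fit_lambda_z(p)
        assert fit.lambda_z == pytest.approx(0.0693, rel=1e-12)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-12)

    def test_two_usable_points_rejected(self):
        p = make_profile([5.0, 30.0], [100.0, 50.0])
        with pytest.raises(InsufficientDataError):
            fit_lambda_z(p)

    def test_rising_profile_rejected(self):
        p = make_profile([5, 15, 30, 60], [10, 20, 30, 40])
        with pytest.raises(nca.NoEliminationPhaseError):
            fit_lambda_z(p)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        cfg = synthetic.PKSimConfig(route="iv_bolus", error_cv=0.1,
                                    n_subjects=1, seed=seed)
        p = synthetic.simulate_iv_profile(cfg)[0]
        fit = fit_lambda_z(p)
        adj, lz, n = lambda_z_oracle(p)
        assert fit.lambda_z == pytest.approx(lz, rel=1e-10)
        assert fit.n_points == n

    @pytest.mark.parametrize("seed", range(10))
    def test_oral_matches_oracle(self, seed):
        cfg = synthetic.PKSimConfig(route="oral", dose_per_kg=20.0, ka=0.05,
                                    f_abs=0.01, error_cv=0.1, n_subjects=1,
                                    seed=seed)
        p = synthetic.simulate_oral_profile(cfg)[0]
        fit = fit_lambda_z(p)
        adj, lz, n = lambda_z_oracle(p)
        assert fit.lambda_z == pytest.approx(lz, rel=1e-10)

    def test_last_3_policy(self):
        cfg = synthetic.PKSimConfig(route="iv_bolus", error_cv=0.1,
                                    n_subjects=1, seed=5)
        p = synthetic.simulate_iv_profile(cfg)[0]
        fit = fit_lambda_z(p, "last_3")
        assert fit.n_points == 3
        t, c = p.observed()
        slope, _ = np.polyfit(t[-3:], np.log(c[-3:]), 1)
        assert fit.lambda_z == pytest.approx(-slope, rel=1e-10)

    def test_unknown_policy(self):
        p = make_profile([5, 15, 30, 60], [100, 70, 40, 20])
        with pytest.raises(ConfigurationError):
            fit_lambda_z(p, "first_3")


class TestHalfLife:
    def test_reported_oral_value(self):
        assert round_half_up(half_life(0.005), 1) == 138.6

    def test_ln2(self):
        assert half_life(math.log(2)) == pytest.approx(1.0)

    def test_iv_rate(self):
        # 0.693/0.016 = 43.3; differs from the reported IV mean because
        # per-animal half-lives were averaged, not 0.693/mean(lambda_z)
        assert round_half_up(half_life(0.016), 1) == 43.3

    def test_identity_with_lambda_z(self):
        for lz in (0.001, 0.0137, 0.2):
            assert half_life(lz) * lz == pytest.approx(math.log(2), rel=1e-15)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            half_life(0.0)


class TestAUC:
    def test_constant_concentration(self):
        p = make_profile([0.0, 50.0, 100.0], [10.0, 10.0, 10.0])
        assert auc_trapezoid(p) == pytest.approx(1000.0)

    def test_triangle(self):
        p = make_profile([0.0, 10.0, 20.0], [0.0, 100.0, 0.0], route="oral")
        assert auc_trapezoid(p) == pytest.approx(1000.0)

    def test_dense_exponential_vs_closed_form(self, dense_iv_profile):
        p, k, c0 = dense_iv_profile
        t_end = p.times[-1]
        analytic = c0 / k * (1 - math.exp(-k * t_end))
        assert auc_trapezoid(p) == pytest.approx(analytic, rel=0.002)

    def test_oral_prepends_time_zero(self):
        p = make_profile([10.0, 20.0], [100.0, 0.0], route="oral")
        assert auc_trapezoid(p) == pytest.approx(500.0 + 500.0)

    def test_iv_back_extrapolates_c0(self):
        k = 0.01
        t = np.array([5.0, 15.0, 30.0])
        p = make_profile(t, 1000.0 * np.exp(-k * t))
        # log-linear through the first two points recovers C(0) = 1000 exactly
        auc = auc_trapezoid(p)
        grid_t = np.concatenate([[0.0], t])
        grid_c = np.concatenate([[1000.0], 1000.0 * np.exp(-k * t)])
        assert auc == pytest.approx(np.trapezoid(grid_c, grid_t), rel=1e-12)

    def test_iv_first_point_policy(self):
        t = np.array([5.0, 15.0, 30.0])
        p = make_profile(t, [100.0, 80.0, 60.0])
        auc = auc_trapezoid(p, c0_policy="first_point")
        assert auc == pytest.approx(np.trapezoid([100.0, 80.0, 60.0], t))

    def test_t_end_beyond_data_rejected(self):
        p = make_profile([0.0, 10.0], [5.0, 5.0])
        with pytest.raises(WindowError):
            auc_trapezoid(p, t_end=20.0)

    def test_additive_and_monotone_in_t_end(self):
        p = make_profile([0.0, 10.0, 25.0, 60.0], [100.0, 80.0, 40.0, 10.0])
        a50 = auc_trapezoid(p, 50.0)
        a60 = auc_trapezoid(p, 60.0)
        assert a60 >= a50
        # additivity: [0,60] = [0,25] + trapezoid over [25,60]
        assert auc_trapezoid(p, 25.0) + 0.5 * (40 + 10) * 35 == pytest.approx(a60)

    def test_blq_policy(self):
        # pre-Tmax BLQ contributes 0; post-Tmax BLQ excluded
        p = make_profile([15, 30, 60, 90], [2.0, 50.0, 25.0, 1.0],
                         blq=[True, False, False, True], route="oral")
        expected = np.trapezoid([0.0, 0.0, 50.0, 25.0], [0.0, 15.0, 30.0, 60.0])
        assert auc_trapezoid(p) == pytest.approx(expected)


class TestAUMC:
    def test_constant_concentration(self):
        p = make_profile([0.0, 50.0, 100.0], [10.0, 10.0, 10.0])
        assert aumc_trapezoid(p) == pytest.approx(10.0 * 100.0**2 / 2)

    def test_triangle_first_moment(self):
        p = make_profile([0.0, 10.0, 20.0], [0.0, 100.0, 0.0], route="oral")
        assert aumc_trapezoid(p) == pytest.approx(10_000.0)

    def test_dense_exponential_vs_analytic(self, dense_iv_profile):
        p, k, c0 = dense_iv_profile
        T = p.times[-1]
        analytic = c0 / k**2 * (1 - math.exp(-k * T) * (1 + k * T))
        assert aumc_trapezoid(p) == pytest.approx(analytic, rel=0.005)


class TestMRT:
    def test_constant_profile_half_interval(self):
        p = make_profile([0.0, 50.0, 100.0], [10.0, 10.0, 10.0])
        assert mrt(auc_trapezoid(p), aumc_trapezoid(p)) == pytest.approx(50.0)

    def test_simple_ratio(self):
        assert mrt(1000.0, 10_000.0) == pytest.approx(10.0)

    def test_zero_auc_rejected(self):
        with pytest.raises(ValueError):
            mrt(0.0, 10.0)

    def test_long_dense_iv_approaches_1_over_k(self):
        k = 0.01
        t = np.arange(0.0, 10 * math.log(2) / k + 1.0, 0.5)
        p = make_profile(t, 1000.0 * np.exp(-k * t))
        assert mrt(auc_trapezoid(p), aumc_trapezoid(p)) == pytest.approx(1 / k, rel=0.02)


class TestVdCl:
    def test_direct_arithmetic(self):
        p = make_profile([5.0, 30.0, 60.0], [100.0, 80.0, 60.0],
                         dose_per_kg=2.0, body_weight=0.02)  # dose 40000 ng
        vd, cl = vd_cl(p, 0.01, 100_000.0)
        assert vd == pytest.approx(40.0)
        assert cl == pytest.approx(0.4)

    @given(lz=st.floats(0.001, 0.1), auc=st.floats(1e3, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_cl_over_vd_is_lambda_z(self, lz, auc):
        p = make_profile([5.0, 30.0, 60.0], [100.0, 80.0, 60.0])
        vd, cl = vd_cl(p, lz, auc)
        assert cl / vd == pytest.approx(lz, rel=1e-12)

    def test_oral_rejected(self):
        p = make_profile([15.0, 30.0, 60.0], [10.0, 20.0, 15.0], route="oral")
        with pytest.raises(NotApplicableError):
            vd_cl(p, 0.01, 1000.0)

    def test_missing_body_weight_rejected(self):
        p = make_profile([5.0, 30.0, 60.0], [100.0, 80.0, 60.0], body_weight=None)
        with pytest.raises(ConfigurationError):
            vd_cl(p, 0.01, 1000.0)

    def test_auc_inf_recovers_simulator_volume(self):
        cfg = synthetic.PKSimConfig(route="iv_bolus", error_cv=0.0)
        p = synthetic.simulate_iv_profile(cfg)[0]
        fit = fit_lambda_z(p)
        auc = auc_trapezoid(p)
        vd, _ = vd_cl(p, fit.lambda_z, auc, convention="auc_inf")
        assert vd == pytest.approx(cfg.volume_ml, rel=0.02)


class TestBioavailability:
    def test_equal_dose_normalized_aucs(self):
        assert bioavailability(1000.0, 10.0, 2000.0, 20.0) == pytest.approx(100.0)

    def test_reported_table_means(self):
        # dose-corrected arithmetic on the printed mean AUCs and doses
        f = bioavailability(6176.0, 20.0, 109_500.0, 2.0)
        assert round_half_up(f, 2) == 0.56

    def test_linear_in_oral_auc(self):
        f1 = bioavailability(1000.0, 20.0, 50_000.0, 2.0)
        f2 = bioavailability(500.0, 20.0, 50_000.0, 2.0)
        assert f2 == pytest.approx(f1 / 2)

    def test_zero_inputs_rejected(self):
        with pytest.raises(ValueError):
            bioavailability(0.0, 20.0, 1000.0, 2.0)


class TestRunNCAAndSummarize:
    def test_noise_free_iv_recovers_ground_truth(self):
        cfg = synthetic.PKSimConfig(route="iv_bolus", error_cv=0.0)
        p = synthetic.simulate_iv_profile(cfg)[0]
        res = run_nca(p)
        assert res.lambda_z == pytest.approx(cfg.k_elim, rel=1e-3)
        assert res.t_half * res.lambda_z == pytest.approx(math.log(2), rel=1e-12)
        assert res.c_max == pytest.approx(2590.0, abs=0.1)

    def test_noise_free_dense_lambda_within_0_1_pct(self, dense_iv_profile):
        p, k, _ = dense_iv_profile
        res = run_nca(p)
        assert res.lambda_z == pytest.approx(k, rel=0.001)

    def test_oral_f_against_iv_reference(self):
        iv_cfg = synthetic.PKSimConfig(route="iv_bolus", k_elim=0.025, error_cv=0.0)
        oral_cfg = synthetic.PKSimConfig(route="oral", dose_per_kg=20.0,
                                         k_elim=0.025, ka=0.1, f_abs=0.003,
                                         error_cv=0.0)
        iv_res = run_nca(synthetic.simulate_iv_profile(iv_cfg)[0])
        res = run_nca(synthetic.simulate_oral_profile(oral_cfg)[0],
                      iv_reference=(iv_res.auc_0_t, 2.0))
        assert res.f_pct == pytest.approx(0.3, rel=0.15)

    def test_summarize_identical_subjects(self):
        cfg = synthetic.PKSimConfig(route="iv_bolus", error_cv=0.0, n_subjects=3)
        results = [run_nca(p) for p in synthetic.simulate_iv_profile(cfg)]
        tbl = summarize(results).set_index("parameter")
        np.testing.assert_allclose(tbl["sd"], 0.0, atol=1e-12)
        assert tbl.loc["lambda_z", "n"] == 3

    def test_summarize_mean(self):
        cfg = synthetic.PKSimConfig(route="iv_bolus", error_cv=0.0, n_subjects=2)
        results = [run_nca(p) for p in synthetic.simulate_iv_profile(cfg)]
        results[0].t_half, results[1].t_half = 40.0, 60.0
        tbl = summarize(results).set_index("parameter")
        assert tbl.loc["t_half", "mean"] == pytest.approx(50.0)

    def test_summarize_mixed_routes_rejected(self):
        iv = run_nca(synthetic.simulate_iv_profile(
            synthetic.PKSimConfig(route="iv_bolus"))[0])
        oral = run_nca(synthetic.simulate_oral_profile(
            synthetic.PKSimConfig(route="oral", dose_per_kg=20.0, ka=0.05,
                                  f_abs=0.01))[0])
        with pytest.raises(ValueError):
            summarize([iv, oral])

    def test_summarize_matches_mean_sd_cv_oracle(self):
        from pkquant.validation import mean_sd_cv
        cfg = synthetic.PKSimConfig(route="iv_bolus", error_cv=0.05, n_subjects=5, seed=8)
        results = [run_nca(p) for p in synthetic.simulate_iv_profile(cfg)]
        tbl = summarize(results).set_index("parameter")
        oracle = mean_sd_cv([r.t_half for r in results], "population")
        assert tbl.loc["t_half", "mean"] == pytest.approx(oracle.mean, rel=1e-12)
        assert tbl.loc["t_half", "sd"] == pytest.approx(oracle.sd, rel=1e-12)
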