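"""Gamma-variate model evaluation, closed-form indices, and fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from ceusperf import (
    AcquisitionSpec,
    GammaVariateParams,
    NoiseModel,
    TimeIntensityCurve,
    derive_indices,
    eval_gamma_variate,
    fit_gamma_variate,
    goodness_of_fit,
    loglinear_initialize,
    simulate_tic,
)
from ceusperf.gamma_fit import FitOptions
from ceusperf.models import (
    InitializationFailure,
    InsufficientDataError,
    InvalidParameterError,
    TruncatedBolusError,
    UndefinedRSquaredError,
)
from conftest import random_params

E = math.e


class TestEvalGammaVariate:
    def test_unit_parameters_peak_value(self):
        p = GammaVariateParams(A=1, alpha=1, t0=0, C=0)
        val = eval_gamma_variate(p, [1.0])[0]
        assert val == pytest.approx(1.0 * math.exp(-1.0), rel=1e-12)

    def test_value_at_lag_boundary_is_baseline(self):
        p = GammaVariateParams(A=3, alpha=0.4, t0=7.0, C=2.5)
        assert eval_gamma_variate(p, [7.0])[0] == 2.5
        assert np.all(eval_gamma_variate(p, [0.0, 3.0, 6.99]) == 2.5)

    def test_dense_grid_argmax_matches_closed_form(self):
        # brute-force maximization over t in [0, 40] step 0.001
        p = GammaVariateParams(A=2, alpha=0.5, t0=0, C=0)
        grid = np.arange(0, 40.0001, 0.001)
        vals = eval_gamma_variate(p, grid)
        k = int(np.argmax(vals))
        assert grid[k] == pytest.approx(2.000, abs=1e-3)  # 1/alpha
        assert vals[k] == pytest.approx(2 / (0.5 * E), rel=1e-6)  # A/(alpha*e)

    def test_non_finite_parameter_rejected(self):
        with pytest.raises(InvalidParameterError):
            GammaVariateParams(A=np.nan, alpha=1.0)
        with pytest.raises(InvalidParameterError):
            GammaVariateParams(A=1.0, alpha=np.inf)

    def test_non_finite_times_rejected(self):
        p = GammaVariateParams(A=1, alpha=1)
        with pytest.raises(InvalidParameterError):
            eval_gamma_variate(p, [0.0, np.nan])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_peak_location_and_height_property(self, seed):
        """Dense-grid argmax sits at t0 + TTP; grid max equals C + DPI."""
        rng = np.random.default_rng(seed)
        p = random_params(rng)
        idx = derive_indices(p)
        step = idx.TTP / 1000
        grid = np.arange(p.t0, p.t0 + 10 * idx.TTP, step)
        vals = eval_gamma_variate(p, grid)
        k = int(np.argmax(vals))
        assert abs(grid[k] - (p.t0 + idx.TTP)) <= step
        assert vals[k] == pytest.approx(p.C + idx.DPI, rel=1e-6)


class TestDeriveIndices:
    def test_unit_parameter_identities(self):
        idx = derive_indices(GammaVariateParams(A=1, alpha=1))
        assert idx.AUC == 1.0
        assert idx.DPI == pytest.approx(1 / E, rel=1e-15)
        assert idx.TTP == 1.0

    def test_against_numeric_integration_and_grid_peak(self):
        # independent oracles: quadrature for AUC, grid search for DPI/TTP
        p = GammaVariateParams(A=2.0, alpha=0.5)
        idx = derive_indices(p)
        auc_num, _ = quad(lambda t: p.A * t * np.exp(-p.alpha * t), 0, np.inf)
        assert idx.AUC == pytest.approx(8.0, rel=1e-12)
        assert idx.AUC == pytest.approx(auc_num, rel=1e-9)
        grid = np.arange(0, 40, 0.0005)
        vals = p.A * grid * np.exp(-p.alpha * grid)
        assert idx.DPI == pytest.approx(vals.max(), rel=1e-6)
        assert idx.TTP == pytest.approx(grid[np.argmax(vals)], abs=1e-3)

    def test_cohort_baseline_inversion(self):
        """Pre-operative cohort means TTP = 9.03 s and DPI = 13.04 dB
        invert to alpha ~ 0.1107 1/s and A ~ 3.93 dB/s."""
        alpha = 1 / 9.03
        assert alpha == pytest.approx(0.1107, abs=5e-4)
        A = 13.04 * alpha * E
        assert A == pytest.approx(3.93, abs=5e-3)
        idx = derive_indices(GammaVariateParams(A=A, alpha=alpha))
        assert idx.TTP == pytest.approx(9.03, rel=1e-12)
        assert idx.DPI == pytest.approx(13.04, rel=1e-12)

    def test_identity_suite_random_draws(self, param_rng):
        """AUC*alpha^2 = A, DPI*alpha*e = A, TTP*alpha = 1 on 1,000 draws."""
        for _ in range(1000):
            p = random_params(param_rng)
            idx = derive_indices(p)
            assert idx.AUC * p.alpha**2 == pytest.approx(p.A, rel=1e-12)
            assert idx.DPI * p.alpha * E == pytest.approx(p.A, rel=1e-12)
            assert idx.TTP * p.alpha == pytest.approx(1.0, rel=1e-12)


class TestLoglinearInitialize:
    def test_recovers_slope_and_intercept_analytically(self):
        p = GammaVariateParams(A=3, alpha=0.4, t0=0, C=0)
        t = np.arange(0.5, 30, 0.5)
        tic = TimeIntensityCurve(times=t, intensities=eval_gamma_variate(p, t))
        est = loglinear_initialize(tic, t0=0.0, C=0.0)
        assert est.alpha == pytest.approx(0.4, rel=1e-9)
        assert math.log(est.A) == pytest.approx(math.log(3), abs=1e-9)

    def test_noiseless_round_trip(self, truth_params, clean_tic):
        est = loglinear_initialize(clean_tic, t0=truth_params.t0, C=truth_params.C)
        assert est.A == pytest.approx(truth_params.A, rel=1e-9)
        assert est.alpha == pytest.approx(truth_params.alpha, rel=1e-9)

    def test_increasing_ramp_signals_failure(self):
        t = np.arange(1.0, 20.0)
        tic = TimeIntensityCurve(times=t, intensities=t.copy())
        with pytest.raises(InitializationFailure):
            loglinear_initialize(tic, t0=0.0, C=0.0)

    def test_too_few_usable_samples(self):
        tic = TimeIntensityCurve(times=np.array([0.0, 1.0, 2.0]),
                                 intensities=np.array([0.0, 0.0, 1.0]))
        with pytest.raises(InsufficientDataError):
            loglinear_initialize(tic, t0=0.0, C=0.0)


class TestFitGammaVariate:
    def test_noiseless_recovery(self, truth_params, clean_tic):
        fit = fit_gamma_variate(clean_tic)
        assert fit.params.A == pytest.approx(truth_params.A, rel=1e-6)
        assert fit.params.alpha == pytest.approx(truth_params.alpha, rel=1e-6)
        assert fit.params.t0 == pytest.approx(truth_params.t0, rel=1e-6)
        assert fit.params.C == pytest.approx(truth_params.C, rel=1e-6)
        assert fit.r_squared > 0.999999
        assert fit.converged

    def test_constant_tic_is_truncated_bolus(self):
        t = np.arange(0, 20.0)
        tic = TimeIntensityCurve(times=t, intensities=np.full_like(t, 7.0))
        with pytest.raises(TruncatedBolusError):
            fit_gamma_variate(tic)

    def test_rising_tail_is_truncated_bolus(self):
        # peak at the last sample: bolus cut off by the end of capture
        p = GammaVariateParams(A=2, alpha=0.05, t0=0, C=0)
        t = np.arange(0, 10.0, 0.5)
        tic = TimeIntensityCurve(times=t, intensities=eval_gamma_variate(p, t))
        with pytest.raises(TruncatedBolusError):
            fit_gamma_variate(tic)

    def test_fixed_t0_and_C_are_respected(self, truth_params, clean_tic):
        fit = fit_gamma_variate(clean_tic, FitOptions(fix_t0=5.0, fix_C=0.5))
        assert fit.params.t0 == 5.0
        assert fit.params.C == 0.5
        assert fit.params.A == pytest.approx(truth_params.A, rel=1e-8)

    def test_sse_never_worse_than_initialization(self, truth_params, acq_10hz):
        rng = np.random.default_rng(11)
        for i in range(20):
            p = GammaVariateParams(
                A=float(rng.uniform(0.5, 10)),
                alpha=float(rng.uniform(0.05, 0.5)),
                t0=float(rng.uniform(0, 20)),
                C=float(rng.uniform(0, 5)),
            )
            tic = simulate_tic(
                p, acq_10hz,
                NoiseModel("multiplicative-linear", 0.1, seed=i),
            )
            fit = fit_gamma_variate(tic)
            init = loglinear_initialize(tic, t0=fit.params.t0, C=fit.params.C)
            resid = eval_gamma_variate(init, tic.times) - tic.intensities
            assert fit.sse <= float(resid @ resid) + 1e-12

    def test_scaling_equivariance(self, truth_params, acq_10hz):
        """Scaling intensities above baseline by k scales A, AUC, DPI by k
        and leaves alpha, TTP unchanged."""
        k = 3.7
        base = simulate_tic(truth_params, acq_10hz, NoiseModel())
        scaled = TimeIntensityCurve(
            times=base.times,
            intensities=(base.intensities - truth_params.C) * k + truth_params.C,
        )
        f1 = fit_gamma_variate(base)
        f2 = fit_gamma_variate(scaled)
        assert f2.params.A == pytest.approx(k * f1.params.A, rel=1e-9)
        assert f2.indices.AUC == pytest.approx(k * f1.indices.AUC, rel=1e-9)
        assert f2.indices.DPI == pytest.approx(k * f1.indices.DPI, rel=1e-9)
        assert f2.params.alpha == pytest.approx(f1.params.alpha, rel=1e-9)
        assert f2.indices.TTP == pytest.approx(f1.indices.TTP, rel=1e-9)

    def test_nls_beats_grid_oracle_on_small_instances(self):
        """On noiseless instances the NLS solution's sse is at least as
        good as an exhaustive grid around the truth."""
        rng = np.random.default_rng(5)
        acq = AcquisitionSpec(duration=80.0, frame_rate=5.0)
        for _ in range(10):
            p = GammaVariateParams(
                A=float(rng.uniform(1, 5)),
                alpha=float(rng.uniform(0.1, 0.5)),
                t0=float(rng.uniform(2, 10)),
                C=float(rng.uniform(0, 2)),
            )
            tic = simulate_tic(p, acq, NoiseModel())
            fit = fit_gamma_variate(tic)
            t, y = tic.times, tic.intensities
            best = np.inf
            for t0v in np.linspace(p.t0 * 0.8, p.t0 * 1.2, 15):
                dt = np.clip(t - t0v, 0, None)
                for alv in np.linspace(p.alpha * 0.8, p.alpha * 1.2, 15):
                    basis = dt * np.exp(-alv * dt)
                    for Av in np.linspace(p.A * 0.8, p.A * 1.2, 15):
                        r = y - Av * basis - p.C
                        best = min(best, float(r @ r))
            assert fit.sse <= best + 1e-12


class TestGoodnessOfFit:
    def test_perfect_fit(self, truth_params, clean_tic):
        fit = fit_gamma_variate(clean_tic)
        gof = goodness_of_fit(fit, clean_tic)
        assert gof["r_squared"] == pytest.approx(1.0, abs=1e-12)
        assert gof["rmse"] == pytest.approx(0.0, abs=1e-9)

    def test_mean_only_fit_has_zero_r_squared(self):
        t = np.arange(8.0)
        y = np.array([1, 3, 1, 3, 1, 3, 1, 3], dtype=float)
        # residuals (1, -1, ...) around the mean: rmse = 1, r2 = 0
        sse = float(((y - y.mean()) ** 2).sum())
        r2 = 1 - sse / sse
        assert r2 == 0.0
        assert math.sqrt(sse / len(y)) == 1.0

    def test_zero_variance_tic_raises(self, clean_tic):
        fit = fit_gamma_variate(clean_tic)
        flat = TimeIntensityCurve(
            times=clean_tic.times,
            intensities=np.full(clean_tic.n_samples, 4.0),
        )
        with pytest.raises(UndefinedRSquaredError):
            goodness_of_fit(fit, flat)
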