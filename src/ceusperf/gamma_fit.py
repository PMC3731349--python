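"""Gamma-variate indicator-dilution model: evaluation, fitting, indices.

The bolus passage of an ultrasound contrast agent through the distal
microcirculation traces a highly skewed curve with an exponentially
decaying tail; the lagged gamma-variate

    I(t) = A * (t - t0) * exp(-alpha * (t - t0)) + C,   t >= t0

is the canonical indicator-dilution fit. From the fitted (A, alpha) the
perfusion indices follow in closed form: AUC = A/alpha^2 (area under the
baseline-subtracted curve), DPI = A/(alpha*e) (curve amplitude above
baseline), and TTP = 1/alpha (arrival-to-peak interval).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .models import (
    FitResult,
    GammaVariateParams,
    InitializationFailure,
    InsufficientDataError,
    InvalidParameterError,
    PerfusionIndices,
    TimeIntensityCurve,
    TruncatedBolusError,
    UndefinedRSquaredError,
)

__all__ = [
    "eval_gamma_variate",
    "derive_indices",
    "loglinear_initialize",
    "fit_gamma_variate",
    "goodness_of_fit",
    "FitOptions",
]


def eval_gamma_variate(params: GammaVariateParams, times) -> np.ndarray:
    """Evaluate the lagged gamma-variate model at the given times.

    Returns C for every time before bolus arrival (t < t0). The curve
    maximum over t >= t0 is C + A/(alpha*e), attained at t = t0 + 1/alpha.
    """
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidParameterError("times must be finite")
    dt = t - params.t0
    out = np.full(t.shape, params.C, dtype=float)
    rising = dt >= 0
    out[rising] = params.A * dt[rising] * np.exp(-params.alpha * dt[rising]) + params.C
    return out


def derive_indices(params: GammaVariateParams) -> PerfusionIndices:
    """Closed-form perfusion indices from fitted kinetic parameters.

    AUC = A/alpha^2, DPI = A/(alpha*e), TTP = 1/alpha; all are
    baseline-subtracted (they depend on A and alpha only).
    """
    if params.alpha <= 0:
        raise InvalidParameterError("alpha must be > 0")
    a, al = params.A, params.alpha
    return PerfusionIndices(
        A=a,
        alpha=al,
        AUC=a / al**2,
        DPI=a / (al * math.e),
        TTP=1.0 / al,
    )


def loglinear_initialize(
    tic: TimeIntensityCurve, t0: float, C: float, eps: Optional[float] = None
) -> GammaVariateParams:
    """Initialize (A, alpha) by linearizing the gamma-variate.

    For samples above baseline and after arrival,
    ln((I - C)/(t - t0)) = ln A - alpha*(t - t0), so ordinary least
    squares on (t - t0) gives slope -alpha and intercept ln A. On a
    noiseless gamma-variate this recovers the true parameters exactly.

    eps is the above-baseline inclusion threshold; by default it scales
    with the enhancement height (1e-7 of peak minus baseline) so that
    far-tail samples, where I - C drowns in the floating-point granularity
    of C itself, do not corrupt the regression.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 samples with I > C + eps and t > t0.
    InitializationFailure
        Fitted slope >= 0 (no wash-out decay present); the caller should
        fall back to a peak-based heuristic.
    """
    t = tic.times
    y = tic.intensities
    if eps is None:
        eps = max(1e-7 * (float(y.max()) - C), 1e-12)
    mask = (y > C + eps) & (t > t0)
    if int(mask.sum()) < 3:
        raise InsufficientDataError(
            f"need >= 3 samples above baseline after t0, got {int(mask.sum())}"
        )
    dt = t[mask] - t0
    z = np.log((y[mask] - C) / dt)
    slope, intercept = np.polyfit(dt, z, 1)
    if slope >= 0:
        raise InitializationFailure("log-linear slope >= 0: no decay detected")
    return GammaVariateParams(A=float(np.exp(intercept)), alpha=float(-slope), t0=t0, C=C)


@dataclass(frozen=True)
class FitOptions:
    """Options for the nonlinear least-squares fit.

    fix_t0 / fix_C pin the lag or the baseline instead of estimating
    them; tol is the relative sse-change convergence criterion.
    """

    fix_t0: Optional[float] = None
    fix_C: Optional[float] = None
    max_iter: int = 500
    tol: float = 1e-8
    linearize: bool = False  # fit on linear power 10^(I/10) instead of dB


def _smoothed_peak_index(y: np.ndarray) -> int:
    """First index attaining the max of the 3-sample moving average."""
    if y.size < 3:
        return int(np.argmax(y))
    kernel = np.ones(3) / 3.0
    sm = np.convolve(y, kernel, mode="same")
    # edges of 'same' convolution average over 2 samples; rescale
    sm[0] = y[:2].mean()
    sm[-1] = y[-2:].mean()
    return int(np.argmax(sm))


def _initial_guess(tic: TimeIntensityCurve, peak_idx: int) -> GammaVariateParams:
    """Baseline from pre-arrival samples, then log-linear (A, alpha)."""
    t, y = tic.times, tic.intensities
    # baseline: first 10% of samples before the peak, at least 3
    n_base = max(3, min(peak_idx, max(3, tic.n_samples // 10)))
    C0 = float(np.mean(y[:n_base]))
    sigma0 = float(np.std(y[:n_base], ddof=1)) if n_base > 1 else 0.0
    # crude arrival: last pre-peak sample still near baseline
    thresh = C0 + max(3.0 * sigma0, 1e-9 * max(1.0, abs(C0)))
    above = np.nonzero(y[: peak_idx + 1] > thresh)[0]
    if above.size:
        t0_guess = float(t[max(int(above[0]) - 1, 0)])
    else:
        t0_guess = float(t[0])
    try:
        return loglinear_initialize(tic, t0=t0_guess, C=C0)
    except (InsufficientDataError, InitializationFailure):
        ttp_obs = max(float(t[peak_idx]) - t0_guess, float(t[1] - t[0]))
        alpha0 = 1.0 / ttp_obs
        peak_height = max(float(y[peak_idx]) - C0, 1e-9)
        return GammaVariateParams(
            A=peak_height * alpha0 * math.e, alpha=alpha0, t0=t0_guess, C=C0
        )


def fit_gamma_variate(
    tic: TimeIntensityCurve, options: FitOptions | None = None
) -> FitResult:
    """Fit the gamma-variate model to a TIC by bounded least squares.

    The fit runs on the TIC in its recorded units (dB video intensity by
    default); set ``options.linearize`` to fit on linear power instead.
    Parameters are bounded (A >= 0, alpha > 0, t0 in [0, time of the
    observed maximum], C free) and initialized by baseline estimation
    plus log-linearization, falling back to a peak heuristic.

    Raises
    ------
    TruncatedBolusError
        No interior peak after 3-sample smoothing (constant series or
        bolus cut off at either end).
    """
    opts = options or FitOptions()
    if tic.n_samples < 8:
        raise InsufficientDataError("need >= 8 samples to fit")
    t = tic.times.copy()
    y = tic.intensities.copy()
    if opts.linearize and tic.units_flag == "dB":
        y = 10.0 ** (y / 10.0)
    peak_idx = _smoothed_peak_index(y)
    if peak_idx == 0 or peak_idx == y.size - 1:
        raise TruncatedBolusError("peak at series boundary: bolus not fully captured")

    work = TimeIntensityCurve(times=t, intensities=y, units_flag=tic.units_flag)
    init = _initial_guess(work, peak_idx)
    if opts.fix_t0 is not None:
        init = GammaVariateParams(init.A, init.alpha, float(opts.fix_t0), init.C)
    if opts.fix_C is not None:
        init = GammaVariateParams(init.A, init.alpha, init.t0, float(opts.fix_C))

    t0_max = float(t[peak_idx])
    free_t0 = opts.fix_t0 is None
    free_C = opts.fix_C is None

    tiny = 1e-12

    def pack(p: GammaVariateParams) -> np.ndarray:
        x = [p.A, p.alpha]
        if free_t0:
            x.append(p.t0)
        if free_C:
            x.append(p.C)
        return np.asarray(x, dtype=float)

    def unpack(x: np.ndarray) -> GammaVariateParams:
        i = 2
        t0 = float(x[i]) if free_t0 else float(opts.fix_t0)  # type: ignore[arg-type]
        if free_t0:
            i += 1
        C = float(x[i]) if free_C else float(opts.fix_C)  # type: ignore[arg-type]
        return GammaVariateParams(
            A=max(float(x[0]), 0.0), alpha=max(float(x[1]), tiny), t0=max(t0, 0.0), C=C
        )

    def residuals(x: np.ndarray) -> np.ndarray:
        return eval_gamma_variate(unpack(x), t) - y

    lo = [0.0, tiny]
    hi = [np.inf, np.inf]
    if free_t0:
        lo.append(0.0)
        hi.append(t0_max)
    if free_C:
        lo.append(-np.inf)
        hi.append(np.inf)

    x0 = pack(init)
    x0 = np.clip(x0, lo, hi)
    sse_init = float(np.sum(residuals(x0) ** 2))

    res = least_squares(
        residuals,
        x0,
        bounds=(lo, hi),
        method="trf",
        ftol=opts.tol,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=opts.max_iter * (len(x0) + 1),
    )
    params = unpack(res.x)
    sse = float(np.sum(res.fun**2))
    if sse > sse_init:  # least_squares never worsens, but guard anyway
        params = unpack(x0)
        sse = sse_init
    indices = derive_indices(params)
    fitted = eval_gamma_variate(params, t)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else None
    rmse = math.sqrt(sse / y.size)
    return FitResult(
        params=params,
        indices=indices,
        sse=sse,
        r_squared=r2,
        rmse=rmse,
        converged=bool(res.status > 0),
        n_iter=int(res.nfev),
    )


def goodness_of_fit(fit: FitResult, tic: TimeIntensityCurve) -> dict:
    """Recompute r_squared and rmse of a fit against a TIC.

    r_squared = 1 - sse / total-sum-of-squares about the TIC mean. On a
    zero-variance TIC r_squared is undefined and an UndefinedRSquaredError
    is raised (the caller should report rmse only).
    """
    y = tic.intensities
    pred = eval_gamma_variate(fit.params, tic.times)
    sse = float(np.sum((y - pred) ** 2))
    rmse = math.sqrt(sse / y.size)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedRSquaredError(f"zero-variance TIC; rmse = {rmse}")
    return {"r_squared": 1.0 - sse / sst, "rmse": rmse}
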