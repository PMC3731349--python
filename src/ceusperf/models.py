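"""Domain types for CEUS perfusion quantification.

The central objects are the time-intensity curve (TIC) sampled from a
region of interest in a contrast-enhanced ultrasound cine loop, the
gamma-variate kinetic parameters fitted to it, and the perfusion indices
derived from those parameters in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Tuple

import numpy as np

UnitsFlag = Literal["dB", "linear"]


# ---------------------------------------------------------------------------
# Errors

class CeusError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CeusError, ValueError):
    """A kinetic parameter violates its invariant (non-finite, wrong sign)."""


class InsufficientDataError(CeusError, ValueError):
    """Too few usable samples for the requested operation."""


class InitializationFailure(CeusError, RuntimeError):
    """Log-linear initialization found no decaying wash-out (slope >= 0)."""


class TruncatedBolusError(CeusError, ValueError):
    """The TIC has no interior peak; the bolus passage is cut off."""


class OutOfBoundsError(CeusError, ValueError):
    """An ROI extends beyond the image."""


class InsufficientBaselineError(CeusError, ValueError):
    """Fewer than 3 samples fall in the requested baseline window."""


class NoBolusDetectedError(CeusError, ValueError):
    """No sustained threshold crossing above baseline was found."""


class SceneDefinitionError(CeusError, ValueError):
    """Synthetic cine scene regions overlap or fall outside the frame."""


class DegenerateDesignError(CeusError, ValueError):
    """The panel cannot identify the model (e.g. a single subject)."""


class UndefinedRSquaredError(CeusError, ValueError):
    """R-squared is undefined because the TIC has zero variance."""


# ---------------------------------------------------------------------------
# Kinetic model state

@dataclass(frozen=True)
class GammaVariateParams:
    """Parameters of the lagged gamma-variate bolus model.

    I(t) = A * (t - t0) * exp(-alpha * (t - t0)) + C   for t >= t0,
    I(t) = C                                           for t <  t0.

    Attributes
    ----------
    A : float
        Upslope scaling factor, intensity-units per second. Proportional
        to the initial wash-in rate of the bolus.
    alpha : float
        Rate constant (1/s); the reciprocal of the curve width. Governs
        the wash-out decay.
    t0 : float
        Bolus arrival lag in seconds, measured from the start of the
        acquisition.
    C : float
        Baseline intensity asymptote, intensity-units.
    """

    A: float
    alpha: float
    t0: float = 0.0
    C: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.A, self.alpha, self.t0, self.C)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite parameter in {vals}")
        if self.A < 0:
            raise InvalidParameterError(f"A must be >= 0, got {self.A}")
        if self.alpha <= 0:
            raise InvalidParameterError(f"alpha must be > 0, got {self.alpha}")
        if self.t0 < 0:
            raise InvalidParameterError(f"t0 must be >= 0, got {self.t0}")


@dataclass(frozen=True)
class PerfusionIndices:
    """The five quantitative perfusion indices of a fitted TIC.

    AUC = A / alpha**2  (area under the baseline-subtracted curve),
    DPI = A / (alpha * e)  (derived peak intensity above baseline),
    TTP = 1 / alpha  (time from bolus arrival to the curve maximum).
    """

    A: float
    alpha: float
    AUC: float
    DPI: float
    TTP: float

    def as_dict(self) -> dict:
        return {
            "A": self.A,
            "alpha": self.alpha,
            "AUC": self.AUC,
            "DPI": self.DPI,
            "TTP": self.TTP,
        }


INDEX_NAMES: Tuple[str, ...] = ("A", "alpha", "AUC", "DPI", "TTP")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a nonlinear least-squares gamma-variate fit."""

    params: GammaVariateParams
    indices: PerfusionIndices
    sse: float
    r_squared: Optional[float]
    rmse: float
    converged: bool
    n_iter: int


# ---------------------------------------------------------------------------
# Signal containers

@dataclass(frozen=True)
class TimeIntensityCurve:
    """A sampled (time, intensity) series from one ROI.

    times are seconds from acquisition start, strictly increasing;
    intensities are in the units indicated by ``units_flag`` (video dB by
    default, matching commercial TIC tools).
    """

    times: np.ndarray
    intensities: np.ndarray
    units_flag: UnitsFlag = "dB"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.shape != y.shape:
            raise ValueError("times and intensities must be 1-D and equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)

    @property
    def n_samples(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class CineLoop:
    """A timed frame stack: T frames of H x W pixels plus geometry.

    pixel_spacing is (row, col) millimetres per pixel.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    pixel_spacing: Tuple[float, float]
    units_flag: UnitsFlag = "dB"

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        t = np.asarray(self.frame_times, dtype=float)
        if f.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if t.ndim != 1 or t.size != f.shape[0]:
            raise ValueError("frame_times must match the number of frames")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if not (self.pixel_spacing[0] > 0 and self.pixel_spacing[1] > 0):
            raise ValueError("pixel_spacing must be positive")
        object.__setattr__(self, "frames", f)
        object.__setattr__(self, "frame_times", t)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ROISpec:
    """A square/rectangular ROI given by pixel centre and physical size.

    Default size is the 5 mm x 5 mm square used on the peripheral renal
    cortex.
    """

    center: Tuple[int, int]
    size_mm: Tuple[float, float] = (5.0, 5.0)
    shape: Literal["square"] = "square"

    def __post_init__(self) -> None:
        if self.size_mm[0] <= 0 or self.size_mm[1] <= 0:
            raise ValueError("size_mm must be positive")


# ---------------------------------------------------------------------------
# Synthetic-data configuration

@dataclass(frozen=True)
class NoiseModel:
    """Speckle-like noise layer applied on the linear power scale.

    ``multiplicative-linear`` multiplies each sample's linear power by an
    independent mean-1 gamma factor with standard deviation ``cv`` (a
    Rayleigh-like speckle surrogate), then re-compresses to dB when the
    acquisition is log-compressed.
    """

    kind: Literal["none", "multiplicative-linear"] = "none"
    cv: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.kind not in ("none", "multiplicative-linear"):
            raise ValueError(f"unknown noise kind {self.kind!r}")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Cine acquisition envelope: 160 s capture at 10 Hz by default."""

    duration: float = 160.0
    frame_rate: float = 10.0
    units_flag: UnitsFlag = "dB"

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be positive")

    def frame_times(self) -> np.ndarray:
        n = int(round(self.duration * self.frame_rate))
        return np.arange(n) / self.frame_rate


# Healthy baseline kinetics inverted from the cohort's pre-operative means:
# TTP = 9.03 s  => alpha = 1/9.03 ~ 0.1107 1/s
# DPI = 13.04 dB => A = DPI * alpha * e ~ 3.93 dB/s
BASELINE_TTP_S = 9.03
BASELINE_DPI_DB = 13.04
BASELINE_ALPHA = 1.0 / BASELINE_TTP_S
BASELINE_A = BASELINE_DPI_DB * BASELINE_ALPHA * math.e


@dataclass(frozen=True)
class CohortConfig:
    """Longitudinal cohort generator settings.

    Five subjects observed weekly from week 0 with staggered dropout
    (last observed weeks 6, 6, 12, 13, 16), kinetic truth drifting
    multiplicatively per week: A_iw = A0 * b_i^A * drift_A^w * e_iw^A and
    likewise for alpha. Random effects and replicate noise are log-normal
    (positivity).
    """

    n_subjects: int = 5
    weeks: Tuple[int, ...] = tuple(range(17))
    dropout_weeks: Tuple[int, ...] = (6, 6, 12, 13, 16)
    baseline_A: float = BASELINE_A
    baseline_alpha: float = BASELINE_ALPHA
    drift_A: float = 0.97
    drift_alpha: float = 0.93
    between_subject_sd: float = 0.15
    within_subject_sd: float = 0.05
    # Correlation of the replicate log-noise on (A, alpha). Both indices
    # come from fitting the same noisy TIC, so their errors are strongly
    # positively correlated (~0.9 measured on Monte-Carlo TIC fits).
    replicate_corr: float = 0.9
    baseline_t0: float = 5.0
    baseline_C: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if len(self.dropout_weeks) != self.n_subjects:
            raise ValueError("dropout_weeks must have one entry per subject")
        wk = set(self.weeks)
        if not set(self.dropout_weeks) <= wk:
            raise ValueError("dropout_weeks must be a subset of weeks")
        if self.between_subject_sd < 0 or self.within_subject_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not -1.0 <= self.replicate_corr <= 1.0:
            raise ValueError("replicate_corr must be in [-1, 1]")
        if self.drift_A <= 0 or self.drift_alpha <= 0:
            raise ValueError("drifts must be positive multiplicative factors")
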