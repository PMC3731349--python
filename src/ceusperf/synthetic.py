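"""Synthetic TICs, cine loops, and longitudinal cohorts.

Emulates the data the perfusion analysis assumes: a bolus-injection TIC
(lagged gamma-variate wash-in/wash-out over a baseline), speckle-like
multiplicative noise on the linear power scale re-compressed to dB, a
two-region kidney scene in which the cortex enhances before the medulla,
and a small weekly cohort with staggered dropout whose kinetic truth
drifts multiplicatively as ischemia progresses.

The cohort defaults reflect the study conditions the analysis targets:
5 subjects, weeks 0..16, last observed weeks (6, 6, 12, 13, 16), healthy
baseline kinetics inverted from pre-operative index means (TTP 9.03 s,
DPI 13.04 dB), A drifting down 3%/week and alpha down 7%/week so that
AUC, DPI and TTP rise while A falls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .gamma_fit import derive_indices, eval_gamma_variate
from .models import (
    AcquisitionSpec,
    CineLoop,
    CohortConfig,
    GammaVariateParams,
    NoiseModel,
    SceneDefinitionError,
    TimeIntensityCurve,
)

__all__ = [
    "simulate_tic",
    "simulate_cine",
    "simulate_cohort",
    "cohort_to_long",
    "SceneRegion",
    "CineScene",
]


def _apply_linear_noise(
    intensities: np.ndarray, units_flag: str, cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiply linear power by i.i.d. mean-1 gamma factors with sd cv.

    dB series are decompressed to power, perturbed, re-compressed; linear
    series are perturbed in place. Gamma(shape=1/cv^2, scale=cv^2) has
    mean 1 and sd cv and is strictly positive, so log-compression stays
    defined — a standard speckle surrogate.
    """
    if cv == 0:
        return intensities.copy()
    shape = 1.0 / cv**2
    factors = rng.gamma(shape, cv**2, size=intensities.shape)
    if units_flag == "dB":
        power = 10.0 ** (intensities / 10.0)
        return 10.0 * np.log10(power * factors)
    return intensities * factors


def simulate_tic(
    params: GammaVariateParams,
    acq: AcquisitionSpec | None = None,
    noise: NoiseModel | None = None,
) -> TimeIntensityCurve:
    """Sample a gamma-variate TIC on the acquisition's frame grid.

    With noise.kind='none' the result is bit-identical to
    eval_gamma_variate at the frame times; with 'multiplicative-linear'
    each sample's linear power is scaled by an independent mean-1 factor
    (sd = cv). Reproducible given noise.seed.
    """
    acq = acq or AcquisitionSpec()
    noise = noise or NoiseModel()
    times = acq.frame_times()
    clean = eval_gamma_variate(params, times)
    if noise.kind == "none":
        y = clean
    else:
        rng = np.random.default_rng(noise.seed)
        y = _apply_linear_noise(clean, acq.units_flag, noise.cv, rng)
    return TimeIntensityCurve(times=times, intensities=y, units_flag=acq.units_flag)


@dataclass(frozen=True)
class SceneRegion:
    """A pixel mask plus the kinetics every pixel in it follows."""

    mask: np.ndarray  # boolean (H, W)
    params: GammaVariateParams


@dataclass(frozen=True)
class CineScene:
    """Background level plus kinetic regions (e.g. cortex band, medulla).

    Regions must be disjoint and inside the frame; pixels outside every
    region stay at the constant background intensity.
    """

    height: int
    width: int
    background: float
    regions: Dict[str, SceneRegion]

    def __post_init__(self) -> None:
        occupancy = np.zeros((self.height, self.width), dtype=int)
        for name, region in self.regions.items():
            m = np.asarray(region.mask, dtype=bool)
            if m.shape != (self.height, self.width):
                raise SceneDefinitionError(
                    f"region {name!r} mask shape {m.shape} != frame "
                    f"({self.height}, {self.width})"
                )
            occupancy += m
        if np.any(occupancy > 1):
            raise SceneDefinitionError("region masks overlap")


def simulate_cine(
    scene: CineScene,
    acq: AcquisitionSpec | None = None,
    noise: NoiseModel | None = None,
    pixel_spacing: Tuple[float, float] = (0.5, 0.5),
) -> CineLoop:
    """Render a cine loop in which each region follows its own kinetics.

    Per-pixel noise (independent across pixels and frames) is applied on
    the linear power scale. With no noise, an ROI averaged inside one
    region reproduces that region's kinetics exactly.
    """
    acq = acq or AcquisitionSpec()
    noise = noise or NoiseModel()
    times = acq.frame_times()
    T = times.size
    frames = np.full((T, scene.height, scene.width), scene.background, dtype=float)
    for region in scene.regions.values():
        series = eval_gamma_variate(region.params, times)
        frames[:, np.asarray(region.mask, dtype=bool)] = series[:, None]
    if noise.kind != "none" and noise.cv > 0:
        rng = np.random.default_rng(noise.seed)
        frames = _apply_linear_noise(frames, acq.units_flag, noise.cv, rng)
    return CineLoop(
        frames=frames,
        frame_times=times,
        pixel_spacing=pixel_spacing,
        units_flag=acq.units_flag,
    )


def simulate_cohort(cfg: CohortConfig | None = None) -> pd.DataFrame:
    """Generate a subject x week panel of perfusion indices.

    For subject i at week w the kinetic truth is

        A_iw     = baseline_A     * b_i^A  * drift_A^w     * e_iw^A
        alpha_iw = baseline_alpha * b_i^a  * drift_alpha^w * e_iw^a

    with log-normal subject effects b_i (sd = between_subject_sd on the
    log scale) and log-normal replicate noise e_iw (sd =
    within_subject_sd, correlation replicate_corr between the A and alpha
    components — both indices come from fitting the same noisy TIC, so
    their errors move together). Indices come from the closed forms; rows
    after a subject's dropout week are absent. Columns:
    subject, week, A, alpha, AUC, DPI, TTP.
    """
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    rho = cfg.replicate_corr
    rho_c = float(np.sqrt(max(1.0 - rho**2, 0.0)))
    rows = []
    for i in range(cfg.n_subjects):
        b_A = float(np.exp(rng.normal(0.0, cfg.between_subject_sd)))
        b_al = float(np.exp(rng.normal(0.0, cfg.between_subject_sd)))
        last = cfg.dropout_weeks[i]
        for w in cfg.weeks:
            if w > last:
                # draw anyway to keep the stream aligned across configs
                rng.normal(0.0, 1.0, size=2)
                continue
            z1, z2 = rng.normal(0.0, 1.0, size=2)
            e_A = float(np.exp(cfg.within_subject_sd * z1))
            e_al = float(np.exp(cfg.within_subject_sd * (rho * z1 + rho_c * z2)))
            A_iw = cfg.baseline_A * b_A * cfg.drift_A**w * e_A
            al_iw = cfg.baseline_alpha * b_al * cfg.drift_alpha**w * e_al
            idx = derive_indices(GammaVariateParams(A=A_iw, alpha=al_iw))
            rows.append(
                {
                    "subject": f"S{i + 1}",
                    "week": int(w),
                    **idx.as_dict(),
                }
            )
    return pd.DataFrame(rows, columns=["subject", "week", "A", "alpha", "AUC", "DPI", "TTP"])


def cohort_to_long(panel: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide cohort panel into (subject, week, index, value) rows."""
    return panel.melt(
        id_vars=["subject", "week"], var_name="index", value_name="value"
    ).sort_values(["index", "subject", "week"], ignore_index=True)
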