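"""ROI-based time-intensity curve extraction from cine loops.

A square ROI specified in millimetres is converted to a pixel block via
the cine's pixel spacing; the TIC is the per-frame arithmetic mean over
that block, computed in the cine's native units (dB averaging, mirroring
commercial TIC tools). Baseline level and bolus arrival time are
estimated from the pre-arrival plateau.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .models import (
    CineLoop,
    InsufficientBaselineError,
    NoBolusDetectedError,
    OutOfBoundsError,
    ROISpec,
    TimeIntensityCurve,
)

__all__ = [
    "roi_to_pixels",
    "extract_tic",
    "estimate_baseline",
    "detect_arrival_time",
]


def roi_to_pixels(
    roi: ROISpec, spacing: Tuple[float, float], dims: Tuple[int, int]
) -> Tuple[slice, slice]:
    """Convert a physical ROI to pixel slices (rows, cols).

    The extent per side is round(size_mm / spacing), floored at 1 pixel,
    centred on roi.center with even extents biased toward the top-left.
    """
    H, W = dims
    extents = []
    for size, sp in zip(roi.size_mm, spacing):
        n = max(1, int(round(size / sp)))
        extents.append(n)
    slices = []
    for c, n, dim in zip(roi.center, extents, (H, W)):
        start = c - n // 2
        # even extent: n//2 before centre, n - n//2 after => top-left bias
        if n % 2 == 0:
            start = c - n // 2
        stop = start + n
        if start < 0 or stop > dim:
            raise OutOfBoundsError(
                f"ROI rows/cols [{start}, {stop}) exceed image dimension {dim}"
            )
        slices.append(slice(start, stop))
    return slices[0], slices[1]


def extract_tic(cine: CineLoop, roi: ROISpec) -> TimeIntensityCurve:
    """Average each frame over the ROI pixel block, in native units."""
    rows, cols = roi_to_pixels(roi, cine.pixel_spacing, cine.frames.shape[1:])
    series = cine.frames[:, rows, cols].mean(axis=(1, 2))
    return TimeIntensityCurve(
        times=cine.frame_times.copy(),
        intensities=series,
        units_flag=cine.units_flag,
    )


def estimate_baseline(tic: TimeIntensityCurve, window: float) -> dict:
    """Mean and sample SD of the pre-arrival samples (t < window)."""
    mask = tic.times < window
    n = int(mask.sum())
    if n < 3:
        raise InsufficientBaselineError(
            f"baseline window {window} s covers {n} samples; need >= 3"
        )
    vals = tic.intensities[mask]
    return {"C0": float(vals.mean()), "sigma0": float(vals.std(ddof=1))}


def detect_arrival_time(
    tic: TimeIntensityCurve, C0: float, sigma0: float, k: float = 3.0
) -> float:
    """Time of the first sustained crossing above C0 + k*sigma0.

    A crossing counts only if followed by at least 2 consecutive samples
    also above threshold, so isolated noise spikes do not trigger. With
    sigma0 = 0 the threshold is C0 plus a machine-epsilon-scaled offset.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    if sigma0 > 0:
        thresh = C0 + k * sigma0
    else:
        thresh = C0 + 8 * np.finfo(float).eps * max(1.0, abs(C0))
    above = tic.intensities > thresh
    for i in range(above.size - 2):
        if above[i] and above[i + 1] and above[i + 2]:
            return float(tic.times[i])
    raise NoBolusDetectedError(
        f"no sustained crossing above {thresh:.6g} found in {tic.n_samples} samples"
    )
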