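"""Optional plotting: TIC with fitted gamma-variate overlay."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .gamma_fit import eval_gamma_variate
from .models import GammaVariateParams, TimeIntensityCurve


def plot_tic_fit(
    tic: TimeIntensityCurve, report: dict, path: Union[str, Path]
) -> None:
    """Scatter the TIC samples and overlay the fitted curve."""
    params = GammaVariateParams(
        A=report["A"], alpha=report["alpha"], t0=report["t0"], C=report["C"]
    )
    grid = np.linspace(tic.times[0], tic.times[-1], 1000)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(tic.times, tic.intensities, ".", ms=2, alpha=0.5, label="TIC samples")
    ax.plot(grid, eval_gamma_variate(params, grid), "-", lw=2, label="gamma-variate fit")
    peak_t = params.t0 + report["TTP"]
    ax.axvline(peak_t, ls=":", color="gray")
    ax.annotate(f"TTP = {report['TTP']:.2f} s", (peak_t, ax.get_ylim()[1] * 0.95))
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"intensity ({tic.units_flag})")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
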