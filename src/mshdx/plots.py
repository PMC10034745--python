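"""Uptake-plot helpers (log-time axis, intrinsic-curve overlay)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .intrinsic import ResidueRates, intrinsic_uptake_curve
from .kinetics import StretchedExpModel
from .series import UptakeSeries


def plot_uptake(
    series: UptakeSeries,
    fit: StretchedExpModel | None = None,
    intrinsic: ResidueRates | None = None,
    title: str | None = None,
    path=None,
):
    """Uptake vs log labeling time with optional fit and intrinsic overlay.

    Returns the matplotlib figure; saves to ``path`` (SVG/PNG by extension)
    when given.
    """
    fig, ax = plt.subplots(figsize=(5, 3.4))
    t_grid = np.geomspace(series.exposures[0] / 2, series.exposures[-1] * 1.5, 200)
    mean = series.means()
    sd = series.sds()
    ax.errorbar(
        series.exposures, mean, yerr=np.where(np.isnan(sd), 0.0, sd),
        fmt="o", ms=4, capsize=2, color="#1f4e79", label="observed",
    )
    if fit is not None and fit.success:
        ax.plot(t_grid, fit.predict(t_grid), "--", color="#c03030",
                label=f"{fit.n_phases}-phase fit")
    if intrinsic is not None:
        ax.plot(
            t_grid,
            intrinsic_uptake_curve(intrinsic, t_grid),
            ":", color="black", label="intrinsic (unprotected)",
        )
    ax.set_xscale("log")
    ax.set_xlabel("labeling time (s)")
    ax.set_ylabel(f"deuterium uptake ({series.units})")
    if title:
        ax.set_title(title, fontsize=10)
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
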