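"""Back-exchange estimation and correction.

Deuterium is partially lost to protonated solvent during quench, digestion
and chromatography.  A maximally deuterated (maxD) reference sample of the
same peptide calibrates this loss: the ratio of its measured uptake to the
theoretical maximum (f_D2O * Q) is the peptide-specific retention fraction.
Retention is treated as a single time-invariant scalar per peptide -- on
this instrument back-exchange shows no dependence on mixing time (linear
regression of retention vs time is reported as a diagnostic so users can
verify this on their own data).  Observed uptake is corrected by division:

    corrected = observed / retention
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .series import UptakeSeries


@dataclass(frozen=True)
class BackExchangeModel:
    """Per-peptide back-exchange calibration.

    ``retention`` is the mean maxD uptake divided by the theoretical maximum
    (values > 1 are kept and flagged unless ``clip`` was requested at
    estimation time).  The regression fields quantify any dependence of
    retention on mixing time (slope in retention-fraction per second).
    """

    retention: float
    per_exposure_retention: np.ndarray
    exposures: np.ndarray
    slope_per_s: float
    intercept: float
    r_squared: float
    p_value: float
    flagged: bool = False

    @property
    def backexchange_percent(self) -> float:
        """Deuterium lost, as a percentage of the theoretical maximum."""
        return 100.0 * (1.0 - self.retention)


def estimate_backexchange(
    maxD: UptakeSeries, theoretical_max: float, clip: bool = False
) -> BackExchangeModel:
    """Estimate the retention fraction from a maxD reference series.

    ``theoretical_max`` is f_D2O * Q in Da (from the intrinsic-rates stage).
    Also reports the linear regression of per-exposure retention against
    mixing time as a time-invariance diagnostic; a perfectly flat series
    yields slope 0 and (by convention) R^2 = 0.
    """
    if not maxD.is_maxD_reference:
        raise ValueError("series is not flagged as a maxD reference")
    if theoretical_max <= 0:
        raise ValueError("theoretical_max must be positive")
    if maxD.exposures.size == 0:
        raise ValueError("empty maxD series")

    t, u = maxD.flat()
    retention = float(np.mean(u) / theoretical_max)
    per_exposure = maxD.means() / theoretical_max
    flagged = retention > 1.0
    if flagged:
        if clip:
            retention = 1.0
        else:
            warnings.warn(
                f"maxD retention {retention:.3f} exceeds 1; "
                "not clipped (pass clip=True to clip)",
                stacklevel=2,
            )

    r = u / theoretical_max
    if np.unique(t).size < 2 or np.allclose(r, r[0]):
        slope, intercept, r2, p = 0.0, float(np.mean(r)), 0.0, 1.0
    else:
        res = stats.linregress(t, r)
        slope, intercept = float(res.slope), float(res.intercept)
        r2, p = float(res.rvalue**2), float(res.pvalue)
    return BackExchangeModel(
        retention=retention,
        per_exposure_retention=per_exposure,
        exposures=maxD.exposures.copy(),
        slope_per_s=slope,
        intercept=intercept,
        r_squared=r2,
        p_value=p,
        flagged=flagged,
    )


def correct_uptake(
    observed: UptakeSeries,
    model: BackExchangeModel,
    theoretical_max: float | None = None,
) -> UptakeSeries:
    """Divide observed uptake by the retention fraction (absolute Da scale).

    If ``theoretical_max`` is given, corrected values exceeding it by more
    than 5% trigger a warning (kept, not clipped, to preserve the noise
    structure for downstream fitting).
    """
    if model.retention <= 0:
        raise ValueError("retention must be positive")
    if observed.units != "Da":
        raise ValueError("correct_uptake expects observed uptake in Da")
    corrected = observed.uptake / model.retention
    if theoretical_max is not None:
        with np.errstate(invalid="ignore"):
            n_over = int(np.sum(corrected[~np.isnan(corrected)] > 1.05 * theoretical_max))
        if n_over:
            warnings.warn(
                f"{n_over} corrected value(s) exceed the theoretical maximum "
                f"by > 5% (retention={model.retention:.3f})",
                stacklevel=2,
            )
    return observed.with_uptake(corrected, state=observed.state)


def normalize_percent(absolute: UptakeSeries, theoretical_max: float) -> UptakeSeries:
    """Normalize absolute uptake (Da) to percent of the theoretical maximum.

    ``theoretical_max`` already includes the D2O-fraction factor, so a fully
    exchanged peptide reads 100%.
    """
    if theoretical_max <= 0:
        raise ValueError("theoretical_max must be positive")
    if absolute.units != "Da":
        raise ValueError("normalize_percent expects absolute uptake in Da")
    return absolute.with_uptake(
        100.0 * absolute.uptake / theoretical_max, units="percent"
    )
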