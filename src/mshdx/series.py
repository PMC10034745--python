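"""Replicated deuterium-uptake time series."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .peptides import PeptideSpec


@dataclass(frozen=True)
class UptakeSeries:
    """Deuterium uptake vs labeling time for one peptide.

    ``uptake`` is a 2-D array of shape (n_exposures, max_replicates); ragged
    replicate structure is padded with NaN.  ``units`` is ``"Da"`` (absolute
    mass shift) or ``"percent"`` (of the theoretical maximum).
    ``is_maxD_reference`` marks a maximally deuterated control series used
    for back-exchange estimation.
    """

    peptide: PeptideSpec
    exposures: np.ndarray
    uptake: np.ndarray
    units: str = "Da"
    is_maxD_reference: bool = False
    state: str = "labeled"
    protein: str = "peptide"

    def __post_init__(self) -> None:
        exposures = np.asarray(self.exposures, dtype=float)
        uptake = np.atleast_2d(np.asarray(self.uptake, dtype=float))
        object.__setattr__(self, "exposures", exposures)
        object.__setattr__(self, "uptake", uptake)
        if exposures.ndim != 1 or uptake.shape[0] != exposures.size:
            raise ValueError("uptake rows must match number of exposures")
        if np.any(exposures <= 0):
            raise ValueError("exposures must be strictly positive (seconds)")
        if np.any(np.diff(exposures) <= 0):
            raise ValueError("exposures must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(uptake[~np.isnan(uptake)] < 0):
                raise ValueError("uptake values must be >= 0")
        if np.any(np.all(np.isnan(uptake), axis=1)):
            raise ValueError("every exposure needs at least one replicate")
        if self.units not in ("Da", "percent"):
            raise ValueError(f"unknown units {self.units!r}")

    # -- summaries ---------------------------------------------------------

    def means(self) -> np.ndarray:
        return np.nanmean(self.uptake, axis=1)

    def sds(self) -> np.ndarray:
        return np.nanstd(self.uptake, axis=1, ddof=1)

    def n_replicates(self) -> np.ndarray:
        return np.sum(~np.isnan(self.uptake), axis=1)

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """All (time, uptake) points in long form, NaN padding dropped."""
        t = np.repeat(self.exposures, self.uptake.shape[1])
        u = self.uptake.ravel()
        ok = ~np.isnan(u)
        return t[ok], u[ok]

    def with_uptake(self, uptake: np.ndarray, **changes) -> "UptakeSeries":
        return replace(self, uptake=uptake, **changes)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table (one row per replicate measurement)."""
        rows = []
        for i, exp in enumerate(self.exposures):
            for j, val in enumerate(self.uptake[i]):
                if np.isnan(val):
                    continue
                rows.append(
                    {
                        "Protein": self.protein,
                        "Sequence": self.peptide.sequence,
                        "Start": self.peptide.start_residue,
                        "End": self.peptide.end_residue,
                        "State": self.state,
                        "Exposure": exp,
                        "Replicate": j + 1,
                        "Uptake": val,
                        "Units": self.units,
                    }
                )
        return pd.DataFrame(rows)
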