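"""Sequence-dependent intrinsic amide exchange rates.

Computes the chemical (random-coil) exchange rate constant of each backbone
amide from the poly-DL-alanine reference rates and nearest-neighbour
side-chain factors of Bai, Milne, Mayne & Englander (1993), and from them
the theoretical maximum-exchange uptake curve

    D_int(t) = f_D2O * sum_i (1 - exp(-k_int,i * t))

summed over the included residues (third residue onward, prolines excluded).

The catalysis model is the standard three-term form

    k_int = k_A [D+] 10^(lamA+rhoA)  +  k_B [OD-] 10^(lamB+rhoB)
            +  k_W 10^(lamB+rhoB)

with glass-electrode correction pD = pD_read + 0.4, [OD-] from the
temperature-corrected D2O autoionization constant, and Arrhenius
temperature factors on each catalytic term.  Parameter tables ship as
versioned package data (``mshdx/data``) and may be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .peptides import LabelingConditions, PeptideSpec

R_KCAL = 1.987204e-3  # gas constant, kcal/(mol K)

PD_MIN, PD_MAX = 1.0, 13.0
T_MIN, T_MAX = 258.0, 323.0

# residues whose factors depend on protonation state: (protonated row,
# deprotonated row, name of the pK constant in the reference table)
_IONIZABLE = {
    "D": ("D0", "D-", "pK_asp"),
    "E": ("E0", "E-", "pK_glu"),
    "H": ("H+", "H0", "pK_his"),
}


class RateTable:
    """Parameter tables for intrinsic-rate calculation.

    Wraps the side-chain factor table (log10 lambda/rho values for acid and
    base catalysis) and the scalar reference constants.  ``version`` is read
    from the table comment header.
    """

    def __init__(self, factors: pd.DataFrame, constants: dict[str, float], version: str):
        self.factors = factors.set_index("code") if "code" in factors.columns else factors
        self.constants = constants
        self.version = version

    @classmethod
    def from_csv(cls, factors_path, constants_path) -> "RateTable":
        factors = pd.read_csv(factors_path, comment="#")
        const_df = pd.read_csv(constants_path, comment="#")
        constants = dict(zip(const_df["name"], const_df["value"].astype(float)))
        version = "unversioned"
        with open(factors_path) as fh:
            for line in fh:
                if "Table version:" in line:
                    version = line.split("Table version:")[1].strip()
                    break
        return cls(factors, constants, version)

    # -- catalysis factor lookup ------------------------------------------

    def _blend(self, row_prot: str, row_deprot: str, col: str, pD: float, pK: float) -> float:
        """Population-weighted factor of an ionizable group (log10 scale)."""
        fp = self.factors.at[row_prot, col]
        fd = self.factors.at[row_deprot, col]
        num = 10.0 ** fp * 10.0 ** (-pD) + 10.0 ** fd * 10.0 ** (-pK)
        den = 10.0 ** (-pD) + 10.0 ** (-pK)
        return math.log10(num / den)

    def factor(self, aa: str, col: str, pD: float) -> float:
        """log10 side-chain factor of residue ``aa`` for column ``col``
        (one of lambda_acid, rho_acid, lambda_base, rho_base) at pD."""
        if aa in _IONIZABLE:
            prot, deprot, pk_name = _IONIZABLE[aa]
            return self._blend(prot, deprot, col, pD, self.constants[pk_name])
        return float(self.factors.at[aa, col])

    def cterm_factor(self, col: str, pD: float) -> float:
        return self._blend("CT0", "CT-", col, pD, self.constants["pK_cterm"])

    def nterm_factor(self, col: str) -> float:
        return float(self.factors.at["NT", col])

    # -- solvent / temperature terms --------------------------------------

    def pKD(self, temperature: float) -> float:
        """D2O autoionization pK at ``temperature`` (van't Hoff)."""
        c = self.constants
        return c["pKD_ref"] + (c["dH_ion_kcal"] / (math.log(10.0) * R_KCAL)) * (
            1.0 / temperature - 1.0 / c["T_ref_K"]
        )

    def arrhenius(self, which: str, temperature: float) -> float:
        """Temperature factor on the reference rate (1.0 at T_ref)."""
        ea = self.constants[f"Ea_{which}_kcal"]
        t_ref = self.constants["T_ref_K"]
        return math.exp(-(ea / R_KCAL) * (1.0 / temperature - 1.0 / t_ref))


@lru_cache(maxsize=4)
def _default_table_cached() -> RateTable:
    data = resources.files("mshdx") / "data"
    return RateTable.from_csv(
        Path(str(data / "sidechain_factors.csv")),
        Path(str(data / "reference_rates.csv")),
    )


def default_table() -> RateTable:
    """The packaged Bai-1993 D2O parameter table."""
    return _default_table_cached()


@dataclass(frozen=True)
class ResidueRates:
    """Per-residue intrinsic exchange rate constants for one peptide.

    ``rates`` holds one value per residue (s^-1), in peptide order; excluded
    positions (N-terminal pair, prolines) carry exactly 0 so they drop out
    of uptake sums.  ``excluded`` maps 1-based local position -> reason.
    """

    peptide: PeptideSpec
    conditions: LabelingConditions
    rates: np.ndarray
    excluded: dict[int, str]
    table_version: str = "bai1993-d2o-v1"

    @property
    def included_rates(self) -> np.ndarray:
        return self.rates[self.rates > 0.0]

    def by_residue_number(self) -> dict[int, float]:
        """Rates keyed by parent-protein residue number."""
        start = self.peptide.start_residue
        return {start + i: float(k) for i, k in enumerate(self.rates)}


def residue_intrinsic_rates(
    peptide: PeptideSpec,
    cond: LabelingConditions,
    table: RateTable | None = None,
) -> ResidueRates:
    """Intrinsic (random-coil) exchange rate of every amide in ``peptide``.

    The first two residues and prolines are excluded (rate exactly 0).  The
    acid/base/water catalytic terms are corrected for the working pD, the
    labeling temperature and the flanking side chains; the C-terminal
    residue additionally carries the carboxyl(ate) factor.

    Raises
    ------
    ValueError
        For non-canonical residues (via ``PeptideSpec``) or conditions
        outside the validity range of the parameter tables
        (corrected pD 1-13, temperature 258-323 K).
    """
    table = table or default_table()
    pD = cond.pD
    if not PD_MIN <= pD <= PD_MAX:
        raise ValueError(f"corrected pD {pD:.2f} outside table range [{PD_MIN}, {PD_MAX}]")
    if not T_MIN <= cond.temperature <= T_MAX:
        raise ValueError(
            f"temperature {cond.temperature} K outside table range [{T_MIN}, {T_MAX}]"
        )

    t = cond.temperature
    c = table.constants
    d_conc = 10.0 ** (-pD)
    od_conc = 10.0 ** (pD - table.pKD(t))
    ka = 10.0 ** c["log10_ka_ref"] * table.arrhenius("acid", t)
    kb = 10.0 ** c["log10_kb_ref"] * table.arrhenius("base", t)
    kw = 10.0 ** c["log10_kw_ref"] * table.arrhenius("water", t)

    seq = peptide.sequence
    n = len(seq)
    rates = np.zeros(n)
    excluded: dict[int, str] = {}
    for pos in range(1, n + 1):
        reason = peptide.exclusion_reason(pos)
        if reason is not None:
            excluded[pos] = reason
            continue
        aa = seq[pos - 1]
        left = seq[pos - 2]  # pos >= 3 always holds here
        log_fa = table.factor(aa, "lambda_acid", pD) + table.factor(left, "rho_acid", pD)
        log_fb = table.factor(aa, "lambda_base", pD) + table.factor(left, "rho_base", pD)
        if pos == n:
            log_fa += table.cterm_factor("lambda_acid", pD)
            log_fb += table.cterm_factor("lambda_base", pD)
        k_min = (
            ka * d_conc * 10.0 ** log_fa
            + kb * od_conc * 10.0 ** log_fb
            + kw * 10.0 ** log_fb
        )
        rates[pos - 1] = k_min / 60.0  # min^-1 -> s^-1
    return ResidueRates(peptide, cond, rates, excluded, table.version)


def intrinsic_uptake_curve(
    rates: ResidueRates,
    times,
    d2o_fraction: float | None = None,
) -> np.ndarray:
    """Theoretical maximum-exchange uptake curve (Da vs labeling time).

    ``D_int(t) = f * sum_i (1 - exp(-k_i t))`` over included residues.
    Monotone non-decreasing, 0 at t=0, asymptote ``f * Q``.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("labeling times must be >= 0")
    if d2o_fraction is None:
        d2o_fraction = rates.conditions.d2o_fraction
    k = rates.rates[rates.rates > 0.0]
    if k.size == 0:
        return np.zeros_like(times)
    return d2o_fraction * np.sum(1.0 - np.exp(-np.outer(times, k)), axis=1)


def theoretical_max_uptake(peptide: PeptideSpec, d2o_fraction: float) -> float:
    """Asymptotic uptake f_D2O * Q used for normalization and back-exchange."""
    return d2o_fraction * peptide.n_exchangeable
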