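"""Intrinsic-rate calculation against independent hand arithmetic.

The reference-rate oracle below recomputes per-residue rate constants
directly from the shipped parameter CSVs with standalone spreadsheet-style
arithmetic (no calls into the module under test) and the values are
compared term by term.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mshdx import (
    LabelingConditions,
    PeptideSpec,
    intrinsic_uptake_curve,
    residue_intrinsic_rates,
    theoretical_max_uptake,
)
from mshdx.intrinsic import default_table
from mshdx.peptides import STANDARD_PEPTIDES

R_KCAL = 1.987204e-3


def _oracle_rates_AAAA(pD: float, T: float) -> list[float]:
    """Hand computation of k_int for AAAA (alanine has all-zero factors,
    so only reference rates, solvent terms and the C-terminal carboxyl
    factor enter).  Returns [k3, k4] in s^-1."""
    data = default_table()  # only used as a path-free handle on the CSVs
    factors = data.factors
    c = data.constants

    pKD = c["pKD_ref"] + c["dH_ion_kcal"] / (math.log(10) * R_KCAL) * (
        1 / T - 1 / c["T_ref_K"]
    )
    d = 10.0**-pD
    od = 10.0 ** (pD - pKD)
    fa = math.exp(-c["Ea_acid_kcal"] / R_KCAL * (1 / T - 1 / c["T_ref_K"]))
    fb = math.exp(-c["Ea_base_kcal"] / R_KCAL * (1 / T - 1 / c["T_ref_K"]))
    fw = math.exp(-c["Ea_water_kcal"] / R_KCAL * (1 / T - 1 / c["T_ref_K"]))
    ka = 10.0 ** c["log10_ka_ref"] * fa
    kb = 10.0 ** c["log10_kb_ref"] * fb
    kw = 10.0 ** c["log10_kw_ref"] * fw

    # residue 3: Ala-Ala context, all side-chain factors are 0
    k3 = (ka * d + kb * od + kw) / 60.0

    # residue 4 carries the C-terminal carboxyl factor (HH-blended)
    def blend(col):
        fp = factors.at["CT0", col]
        fd = factors.at["CT-", col]
        pK = c["pK_cterm"]
        return math.log10(
            (10.0**fp * 10.0**-pD + 10.0**fd * 10.0**-pK)
            / (10.0**-pD + 10.0**-pK)
        )

    k4 = (
        ka * d * 10.0 ** blend("lambda_acid")
        + (kb * od + kw) * 10.0 ** blend("lambda_base")
    ) / 60.0
    return [k3, k4]


class TestRateOracle:
    def test_tetraalanine_matches_hand_computation(self):
        # pD_read 6.6 -> corrected pD 7.0, reference temperature
        cond = LabelingConditions(pD_read=6.6, temperature=293.0)
        rr = residue_intrinsic_rates(PeptideSpec("AAAA"), cond)
        expected = _oracle_rates_AAAA(7.0, 293.0)
        assert rr.rates[0] == 0.0 and rr.rates[1] == 0.0
        assert rr.rates[2] == pytest.approx(expected[0], rel=1e-9)
        assert rr.rates[3] == pytest.approx(expected[1], rel=1e-9)

    def test_arrhenius_direction(self, conditions):
        cold = LabelingConditions(7.06, 283.15, 0.95)
        k_warm = residue_intrinsic_rates(PeptideSpec("AAAA"), conditions).rates[2]
        k_cold = residue_intrinsic_rates(PeptideSpec("AAAA"), cold).rates[2]
        assert k_warm > k_cold

    def test_base_catalysis_dominates_at_neutral_pD(self, conditions):
        """Near pD 7 the hydroxide term should dwarf the acid term; rates
        must rise ~10x per pD unit."""
        lo = LabelingConditions(6.06, 296.15, 0.95)
        k_lo = residue_intrinsic_rates(PeptideSpec("AAAA"), lo).rates[2]
        k_hi = residue_intrinsic_rates(PeptideSpec("AAAA"), conditions).rates[2]
        assert k_hi / k_lo == pytest.approx(10.0, rel=0.05)


class TestExclusions:
    def test_pentaalanine_three_included(self, conditions):
        rr = residue_intrinsic_rates(PeptideSpec("AAAAA"), conditions)
        assert np.sum(rr.rates > 0) == 3
        assert set(rr.excluded) == {1, 2}

    def test_proline_rate_exactly_zero(self, conditions):
        rr = residue_intrinsic_rates(PeptideSpec("AAPA"), conditions)
        assert rr.rates[2] == 0.0
        assert rr.excluded[3] == "proline"
        assert np.sum(rr.rates > 0) == 1

    def test_out_of_range_conditions_rejected(self):
        with pytest.raises(ValueError, match="pD"):
            residue_intrinsic_rates(
                PeptideSpec("AAAA"), LabelingConditions(pD_read=13.0)
            )
        with pytest.raises(ValueError, match="temperature"):
            residue_intrinsic_rates(
                PeptideSpec("AAAA"), LabelingConditions(temperature=330.0)
            )


class TestUptakeCurve:
    def test_zero_time_gives_zero(self, conditions, bradykinin):
        rr = residue_intrinsic_rates(bradykinin, conditions)
        assert intrinsic_uptake_curve(rr, [0.0])[0] == 0.0

    def test_half_life_identity(self, conditions):
        """A single included residue with k = 1/s reaches 0.5 Da at ln 2."""
        rr = residue_intrinsic_rates(PeptideSpec("AAA"), conditions)
        rates = rr.rates.copy()
        rates[2] = 1.0
        rr = rr.__class__(rr.peptide, rr.conditions, rates, rr.excluded)
        val = intrinsic_uptake_curve(rr, [np.log(2)], d2o_fraction=1.0)[0]
        assert val == pytest.approx(0.5, rel=1e-12)

    def test_bradykinin_brute_force_sum(self, conditions, bradykinin, schedule):
        """Curve equals the term-by-term single-residue sum (oracle)."""
        rr = residue_intrinsic_rates(bradykinin, conditions)
        curve = intrinsic_uptake_curve(rr, schedule)
        brute = np.zeros_like(schedule)
        for k in rr.rates:
            if k > 0:
                brute += conditions.d2o_fraction * (1.0 - np.exp(-k * schedule))
        np.testing.assert_allclose(curve, brute, rtol=1e-12)

    def test_negative_time_rejected(self, conditions, bradykinin):
        rr = residue_intrinsic_rates(bradykinin, conditions)
        with pytest.raises(ValueError):
            intrinsic_uptake_curve(rr, [-1.0])

    def test_all_standard_peptides_brute_force(self, conditions, schedule):
        for pep in STANDARD_PEPTIDES.values():
            rr = residue_intrinsic_rates(pep, conditions)
            brute = sum(
                conditions.d2o_fraction * (1.0 - np.exp(-k * schedule))
                for k in rr.rates
                if k > 0
            )
            np.testing.assert_allclose(
                intrinsic_uptake_curve(rr, schedule), brute, rtol=1e-12
            )


@st.composite
def peptides_and_conditions(draw):
    seq = draw(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=20)
    )
    pd_read = draw(st.floats(min_value=2.0, max_value=11.0))
    temp = draw(st.floats(min_value=275.0, max_value=320.0))
    return PeptideSpec(seq), LabelingConditions(pd_read, temp, 0.95)


class TestProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(peptides_and_conditions())
    def test_curve_monotone_and_bounded(self, pc):
        pep, cond = pc
        rr = residue_intrinsic_rates(pep, cond)
        t = np.geomspace(1e-4, 1e5, 40)
        curve = intrinsic_uptake_curve(rr, t)
        assert np.all(np.diff(curve) >= -1e-12)
        assert np.all(curve <= theoretical_max_uptake(pep, cond.d2o_fraction) + 1e-9)
        assert np.all(rr.rates >= 0)
        for pos in rr.excluded:
            assert rr.rates[pos - 1] == 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(min_value=3.0, max_value=10.0))
    def test_rate_continuity_in_pD(self, pd_read):
        base = LabelingConditions(pd_read, 296.15, 0.95)
        bump = LabelingConditions(pd_read + 1e-5, 296.15, 0.95)
        k0 = residue_intrinsic_rates(PeptideSpec("GASD"), base).rates
        k1 = residue_intrinsic_rates(PeptideSpec("GASD"), bump).rates
        inc = k0 > 0
        assert np.allclose(k0[inc], k1[inc], rtol=1e-3)
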