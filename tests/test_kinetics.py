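import numpy as np
import pytest

from conftest import make_series
from mshdx import (
    PeptideSpec,
    fit_first_order_decay,
    fit_stretched_exponential,
    protection_factors,
    select_model,
    simulate_dnpa,
)
from mshdx.kinetics import StretchedExpModel, ensemble_ln_pf


def stretched(t, q, k, beta):
    return q * (1.0 - np.exp(-((k * t) ** beta)))


@pytest.fixture
def polyala():
    return PeptideSpec("A" * 10)


class TestFit:
    def test_single_phase_noiseless_recovery(self, polyala, schedule):
        s = make_series(polyala, schedule, stretched(schedule, 4.0, 2.0, 1.0))
        fit = fit_stretched_exponential(s, 1)
        assert fit.status == "fitted"
        assert fit.amplitudes[0] == pytest.approx(4.0, rel=1e-4)
        assert fit.rates[0] == pytest.approx(2.0, rel=1e-4)
        assert fit.betas[0] == pytest.approx(1.0, abs=1e-3)

    def test_two_phase_recovery_with_noise(self, polyala):
        """(Q=2, k=10, b=0.8) + (Q=3, k=0.05, b=1), 1% noise, 15 points:
        rates recovered within 10% across repeated simulations."""
        t = np.geomspace(0.05, 300, 15)
        truth = stretched(t, 2, 10, 0.8) + stretched(t, 3, 0.05, 1.0)
        recovered = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            u = truth[:, None] * (1 + 0.01 * rng.standard_normal((15, 3)))
            s = make_series(polyala, t, np.zeros_like(t)).with_uptake(
                np.clip(u, 0, None)
            )
            fit = fit_stretched_exponential(s, 2)
            recovered.append(fit.rates)
        recovered = np.array(recovered)
        assert np.all(np.abs(recovered[:, 0] / 10.0 - 1) < 0.10)
        assert np.all(np.abs(recovered[:, 1] / 0.05 - 1) < 0.10)

    def test_r_squared_high_on_schedule(self, conditions, bradykinin, schedule):
        """Bradykinin-like synthetic data on the 15-point schedule fits a
        stretched exponential with R^2 >= 0.99."""
        from mshdx import intrinsic_uptake_curve, residue_intrinsic_rates

        rr = residue_intrinsic_rates(bradykinin, conditions)
        curve = intrinsic_uptake_curve(rr, schedule)
        s = make_series(bradykinin, schedule, curve, noise_sd=0.03, n_rep=3, seed=5)
        fit = fit_stretched_exponential(s, 1)
        assert fit.r_squared >= 0.99

    def test_insufficient_points_rejected(self, polyala):
        t = np.array([0.1, 1.0, 10.0])
        s = make_series(polyala, t, stretched(t, 2, 1, 1))
        with pytest.raises(ValueError, match="insufficient"):
            fit_stretched_exponential(s, 1)

    def test_amplitude_sum_respects_cap(self, polyala, schedule):
        s = make_series(
            polyala, schedule, stretched(schedule, 5.0, 1.0, 0.9),
            noise_sd=0.05, n_rep=3, seed=3,
        )
        fit = fit_stretched_exponential(s, 2, q_total=5.0)
        assert fit.total_amplitude <= 1.05 * 5.0 + 1e-3

    def test_fitted_curve_monotone(self, polyala, schedule):
        s = make_series(
            polyala, schedule, stretched(schedule, 3.0, 0.5, 0.7),
            noise_sd=0.08, n_rep=3, seed=11,
        )
        fit = fit_stretched_exponential(s, 2)
        grid = np.geomspace(1e-3, 1e4, 300)
        assert np.all(np.diff(fit.predict(grid)) >= -1e-10)


class TestSelectModel:
    def test_pure_single_phase_selects_one(self, polyala, schedule):
        s = make_series(
            polyala, schedule, stretched(schedule, 4.0, 2.0, 1.0),
            noise_sd=0.04, n_rep=3, seed=2,
        )
        assert select_model(s, q_total=5.0).n_phases == 1

    def test_well_separated_two_phase_selects_two(self, polyala, schedule):
        truth = stretched(schedule, 2, 10, 1.0) + stretched(schedule, 3, 0.05, 1.0)
        s = make_series(polyala, schedule, truth, noise_sd=0.05, n_rep=3, seed=4)
        assert select_model(s, q_total=5.5).n_phases == 2

    def test_flat_series_uninformative(self, polyala, schedule):
        s = make_series(polyala, schedule, np.zeros(len(schedule)))
        sel = select_model(s)
        assert sel.status == "uninformative"
        assert sel.amplitudes[0] == 0.0

    def test_noiseless_single_phase_does_not_overfit(self, polyala, schedule):
        s = make_series(polyala, schedule, stretched(schedule, 4.0, 2.0, 0.9))
        assert select_model(s).n_phases == 1


class TestProtectionFactors:
    def _model(self, rates, amps=None):
        rates = np.asarray(rates, dtype=float)
        n = rates.size
        amps = np.asarray(amps if amps is not None else np.ones(n), dtype=float)
        return StretchedExpModel(
            n, amps, rates, np.ones(n), 0.0, 1.0, 30
        )

    def test_unprotected_gives_zero(self):
        pf = protection_factors(self._model([5.0, 0.1]), self._model([5.0, 0.1]))
        np.testing.assert_allclose(pf.ln_pf, 0.0)

    def test_tenfold_protection(self):
        pf = protection_factors(self._model([1.0]), self._model([10.0]))
        assert pf.ln_pf[0] == pytest.approx(np.log(10.0))

    def test_mismatched_phase_counts_warn_and_rank_match(self):
        exp = self._model([1.0, 0.01], amps=[3.0, 1.0])
        intr = self._model([10.0])
        with pytest.warns(UserWarning, match="amplitude rank"):
            pf = protection_factors(exp, intr)
        assert pf.ln_pf.size == 1
        assert pf.ln_pf[0] == pytest.approx(np.log(10.0))

    def test_weighted_average(self):
        pf = protection_factors(
            self._model([1.0, 0.1], amps=[3.0, 1.0]), self._model([10.0, 1.0])
        )
        expected = (3 * np.log(10) + 1 * np.log(10)) / 4
        assert pf.weighted_ln_pf == pytest.approx(expected)

    def test_ensemble_recovery_uniform_protection(self, conditions, bradykinin, schedule):
        """Scaling every intrinsic rate by e^2 shifts the ensemble fit by
        ln Pf = 2 exactly (noise-free)."""
        from mshdx import intrinsic_uptake_curve, residue_intrinsic_rates

        rr = residue_intrinsic_rates(bradykinin, conditions)
        intr = make_series(
            bradykinin, schedule, intrinsic_uptake_curve(rr, schedule),
            state="intrinsic",
        )
        slowed = rr.__class__(
            rr.peptide, rr.conditions, rr.rates / np.exp(2.0), rr.excluded
        )
        exp = make_series(
            bradykinin, schedule, intrinsic_uptake_curve(slowed, schedule)
        )
        ln_pf = ensemble_ln_pf(exp, intr, q_total=4.75)
        assert ln_pf == pytest.approx(2.0, abs=0.05)


class TestFirstOrderDecay:
    def test_noiseless_exact(self):
        t = np.tile([0.04, 0.1, 0.2, 0.3, 0.4, 0.5], 3)
        trace = simulate_dnpa(20.1, t)
        fit = fit_first_order_decay(t, trace)
        assert fit.decaying
        assert fit.k == pytest.approx(20.1, rel=1e-6)

    def test_constant_signal_flagged(self):
        t = np.linspace(0.04, 0.5, 8)
        fit = fit_first_order_decay(t, np.ones_like(t))
        assert not fit.decaying
        assert fit.k_ci[0] <= 0.0 <= fit.k_ci[1]

    def test_noisy_recovery_within_ten_percent(self):
        t = np.tile([0.04, 0.1, 0.2, 0.3, 0.4, 0.5], 3)
        trace = simulate_dnpa(20.1, t, noise_cv=0.03, seed=42)
        fit = fit_first_order_decay(t, trace)
        assert fit.k == pytest.approx(20.1, rel=0.10)
        assert fit.k_ci[0] < 20.1 < fit.k_ci[1]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_first_order_decay([0.1, 0.2, 0.3], [3, 2, 1])
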