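"""4PL fitting, ROUT outlier removal, and the EC50 -> Ki conversion."""

import numpy as np
import pytest
from scipy.optimize import brentq

from pparbias.equilibria import BindingSystem, competitive_equilibrium, fraction_tracer_bound
from pparbias.fitting import TitrationCurve, fit_4pl, four_param_logistic, ki_from_ec50
from pparbias.simulate import PlateSimSpec, default_concentration_series, simulate_plate


def synthetic_4pl_curve(top=0.20, bottom=0.08, ec50=10_000.0, hill=-1.0, noise_sd=0.0, seed=0):
    conc = default_concentration_series()
    y = four_param_logistic(np.log10(conc), bottom, top, np.log10(ec50), hill)
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, y.size)
    return TitrationCurve(conc, y)


class TestFit4PL:
    def test_exact_recovery_on_noise_free_curve(self):
        fit = fit_4pl(synthetic_4pl_curve(), rout_q=0.01)
        assert fit.converged
        assert fit.top == pytest.approx(0.20, rel=1e-6)
        assert fit.bottom == pytest.approx(0.08, rel=1e-6)
        assert fit.ec50 == pytest.approx(10_000.0, rel=1e-6)
        assert fit.hill_slope == pytest.approx(-1.0, rel=1e-6)

    def test_rout_flags_displaced_points_and_spares_clean(self):
        """Q = 1% catches >= 80% of 10-sigma displacements, flags < 2% of clean points."""
        noise_sd = 0.004
        rng = np.random.default_rng(7)
        n_hit = n_disp = n_false = n_clean = 0
        for s in range(500):
            curve = simulate_plate(PlateSimSpec(noise_sd=noise_sd, technical_replicates=2,
                                                dilution_replicates=1, seed=10_000 + s))
            displaced = rng.random(curve.n_obs) < 0.05
            y = curve.responses.copy()
            y[displaced] += rng.choice([-1.0, 1.0], displaced.sum()) * 10 * noise_sd
            fit = fit_4pl(TitrationCurve(curve.concentrations, y), rout_q=0.01)
            n_hit += int((fit.outlier_mask & displaced).sum())
            n_disp += int(displaced.sum())
            n_false += int((fit.outlier_mask & ~displaced).sum())
            n_clean += int((~displaced).sum())
        assert n_hit / n_disp >= 0.80
        assert n_false / n_clean < 0.02

    def test_rout_q_zero_excludes_nothing(self):
        curve = synthetic_4pl_curve(noise_sd=0.004, seed=3)
        fit = fit_4pl(curve, rout_q=0.0)
        assert not fit.outlier_mask.any()

    def test_ec50_ci_coverage(self):
        """Asymptotic 95% CI covers the true midpoint in 93-97% of noisy fits."""
        base = BindingSystem(800.0, 50.0, 200.0)
        f0 = fraction_tracer_bound(base)
        true_ic50 = brentq(
            lambda i: competitive_equilibrium(base.with_competitor(i, 5000.0))[0] - f0 / 2,
            1.0, 1e9, rtol=8.9e-16,
        )
        covered = 0
        n_runs = 500
        for s in range(n_runs):
            curve = simulate_plate(PlateSimSpec(seed=50_000 + s, technical_replicates=2,
                                                dilution_replicates=1))
            fit = fit_4pl(curve, rout_q=0.01)
            lo, hi = fit.ec50_ci
            covered += int(lo <= true_ic50 <= hi)
        assert 0.93 <= covered / n_runs <= 0.97

    def test_invariant_to_observation_order(self):
        curve = synthetic_4pl_curve(noise_sd=0.003, seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(curve.n_obs)
        shuffled = TitrationCurve(curve.concentrations[perm], curve.responses[perm])
        a, b = fit_4pl(curve, rout_q=0.0), fit_4pl(shuffled, rout_q=0.0)
        assert a.ec50 == pytest.approx(b.ec50, rel=1e-9)

    def test_concentration_rescaling_rescales_ec50(self):
        curve = synthetic_4pl_curve(noise_sd=0.003, seed=5)
        rescaled = TitrationCurve(curve.concentrations * 1e3, curve.responses)
        a, b = fit_4pl(curve, rout_q=0.0), fit_4pl(rescaled, rout_q=0.0)
        assert b.ec50 == pytest.approx(a.ec50 * 1e3, rel=1e-6)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match="6 distinct"):
            fit_4pl(TitrationCurve([1.0, 10.0, 100.0], [0.2, 0.14, 0.08]))

    def test_nonconvergence_is_flagged_not_raised(self):
        # pure noise with no sigmoid structure and huge spread
        rng = np.random.default_rng(1)
        conc = default_concentration_series()
        y = rng.normal(0, 1e6, conc.size) * rng.normal(0, 1e6, conc.size)
        fit = fit_4pl(TitrationCurve(conc, y), rout_q=0.0)
        assert isinstance(fit.converged, bool)  # never raises


class TestKiFromEc50:
    def test_cheng_prusoff_limit(self, assay):
        """Dilute receptor and tracer: Ki -> EC50 / (1 + L_free/Kd)."""
        dilute = BindingSystem(1e-3, 1e-3, 200.0)
        ec50 = 5_000.0
        l_free = dilute.tracer_total * (1 - fraction_tracer_bound(dilute))
        expected = ec50 / (1 + l_free / dilute.tracer_kd)
        assert ki_from_ec50(ec50, dilute) == pytest.approx(expected, rel=1e-4)

    def test_exact_on_true_midpoint(self, assay):
        """Conversion inverts the exact equilibrium at the true midpoint."""
        f0 = fraction_tracer_bound(assay)
        for ki_true in (100.0, 5_000.0, 2e5):
            ic50 = brentq(
                lambda i: competitive_equilibrium(assay.with_competitor(i, ki_true))[0] - f0 / 2,
                1e-6, 1e12, rtol=8.9e-16,
            )
            assert ki_from_ec50(ic50, assay) == pytest.approx(ki_true, rel=1e-9)

    def test_roundtrip_simulated_plate_zero_noise(self, assay):
        """Simulate at Ki = 5 uM, fit, convert: recovered within 5% at zero noise."""
        curve = simulate_plate(PlateSimSpec(true_ki=5_000.0, noise_sd=0.0))
        fit = fit_4pl(curve, rout_q=0.0)
        ki = ki_from_ec50(fit, assay)
        assert ki == pytest.approx(5_000.0, rel=0.05)

    def test_monotone_in_ec50(self, assay):
        ec50s = np.geomspace(2_000, 1e6, 12)
        kis = [ki_from_ec50(e, assay) for e in ec50s]
        assert np.all(np.diff(kis) > 0)

    def test_impossible_ec50_rejected(self, assay):
        # EC50 far below the receptor sequestered at the midpoint
        with pytest.raises(ValueError, match="no positive Ki"):
            ki_from_ec50(1.0, assay)

    def test_nonconverged_fit_rejected(self, assay):
        from pparbias.fitting import FitResult

        bad = FitResult(0, 0, 0, 0, {}, (0, 0), np.zeros(1, bool), converged=False)
        with pytest.raises(ValueError, match="non-converged"):
            ki_from_ec50(bad, assay)
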