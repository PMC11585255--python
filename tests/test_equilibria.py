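"""Exactness, limits and conservation laws of the binding-equilibrium solvers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import bisect

from pparbias.equilibria import (
    BindingSystem,
    CoregulatorPool,
    anisotropy_from_intensities,
    competitive_equilibrium,
    free_receptor_cubic,
    free_receptor_fixed_point,
    fraction_tracer_bound,
    multi_competitor_occupancy,
    single_site_occupancy,
)

conc = st.floats(1.0, 1e5)


class TestAnisotropy:
    @pytest.mark.parametrize(
        "ipar, iperp, expected",
        [(1000.0, 1000.0, 0.0), (1000.0, 0.0, 1.0), (2.0, 1.0, 0.25)],
    )
    def test_formula(self, ipar, iperp, expected):
        assert anisotropy_from_intensities(ipar, iperp) == pytest.approx(expected)

    def test_both_zero_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            anisotropy_from_intensities(0.0, 0.0)

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    @settings(max_examples=100, derandomize=True)
    def test_range(self, ipar, iperp):
        if ipar + iperp == 0:
            return
        assert -0.5 <= anisotropy_from_intensities(ipar, iperp) <= 1.0


class TestFractionTracerBound:
    def test_trace_tracer_limit(self):
        f = fraction_tracer_bound(BindingSystem(800.0, 1e-9, 800.0))
        assert f == pytest.approx(0.5, rel=1e-6)

    def test_no_binding_limit(self):
        f = fraction_tracer_bound(BindingSystem(800.0, 50.0, 1e15))
        assert f == pytest.approx(0.0, abs=1e-9)

    def test_matches_bisection_oracle(self):
        p, l, kd = 800.0, 50.0, 200.0

        def mass_balance(r_free):
            return r_free * (1 + l / (kd + r_free)) - p

        r = bisect(mass_balance, 0.0, p, xtol=1e-13)
        expected = (r / (kd + r))
        got = fraction_tracer_bound(BindingSystem(p, l, kd))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_rejects_system_with_competitor(self):
        sys = BindingSystem(800.0, 50.0, 200.0, 1000.0, 500.0)
        with pytest.raises(ValueError, match="competitor"):
            fraction_tracer_bound(sys)


class TestCompetitiveEquilibrium:
    def test_zero_competitor_reduces_to_two_species(self, assay):
        sys = assay.with_competitor(0.0, 5000.0)
        tracer_frac, comp_frac = competitive_equilibrium(sys)
        assert tracer_frac == pytest.approx(fraction_tracer_bound(assay), abs=1e-12)
        assert comp_frac == 0.0

    def test_inert_competitor_reduces_to_two_species(self, assay):
        sys = assay.with_competitor(1e4, 1e18)
        tracer_frac, _ = competitive_equilibrium(sys)
        assert tracer_frac == pytest.approx(fraction_tracer_bound(assay), rel=1e-9)

    def test_matches_fixed_point_oracle_on_random_systems(self):
        rng = np.random.default_rng(42)
        vals = 10 ** rng.uniform(0, 5, size=(1000, 5))
        for p, l, kd, i, ki in vals:
            r_closed = free_receptor_cubic(p, l, kd, i, ki)
            r_fp = free_receptor_fixed_point(p, l, kd, i, ki)
            assert r_closed == pytest.approx(r_fp, rel=1e-9)

    @given(conc, conc, conc, conc, conc)
    @settings(max_examples=200, derandomize=True)
    def test_conservation(self, p, l, kd, i, ki):
        r = free_receptor_cubic(p, l, kd, i, ki)
        tracer_bound = l * r / (kd + r)
        comp_bound = i * r / (ki + r)
        assert r + tracer_bound + comp_bound == pytest.approx(p, rel=1e-9)

    @given(conc, conc, conc, conc, conc, st.floats(1.1, 10.0))
    @settings(max_examples=200, derandomize=True)
    def test_monotonicity(self, p, l, kd, i, ki, factor):
        base = BindingSystem(p, l, kd, i, ki)
        f0, _ = competitive_equilibrium(base)
        f_more_comp, _ = competitive_equilibrium(BindingSystem(p, l, kd, i * factor, ki))
        f_more_rec, _ = competitive_equilibrium(BindingSystem(p * factor, l, kd, i, ki))
        assert f_more_comp <= f0 + 1e-12
        assert f_more_rec >= f0 - 1e-12


class TestMultiCompetitorOccupancy:
    def test_half_saturation(self):
        pool = CoregulatorPool(("A",), (100.0,), (100.0,))
        prof = multi_competitor_occupancy(pool, 1e-3)
        assert prof.fraction_bound_per_species[0] == pytest.approx(0.5)

    def test_two_identical_coregulators_split_evenly(self):
        pool = CoregulatorPool(("A", "B"), (100.0, 100.0), (100.0, 100.0))
        prof = multi_competitor_occupancy(pool, 1e-3)
        assert prof.fraction_bound_per_species == pytest.approx((1 / 3, 1 / 3))
        assert prof.fraction_unoccupied == pytest.approx(1 / 3)

    def test_sums_to_one(self):
        pool = CoregulatorPool(("A", "B", "C"), (150.0, 600.0, 1500.0),
                               (2000.0, 8000.0, 20000.0))
        prof = multi_competitor_occupancy(pool, 50.0, exact=True)
        total = sum(prof.fraction_bound_per_species) + prof.fraction_unoccupied
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_converges_to_exact_as_receptor_vanishes(self):
        pool = CoregulatorPool(("A", "B"), (150.0, 1500.0), (2000.0, 9000.0))
        approx = multi_competitor_occupancy(pool, 1e-6)
        exact = multi_competitor_occupancy(pool, 1e-6, exact=True)
        for a, b in zip(approx.fraction_bound_per_species, exact.fraction_bound_per_species):
            assert a == pytest.approx(b, rel=1e-6)

    def test_cellular_concentrations_within_one_percent(self):
        # receptor 50 nM against coregulators 150-1500 nM at low-micromolar Ki
        pool = CoregulatorPool(("CBP", "PGC1a", "MED1"), (150.0, 600.0, 1500.0),
                               (2000.0, 8000.0, 20000.0))
        with pytest.warns(UserWarning, match="trace-receptor"):
            approx = multi_competitor_occupancy(pool, 50.0)
        exact = multi_competitor_occupancy(pool, 50.0, exact=True)
        for a, b in zip(approx.fraction_bound_per_species + (approx.fraction_unoccupied,),
                        exact.fraction_bound_per_species + (exact.fraction_unoccupied,)):
            assert abs(a - b) < 0.01

    def test_trace_assumption_warning_threshold(self):
        pool = CoregulatorPool(("A",), (100.0,), (100.0,))
        with pytest.warns(UserWarning):
            multi_competitor_occupancy(pool, 11.0)

    def test_nonpositive_ki_rejected(self):
        with pytest.raises(ValueError):
            CoregulatorPool(("A",), (100.0,), (0.0,))

    def test_single_site_occupancy_at_30x_kd_exceeds_90_percent(self):
        assert single_site_occupancy(30.0, 1.0) > 0.90
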