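"""Structural kinetics: clearance functions and the infusion solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from voripk.model_core import (ConcentrationProfile, DoseEvent,
                               StructuralParams, concentration,
                               cumulative_clearance, intrinsic_clearance,
                               sequestration_clearance, total_clearance)

from conftest import ode_concentrations

PUBLISHED = StructuralParams(V=144.79, CL1=6.22, CL2=22.26, Tswitch=87.96,
                          k=0.1, CLseq0=17.68, Thalf_seq=4.17)


class TestClearanceFunctions:
    def test_logistic_midpoint_is_mean_of_phases(self):
        assert intrinsic_clearance(PUBLISHED.Tswitch, PUBLISHED) == pytest.approx(
            (6.22 + 22.26) / 2)

    def test_logistic_asymptote_reaches_late_clearance(self):
        assert intrinsic_clearance(10 * PUBLISHED.Tswitch, PUBLISHED) == pytest.approx(
            22.26, abs=1e-6)

    def test_intrinsic_clearance_at_time_zero(self):
        # CL1 + (CL2-CL1)/(1+e^{k*Tswitch}) evaluated directly
        assert intrinsic_clearance(0.0, PUBLISHED) == pytest.approx(6.2224, abs=1e-4)

    def test_intrinsic_bounded_and_monotone(self):
        t = np.linspace(0, 500, 2001)
        cl = intrinsic_clearance(t, PUBLISHED)
        assert np.all(cl > 6.22) and np.all(cl <= 22.26)  # saturates in float
        assert np.all(np.diff(cl) >= -1e-12)

    @pytest.mark.parametrize("t, expected", [
        (0.0, 17.68), (4.17, 8.84), (8.34, 4.42)])
    def test_sequestration_halves_every_half_life(self, t, expected):
        assert sequestration_clearance(t, PUBLISHED) == pytest.approx(expected)

    def test_sequestration_strictly_decreasing(self):
        t = np.linspace(0, 48, 500)
        assert np.all(np.diff(sequestration_clearance(t, PUBLISHED)) < 0)

    def test_total_is_sum_of_pathways(self):
        t = np.linspace(0, 300, 50)
        np.testing.assert_allclose(
            total_clearance(t, PUBLISHED),
            intrinsic_clearance(t, PUBLISHED) + sequestration_clearance(t, PUBLISHED))
        assert total_clearance(0.0, PUBLISHED) == pytest.approx(23.90, abs=0.01)

    def test_no_sequestration_reduces_to_intrinsic(self):
        p = PUBLISHED.replace(CLseq0=0.0)
        t = np.linspace(0, 200, 20)
        np.testing.assert_allclose(total_clearance(t, p),
                                   intrinsic_clearance(t, p))

    def test_nonfinite_and_negative_times_rejected(self):
        for bad in (np.nan, np.inf, -1.0):
            with pytest.raises(ValueError):
                intrinsic_clearance(bad, PUBLISHED)
            with pytest.raises(ValueError):
                sequestration_clearance(bad, PUBLISHED)

    @pytest.mark.parametrize("kwargs", [
        dict(V=0.0), dict(V=-5.0), dict(CL1=0.0), dict(CL2=-1.0),
        dict(Tswitch=-1.0), dict(k=0.0), dict(CLseq0=-1.0),
        dict(Thalf_seq=0.0), dict(V=np.nan)])
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(V=144.79, CL1=6.22, CL2=22.26, Tswitch=87.96)
        base.update(kwargs)
        with pytest.raises(ValueError):
            StructuralParams(**base)


class TestCumulativeClearance:
    def test_constant_clearance_is_rate_times_interval(self):
        p = StructuralParams(V=100, CL1=7.0, CL2=7.0, Tswitch=50, CLseq0=0.0)
        assert cumulative_clearance(3.0, 10.0, p) == pytest.approx(7.0 * 7.0)

    def test_sequestration_integral_to_infinity(self):
        # all drug the circuit can remove: CLseq0 * Thalf/ln2 litres
        p = PUBLISHED.replace(CL1=1e-9, CL2=1.0001e-9)
        assert cumulative_clearance(0.0, 1e5, p) == pytest.approx(
            17.68 * 4.17 / np.log(2), abs=1e-3)

    def test_matches_adaptive_quadrature(self):
        num, _ = quad(lambda t: float(total_clearance(t, PUBLISHED)), 0, 24,
                      limit=200)
        assert cumulative_clearance(0.0, 24.0, PUBLISHED) == pytest.approx(
            num, rel=1e-8)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 300), st.floats(0, 300), st.floats(0, 300))
    def test_interval_additivity(self, a, b, c):
        a, b, c = sorted((a, b, c))
        total = cumulative_clearance(a, c, PUBLISHED)
        split = (cumulative_clearance(a, b, PUBLISHED)
                 + cumulative_clearance(b, c, PUBLISHED))
        assert split == pytest.approx(total, rel=1e-12, abs=1e-9)

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            cumulative_clearance(10.0, 5.0, PUBLISHED)


def _regimen_doses(weight=87.0, n=20):
    return [DoseEvent(12.0 * i, round((6 if i < 2 else 4) * weight), 2.0)
            for i in range(n)]


class TestConcentrationSolver:
    def test_no_doses_gives_zero_profile(self):
        prof = concentration(np.linspace(0, 48, 10), [], PUBLISHED)
        assert isinstance(prof, ConcentrationProfile)
        np.testing.assert_array_equal(prof.concentrations, 0.0)

    def test_concentration_zero_before_any_infusion(self):
        prof = concentration([0.0, 5.0], [DoseEvent(6.0, 500, 2.0)], PUBLISHED)
        np.testing.assert_array_equal(prof.concentrations, 0.0)

    def test_constant_clearance_infusion_closed_form(self):
        p = StructuralParams(V=100, CL1=10, CL2=10, Tswitch=50, CLseq0=0.0)
        t = np.array([0.25, 0.5, 1.0, 1.5, 1.99])
        c = concentration(t, [DoseEvent(0, 400, 2.0)], p).concentrations
        closed = (200.0 / 10.0) * (1 - np.exp(-10.0 * t / 100.0))
        np.testing.assert_allclose(c, closed, rtol=1e-12)

    def test_linear_in_dose(self):
        t = np.linspace(1, 60, 25)
        doses = [DoseEvent(0, 522, 2.0), DoseEvent(12, 348, 2.0)]
        doubled = [DoseEvent(d.start_time, 2 * d.amount, d.duration)
                   for d in doses]
        c1 = concentration(t, doses, PUBLISHED).concentrations
        c2 = concentration(t, doubled, PUBLISHED).concentrations
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-12)

    def test_superposition_over_dose_events(self):
        t = np.linspace(0.5, 72, 40)
        d1 = [DoseEvent(0, 522, 2.0), DoseEvent(24, 348, 2.0)]
        d2 = [DoseEvent(12, 348, 1.5)]
        c_joint = concentration(t, d1 + d2, PUBLISHED).concentrations
        c_split = (concentration(t, d1, PUBLISHED).concentrations
                   + concentration(t, d2, PUBLISHED).concentrations)
        np.testing.assert_allclose(c_joint, c_split, rtol=1e-10)

    def test_agrees_with_stiff_ode_oracle_on_regimen(self):
        t = np.linspace(0.5, 239.5, 40)
        doses = _regimen_doses()
        mine = concentration(t, doses, PUBLISHED).concentrations
        oracle = ode_concentrations(t, doses, PUBLISHED)
        np.testing.assert_allclose(mine, oracle, rtol=1e-6)

    def test_agrees_with_ode_oracle_on_randomized_configurations(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            p = StructuralParams(
                V=float(rng.uniform(30, 250)), CL1=float(rng.uniform(1, 30)),
                CL2=float(rng.uniform(1, 60)),
                Tswitch=float(rng.uniform(10, 200)),
                k=float(rng.uniform(0.02, 0.5)),
                CLseq0=float(rng.uniform(0, 40)),
                Thalf_seq=float(rng.uniform(0.5, 20)))
            nd = int(rng.integers(1, 10))
            doses = [DoseEvent(float(rng.uniform(0, 10)) + 24 * i,
                               float(rng.uniform(100, 800)),
                               float(rng.uniform(0.5, 4))) for i in range(nd)]
            t = np.sort(rng.uniform(0.1, 24 * nd + 24, 12))
            mine = concentration(t, doses, p).concentrations
            oracle = ode_concentrations(t, doses, p)
            ok = oracle > 1e-9
            np.testing.assert_allclose(mine[ok], oracle[ok], rtol=1e-5)

    def test_mass_balance(self):
        # drug infused = drug remaining + drug cleared, on a fine grid
        doses = [DoseEvent(0, 522, 2.0), DoseEvent(12, 348, 2.0)]
        t = np.linspace(0, 48, 4001)
        c = concentration(t, doses, PUBLISHED).concentrations
        eliminated = np.trapezoid(total_clearance(t, PUBLISHED) * c, t)
        remaining = c[-1] * PUBLISHED.V
        assert eliminated + remaining == pytest.approx(522 + 348, rel=1e-4)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            concentration([2.0, 1.0], [], PUBLISHED)        # unsorted
        with pytest.raises(ValueError):
            concentration([-1.0, 1.0], [], PUBLISHED)       # negative time
        with pytest.raises(ValueError):
            DoseEvent(0.0, 0.0, 2.0)                      # zero amount
        with pytest.raises(ValueError):
            DoseEvent(0.0, 100.0, 0.0)                    # zero duration
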