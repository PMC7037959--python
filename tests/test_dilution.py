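"""Two-stage dilution model: jet expansion, power law, plume height, GCI."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from shipplume.dilution import (
    DilutionParams,
    GridConvergence,
    StackSpec,
    coagulation_fraction_remaining,
    dilution_tendency,
    entrainment_velocity,
    first_stage_dilution_ratio,
    fit_power_law,
    grid_convergence_index,
    initial_plume_temperature,
    plume_cross_section,
    plume_height,
)
from shipplume.events import EVENT_TABLE


class TestEntrainmentVelocity:
    def test_zero_inputs(self):
        assert entrainment_velocity(0.0, 0.0, 0.0) == 0.0

    def test_hand_value(self):
        # sqrt((0.1*5)^2 + (0.1*25)^2) = sqrt(6.5)
        assert entrainment_velocity(5.0, 25.0, 0.0, 0.1) == pytest.approx(2.54951, abs=1e-4)

    @given(st.floats(0, 30), st.floats(0, 30))
    def test_symmetric_in_wind_and_jet(self, u, ujet):
        assert entrainment_velocity(u, ujet) == pytest.approx(entrainment_velocity(ujet, u))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            entrainment_velocity(-1.0, 5.0)


class TestPlumeCrossSection:
    def test_identity_at_t0(self):
        stack = StackSpec(cross_section=2.0)
        assert plume_cross_section(stack, 1.0, 0.0) == pytest.approx(2.0)

    def test_hand_value(self):
        stack = StackSpec(cross_section=1.0, exhaust_velocity=25.0)
        s = plume_cross_section(stack, 2.5495, 1.0, alpha=0.1)
        assert s == pytest.approx((1 + 2.5495) ** 2 - 2.5**2, abs=1e-6)  # 6.349

    def test_monotone_in_entrainment(self):
        stack = StackSpec(cross_section=1.0, exhaust_velocity=25.0)
        areas = [plume_cross_section(stack, sw, 1.0) for sw in (2.6, 3.0, 4.0, 6.0)]
        assert np.all(np.diff(areas) > 0)

    def test_floors_at_stack_area_with_warning(self):
        stack = StackSpec(cross_section=4.0, exhaust_velocity=19.0)
        with pytest.warns(UserWarning, match="flooring"):
            s = plume_cross_section(stack, 0.05, 1.0)
        assert s == 4.0


class TestFirstStageDilution:
    def test_no_expansion_without_wind_or_jet(self):
        stack = StackSpec(cross_section=1.0, exhaust_velocity=0.0)
        assert first_stage_dilution_ratio(stack, 0.0) == pytest.approx(1.0)

    def test_hand_value(self):
        stack = StackSpec(cross_section=1.0, exhaust_velocity=25.0)
        assert first_stage_dilution_ratio(stack, 5.0) == pytest.approx(6.349, abs=1e-3)

    def test_ropax_preset_gives_dr_about_eight(self):
        """DR ~ 8 (confidence interval 7-10) across all harbor-event winds."""
        drs = [
            first_stage_dilution_ratio(StackSpec(), row[6])
            for row in EVENT_TABLE.values()
        ]
        assert all(7.0 <= dr <= 10.0 for dr in drs)
        assert np.mean(drs) == pytest.approx(8.0, abs=1.0)

    def test_monotone_in_wind_and_jet_velocity(self):
        for s0 in (0.3, 0.55, 1.5):
            drs = [
                first_stage_dilution_ratio(StackSpec(s0, 25.0), u)
                for u in np.linspace(0, 10, 21)
            ]
            assert np.all(np.diff(drs) >= -1e-12)
            drs = [
                first_stage_dilution_ratio(StackSpec(s0, vs), 5.0)
                for vs in np.linspace(0, 40, 41)
            ]
            assert np.all(np.diff(drs) >= -1e-12)


class TestPlumeTemperature:
    def test_worked_example(self):
        assert initial_plume_temperature(280.0, 580.0, 8.0) == pytest.approx(317.5)

    def test_equal_temperatures(self):
        for dr in (1.0, 3.0, 100.0):
            assert initial_plume_temperature(285.0, 285.0, dr) == 285.0

    def test_infinite_dilution_limit(self):
        assert initial_plume_temperature(280.0, 580.0, 1e12) == pytest.approx(280.0, abs=1e-6)

    @given(st.floats(250, 310), st.floats(400, 700), st.floats(1, 1000))
    def test_between_ambient_and_exhaust(self, ta, te, dr):
        tp = initial_plume_temperature(ta, te, dr)
        assert ta <= tp <= te

    def test_dr_below_one_rejected(self):
        with pytest.raises(ValueError):
            initial_plume_temperature(280.0, 580.0, 0.5)


class TestCoagulationFractionRemaining:
    def test_no_particles_no_loss(self):
        assert coagulation_fraction_remaining(0.0) == 1.0

    def test_typical_events_range(self):
        """Typical diluted-exhaust loads and winds survive at 0.77-0.95."""
        fractions = [
            coagulation_fraction_remaining(pn, wind_speed=u)
            for pn, u in [(3.2e6, 4.6), (1e7, 4.6), (3.2e6, 2.4), (1e7, 6.3), (5e6, 3.5)]
        ]
        assert all(0.77 <= f <= 0.95 for f in fractions)

    def test_weak_wind_markedly_lower(self):
        weak = coagulation_fraction_remaining(5e6, wind_speed=0.8)
        typical = coagulation_fraction_remaining(5e6, wind_speed=4.6)
        assert weak < 0.75 < typical
        assert 0.0 < weak < 1.0

    def test_fraction_in_unit_interval(self):
        for pn in (1e5, 1e7, 1e9):
            f = coagulation_fraction_remaining(pn, wind_speed=3.0)
            assert 0.0 < f <= 1.0


class TestPowerLawFit:
    def test_noiseless_identity(self):
        x = np.geomspace(40, 3600, 25)
        fit = fit_power_law(x, 5000.0 * x**-1.26)
        assert fit["a"] == pytest.approx(5000.0, rel=1e-6)
        assert fit["b"] == pytest.approx(1.26, abs=1e-6)
        assert fit["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_samples_give_b_zero(self):
        x = np.array([100.0, 200.0, 400.0, 800.0])
        fit = fit_power_law(x, np.full_like(x, 42.0))
        assert fit["b"] == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery(self):
        from shipplume.fixtures import make_dilution_samples

        samples = make_dilution_samples(
            5000.0, 1.26, np.geomspace(40, 3600, 50), noise_sd=0.1, seed=123
        )
        fit = fit_power_law(samples[:, 0], samples[:, 1])
        assert fit["b"] == pytest.approx(1.26, abs=0.05)

    def test_background_subtraction_drops_nonpositive(self):
        x = np.array([100.0, 200.0, 400.0, 800.0, 1600.0])
        y = 5000.0 * x**-1.26 + 3.0
        y[-1] = 2.0  # falls below background after subtraction
        with pytest.warns(UserWarning, match="dropping"):
            fit = fit_power_law(x, y, background=3.0)
        assert fit["n_points"] == 4

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_power_law([100.0, 200.0], [5.0, 2.0])


class TestPlumeHeight:
    def test_initial_height(self):
        p = DilutionParams()
        assert plume_height(0.0, 5.0, p) == pytest.approx(5.5)

    def test_hand_value(self):
        p = DilutionParams(b=1.26, sigma_z_scale=86.49)
        # sqrt(5.5^2 + (86.49*(0.5)^1.26)^2) = 36.53
        assert plume_height(100.0, 5.0, p) == pytest.approx(36.53, abs=0.01)

    def test_calm_wind_stays_at_initial_height(self):
        p = DilutionParams()
        assert plume_height(500.0, 0.0, p) == pytest.approx(5.5)

    def test_monotone_in_time(self):
        p = DilutionParams()
        hs = [plume_height(t, 5.0, p) for t in np.linspace(0, 900, 50)]
        assert np.all(np.diff(hs) >= 0)


class TestDilutionTendency:
    def test_zero_at_background(self):
        assert dilution_tendency(60.0, 60.0, 1.26, 10.0) == 0.0

    def test_hand_value(self):
        assert dilution_tendency(1000.0, 0.0, 1.0, 10.0) == pytest.approx(-100.0)

    def test_closed_form_integration(self):
        """Integrating the tendency reproduces N(t) = N0*(t/t0)^-b."""
        from scipy.integrate import solve_ivp

        b = 1.26
        sol = solve_ivp(
            lambda t, n: dilution_tendency(n, 0.0, b, t),
            (1.0, 900.0),
            [1000.0],
            rtol=1e-10,
            atol=1e-12,
        )
        assert sol.y[0, -1] == pytest.approx(1000.0 * 900.0**-b, rel=0.01)

    @given(st.floats(0.2, 2.0), st.floats(0.0, 500.0), st.floats(0.0, 2000.0))
    def test_no_overshoot(self, b, bg, n0):
        """Explicit steps at dt <= 0.1 s never cross the background value."""
        n, t = n0, 1.0
        for _ in range(200):
            n_next = n + 0.1 * dilution_tendency(n, bg, b, t)
            if n0 >= bg:
                assert n_next >= bg - 1e-9
            else:
                assert n_next <= bg + 1e-9
            n, t = n_next, t + 0.1

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            dilution_tendency(1.0, 0.0, 1.0, 0.0)


class TestGridConvergenceIndex:
    def test_zero_error(self):
        assert grid_convergence_index(GridConvergence(0.0, 2.0, 2.0)) == 0.0

    def test_hand_value(self):
        gci = grid_convergence_index(GridConvergence(0.04, 2.0, 2.0))
        assert gci == pytest.approx(1.25 * 0.04 / 3.0, abs=1e-9)  # 0.016667

    def test_linearity_in_error(self):
        a = grid_convergence_index(GridConvergence(0.02, 1.5, 2.0))
        b = grid_convergence_index(GridConvergence(0.04, 1.5, 2.0))
        assert b == pytest.approx(2 * a)

    def test_invalid_refinement_ratio(self):
        with pytest.raises(ValueError):
            GridConvergence(0.04, 1.0, 2.0)
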