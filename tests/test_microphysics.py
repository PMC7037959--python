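"""Sectional microphysics against closed-form oracles."""

import math

import numpy as np
import pytest

from shipplume.fixtures import exhaust_modes, make_exhaust_distribution
from shipplume.grids import SizeGrid
from shipplume.microphysics import (
    VAPORS,
    background_mixing_step,
    coagulation_step,
    condensation_step,
    deposition_velocity,
    dry_deposition_step,
    equilibrate_water,
    equilibrium_vapor_concentration,
    kelvin_factor,
    rebin,
    saturation_concentration,
)

from shipplume.state import AVOGADRO, AerosolState, COMPONENTS, GasState


@pytest.fixture()
def exhaust(grid):
    state = make_exhaust_distribution(exhaust_modes(), grid)
    state.temperature = 290.0
    state.rh = 72.0
    return state


class TestEquilibriumVapor:
    def test_raoult_zero_mole_fraction(self):
        assert equilibrium_vapor_concentration("C22H46", 290.0, 0.0, 50.0) == 0.0

    def test_kelvin_limit_large_particle(self):
        assert kelvin_factor("C22H46", 290.0, 1e6) == pytest.approx(1.0, abs=1e-4)

    def test_kelvin_ratio_direct_arithmetic(self):
        vp = VAPORS["C22H46"]
        v_m = vp.molar_mass / 1000.0 / vp.liquid_density / AVOGADRO
        kb = 1.380649e-23
        expected = math.exp(
            4 * vp.surface_tension * v_m / (kb * 290.0) * (1 / 1.5e-9 - 1 / 100e-9)
        )
        ratio = kelvin_factor("C22H46", 290.0, 1.5) / kelvin_factor("C22H46", 290.0, 100.0)
        assert ratio == pytest.approx(expected, rel=1e-9)

    def test_saturation_concentration_decreases_when_cold(self):
        assert saturation_concentration("C22H46", 258.0) < saturation_concentration(
            "C22H46", 292.0
        )

    def test_h2so4_involatile(self):
        assert saturation_concentration("H2SO4", 290.0) == 0.0


class TestCondensation:
    def test_no_vapor_involatile_particles_no_change(self, grid):
        from shipplume.fixtures import LognormalMode

        state = make_exhaust_distribution(
            [LognormalMode(1e5, 60.0, 1.5, {"soot": 0.6, "nv_pom": 0.4})], grid
        )
        gases = GasState(temperature=290.0, rh=72.0)
        out, gout = condensation_step(state, gases, 0.1)
        np.testing.assert_allclose(out.number, state.number)
        np.testing.assert_allclose(out.mass, state.mass)

    def test_species_conservation_per_step(self, exhaust):
        """|d(gas + particle)| / total < 1e-8 for every condensing species."""
        gases = GasState(
            {"H2SO4": 3e10, "C22H46": 2e11, "C28H58": 2e11, "C34H70": 3.3e11},
            temperature=290.0,
            rh=72.0,
        )
        state, gout = exhaust, gases
        comp_of = {s: COMPONENTS.index(vp.component) for s, vp in VAPORS.items()}
        for _ in range(20):
            before = {}
            for sp, vp in VAPORS.items():
                to_ug = vp.molar_mass / AVOGADRO * 1e12
                before[sp] = gout[sp] * to_ug
            sv_before = before["C22H46"] + before["C28H58"] + state.mass[comp_of["C22H46"]].sum()
            su_before = before["H2SO4"] + state.mass[comp_of["H2SO4"]].sum()
            el_before = before["C34H70"] + state.mass[comp_of["C34H70"]].sum()
            state, gout = condensation_step(state, gout, 0.1)
            to_ug = lambda sp: VAPORS[sp].molar_mass / AVOGADRO * 1e12
            sv_after = (
                gout["C22H46"] * to_ug("C22H46")
                + gout["C28H58"] * to_ug("C28H58")
                + state.mass[comp_of["C22H46"]].sum()
            )
            su_after = gout["H2SO4"] * to_ug("H2SO4") + state.mass[comp_of["H2SO4"]].sum()
            el_after = gout["C34H70"] * to_ug("C34H70") + state.mass[comp_of["C34H70"]].sum()
            assert abs(sv_after - sv_before) / sv_before < 1e-8
            assert abs(su_after - su_before) / su_before < 1e-8
            assert abs(el_after - el_before) / el_before < 1e-8

    def test_continuum_growth_law(self, grid):
        """Near-continuum uptake approaches 2*pi*Dp*D*C per particle."""
        state = AerosolState.empty(grid, temperature=290.0, rh=50.0)
        sec = grid.section_of(9000.0)  # ~9 um: Kn << 1
        state.number[sec] = 10.0
        state.mass[COMPONENTS.index("soot"), sec] = (
            10.0 * grid.volumes_cm3[sec] * 1800.0 * 1e9
        )
        c34 = 1e9
        gases = GasState({"C34H70": c34}, temperature=290.0, rh=50.0)
        dt = 0.01
        before = state.mass[COMPONENTS.index("elv_om"), sec]
        out, gout = condensation_step(state, gases, dt)
        gained_molec = (out.mass[COMPONENTS.index("elv_om"), sec] - before) / (
            VAPORS["C34H70"].molar_mass / AVOGADRO * 1e12
        )
        d_cm = grid.centers_nm[sec] * 1e-7
        diff = VAPORS["C34H70"].diffusivity_298 * (290.0 / 298.15) ** 1.75
        expected = 2 * math.pi * d_cm * diff * state.number[sec] * c34 * dt
        assert gained_molec == pytest.approx(expected, rel=0.05)

    def test_evaporation_limited_to_available_mass(self, grid):
        state = AerosolState.empty(grid, temperature=300.0, rh=30.0)
        sec = grid.section_of(50.0)
        state.number[sec] = 1e4
        ci = COMPONENTS.index("sv_om")
        state.mass[ci, sec] = 1e-9  # nearly nothing to evaporate
        gases = GasState(temperature=300.0, rh=30.0)
        out, gout = condensation_step(state, gases, 0.1)
        assert out.mass[ci, sec] >= 0.0


class TestCoagulation:
    def test_empty_state(self, grid):
        state = AerosolState.empty(grid)
        out = coagulation_step(state, 0.1)
        assert out.total_number == 0.0

    def test_constant_kernel_smoluchowski(self, grid):
        """Monodisperse decay follows N0/(1 + K*N0*t/2) within 2%."""
        state = AerosolState.empty(grid)
        sec = grid.section_of(50.0)
        state.number[sec] = 1e6
        state.mass[0, sec] = 1e6 * grid.volumes_cm3[sec] * 1800e9
        k_const = 1e-9
        kernel = np.full((grid.n_sections, grid.n_sections), k_const)
        n0 = state.total_number
        for _ in range(100):
            state = coagulation_step(state, 0.1, kernel=kernel)
        expected = n0 / (1.0 + 0.5 * k_const * n0 * 10.0)
        assert state.total_number == pytest.approx(expected, rel=0.02)

    def test_component_mass_conserved(self, exhaust):
        state = exhaust
        before = state.mass.sum(axis=1)
        for _ in range(20):
            state = coagulation_step(state, 0.1)
        after = state.mass.sum(axis=1)
        occupied = before > 0
        np.testing.assert_allclose(after[occupied], before[occupied], rtol=1e-9)

    def test_number_strictly_decreases(self, exhaust):
        state = exhaust
        totals = [state.total_number]
        for _ in range(10):
            state = coagulation_step(state, 0.1)
            totals.append(state.total_number)
        assert np.all(np.diff(totals) < 0)

    def test_states_stay_nonnegative(self, exhaust):
        state = exhaust
        for _ in range(20):
            state = coagulation_step(state, 0.1)
        state.validate()


class TestDryDeposition:
    def test_closed_form_single_section(self, grid):
        state = AerosolState.empty(grid)
        sec = grid.section_of(100.0)
        state.number[sec] = 1e4
        vd = deposition_velocity(np.array([grid.centers_m[sec]]))[0]
        out = dry_deposition_step(state, 1.0, plume_height=10.0)
        expected_loss = 1e4 * (1.0 - math.exp(-vd * 1.0 / 10.0))
        assert 1e4 - out.number[sec] == pytest.approx(expected_loss, rel=1e-9)

    def test_never_exceeds_available(self, exhaust):
        out = dry_deposition_step(exhaust, 0.1, plume_height=5.5)
        assert (out.number >= 0).all() and (out.number <= exhaust.number).all()

    def test_velocity_size_dependence(self):
        """Deposition is fast for ultrafine and coarse sizes, slow at ~0.3 um."""
        d = np.array([5e-9, 300e-9, 5e-6])
        vd = deposition_velocity(d)
        assert vd[1] < vd[0] and vd[1] < vd[2]

    def test_invalid_plume_height(self, exhaust):
        with pytest.raises(ValueError):
            dry_deposition_step(exhaust, 0.1, plume_height=0.0)


class TestBackgroundMixing:
    def test_background_fixed_point(self, grid):
        bg = make_exhaust_distribution(exhaust_modes(5400.0), grid)
        out = background_mixing_step(bg.copy(), bg, 1.26, 10.0, 0.1)
        np.testing.assert_allclose(out.number, bg.number, rtol=1e-12)

    def test_closed_form_decay(self, exhaust, grid):
        """Against zero background, N(900)/N(1) = 900^-b."""
        bg = AerosolState.empty(grid)
        state = exhaust.copy()
        t, dt, b = 1.0, 0.1, 1.26
        while t < 900.0 - 1e-9:
            state = background_mixing_step(state, bg, b, t, dt)
            t += dt
        ratio = state.total_number / exhaust.total_number
        assert ratio == pytest.approx(900.0**-1.26, rel=0.01)

    def test_order_of_magnitude_drop_in_ten_seconds(self, exhaust, grid):
        bg = AerosolState.empty(grid)
        state = exhaust.copy()
        t, dt = 1.0, 0.1
        while t < 10.0 - 1e-9:
            state = background_mixing_step(state, bg, 1.26, t, dt)
            t += dt
        drop = state.total_number / exhaust.total_number
        assert 0.01 < drop < 0.12  # "about one order of magnitude"

    def test_never_crosses_background(self, grid):
        bg = make_exhaust_distribution(exhaust_modes(5400.0), grid)
        state = AerosolState.empty(grid)  # plume below background
        t = 1.0
        for _ in range(100):
            state = background_mixing_step(state, bg, 1.4, t, 0.1)
            assert np.all(state.number <= bg.number * (1 + 1e-12))
            t += 0.1


class TestRebinAndWater:
    def test_rebin_conserves_number_and_mass(self, grid):
        state = AerosolState.empty(grid)
        sec = grid.section_of(10.0)
        state.number[sec] = 1e5
        # mass consistent with a particle 3 sections larger
        big = grid.volumes_cm3[sec + 3]
        state.mass[COMPONENTS.index("sulfate"), sec] = 1e5 * big * 1830e9
        n0, m0 = state.total_number, state.mass.sum()
        rebin(state)
        assert state.number[sec] == 0.0
        assert state.total_number == pytest.approx(n0, rel=1e-12)
        assert state.mass.sum() == pytest.approx(m0, rel=1e-12)
        # content landed around the consistent size
        occupied = np.nonzero(state.number)[0]
        assert set(occupied) <= {sec + 2, sec + 3, sec + 4}

    def test_water_zero_at_dry_air(self, exhaust):
        out = equilibrate_water(exhaust, rh=0.0)
        assert out.mass[COMPONENTS.index("water")].sum() == 0.0

    def test_water_scales_with_hygroscopic_mass(self, exhaust):
        out = equilibrate_water(exhaust, rh=72.0)
        water = out.mass[COMPONENTS.index("water")]
        sulfate = exhaust.mass[COMPONENTS.index("sulfate")]
        assert water.sum() > 0
        assert (water[sulfate == 0] <= water.max()).all()
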