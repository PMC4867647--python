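"""Solute transport: dispersion, the upwind CDE, fertilizer placement."""

import numpy as np
import pytest
from scipy.special import erfc

from whcns.management import ManagementEvent
from whcns.soil_water import HydraulicParams, SoilGrid, SoilLayerSpec
from whcns.solute_transport import (DispersionSpec, SoluteSpecies,
                                    apply_fertilizer, band_weights, cde_step,
                                    dispersion_coefficient)
from whcns.carbon_nitrogen import PoolState, TurnoverParams

from datetime import date


def make_column(dz=5.0, depth=200.0):
    hp = HydraulicParams(0.05, 0.40, 0.02, 1.5, 50.0)
    layer = SoilLayerSpec(0, max(depth, 300.0), 1.4, 40, 40, 20, hp, pH=7.5)
    return SoilGrid([layer], dz=dz, profile_depth=depth)


class TestDispersionCoefficient:
    def test_saturated_tortuosity_collapses(self):
        # tau = theta_s^(7/3)/theta_s^2 = theta_s^(1/3) at saturation
        ths = 0.385
        d = dispersion_coefficient(ths, ths, 0.0, d0=2.4, dispersivity=3.0)
        assert d == pytest.approx(2.4 * ths ** (1.0 / 3.0), rel=1e-12)
        assert d == pytest.approx(1.746, abs=2e-3)

    def test_mechanical_term_linear_in_flux(self):
        base = dispersion_coefficient(0.3, 0.4, 1.0, 2.4, 3.0)
        double = dispersion_coefficient(0.3, 0.4, 2.0, 2.4, 3.0)
        diffusive = dispersion_coefficient(0.3, 0.4, 0.0, 2.4, 3.0)
        assert double - diffusive == pytest.approx(2.0 * (base - diffusive))

    def test_zero_theta_rejected(self):
        with pytest.raises(ValueError):
            dispersion_coefficient(0.0, 0.4, 1.0, 2.4)


class TestCdeStep:
    def test_mass_conserved_without_flow(self):
        grid = make_column()
        grid.set_uniform_head(-100.0)
        theta = grid.theta.copy()
        conc = np.zeros(grid.n_nodes)
        conc[5:10] = 30.0
        sp = SoluteSpecies("nitrate", conc, d0=2.4)
        m0 = sp.column_mass(grid)
        q = np.zeros(grid.n_nodes + 1)
        for _ in range(50):
            res = cde_step(grid, sp, q, theta, 0.5)
        assert sp.column_mass(grid) == pytest.approx(m0, rel=1e-12)
        assert abs(res["mass_error"]) < 1e-10

    def test_flux_inlet_front_matches_analytic(self):
        # steady saturated flow with a continuous surface input; oracle is
        # the exact third-type-inlet solution of the advection-dispersion
        # problem (the flux-boundary variant of the classic step-input
        # front solution)
        grid = make_column(dz=0.25, depth=200.0)
        grid.set_uniform_head(0.0)
        theta = grid.theta.copy()
        v = 25.0
        q0 = v * theta[0]
        faces = np.full(grid.n_nodes + 1, q0)
        sp = SoluteSpecies("nitrate", np.zeros(grid.n_nodes), d0=2.4)
        c0, dt, t_end = 50.0, 0.002, 3.0
        for _ in range(int(t_end / dt)):
            cde_step(grid, sp, faces, theta, dt,
                     top_solute_concentration=c0,
                     dispersion=DispersionSpec(3.0))
        D = dispersion_coefficient(theta[0], grid.theta_s[0], q0, 2.4, 3.0)
        x, t = grid.z, t_end
        a = 0.5 * erfc((x - v * t) / (2.0 * np.sqrt(D * t)))
        b = np.sqrt(v * v * t / (np.pi * D)) * np.exp(
            -((x - v * t) ** 2) / (4.0 * D * t))
        c = -0.5 * (1.0 + v * x / D + v * v * t / D) * np.exp(
            np.clip(v * x / D, None, 700.0)) * erfc(
            (x + v * t) / (2.0 * np.sqrt(D * t)))
        analytic = c0 * (a + b + c)
        assert np.max(np.abs(sp.conc - analytic)) / c0 < 0.02

    def test_upwind_front_is_monotone(self):
        grid = make_column(dz=2.0, depth=100.0)
        grid.set_uniform_head(-30.0)
        theta = grid.theta.copy()
        conc = np.where(grid.z < 30.0, 80.0, 0.0)
        sp = SoluteSpecies("nitrate", conc.astype(float), d0=0.0)
        faces = np.full(grid.n_nodes + 1, 4.0)
        for _ in range(40):
            # inlet held at the plateau concentration: the advected front
            # must stay a single monotone step with no new extrema
            cde_step(grid, sp, faces, theta, 0.25,
                     top_solute_concentration=80.0,
                     dispersion=DispersionSpec(0.0))
            assert sp.conc.max() <= 80.0 + 1e-9
            assert sp.conc.min() >= -1e-12
            assert np.all(np.diff(sp.conc) <= 1e-9)

    def test_adsorbed_species_is_retarded(self):
        grid = make_column(dz=2.0, depth=100.0)
        grid.set_uniform_head(-30.0)
        theta = grid.theta.copy()
        pulse = np.where(grid.z < 10.0, 50.0, 0.0).astype(float)
        free = SoluteSpecies("nitrate", pulse.copy(), d0=1.0)
        stuck = SoluteSpecies("ammonium", pulse.copy(), d0=1.0, kd=1.0)
        faces = np.full(grid.n_nodes + 1, 3.0)
        for _ in range(20):
            cde_step(grid, free, faces, theta, 0.25)
            cde_step(grid, stuck, faces, theta, 0.25)
        centre = lambda s: np.sum(grid.z * s.conc * theta) / np.sum(
            s.conc * theta)
        assert centre(stuck) < centre(free)

    def test_isotherm_mass_consistency(self):
        grid = make_column()
        grid.set_uniform_head(-100.0)
        sp = SoluteSpecies("ammonium", np.full(grid.n_nodes, 5.0), d0=1.2,
                           kd=1.0)
        bulk = sp.bulk_concentration(grid)
        expected = grid.theta * 5.0 + grid.bulk_density * 1.0 * 5.0
        assert np.allclose(bulk, expected)
        sp.add_bulk_mass(grid, np.full(grid.n_nodes, 7.0))
        assert np.allclose(sp.bulk_concentration(grid), expected + 7.0)


class TestFertilizerPlacement:
    def make_species(self, grid):
        return {
            "urea": SoluteSpecies("urea", np.zeros(grid.n_nodes), d0=2.4),
            "ammonium": SoluteSpecies("ammonium", np.zeros(grid.n_nodes),
                                      d0=1.2, kd=1.0),
            "nitrate": SoluteSpecies("nitrate", np.zeros(grid.n_nodes),
                                     d0=2.4),
        }

    def test_surface_urea_mass_and_placement(self):
        grid = make_column(dz=1.0, depth=100.0)
        grid.set_uniform_head(-100.0)
        species = self.make_species(grid)
        ev = ManagementEvent(date(2000, 5, 1), "fertilize", amount=100.0,
                             method="surface", form="urea")
        apply_fertilizer(ev, grid, species)
        assert species["urea"].column_mass(grid) == pytest.approx(100.0)
        bulk = species["urea"].bulk_concentration(grid)
        assert bulk[0] > 0.0
        assert np.all(bulk[1:] == 0.0)  # all within the top 1 cm

    def test_deep_band_placement(self):
        grid = make_column(dz=1.0, depth=100.0)
        grid.set_uniform_head(-100.0)
        species = self.make_species(grid)
        ev = ManagementEvent(date(2000, 5, 1), "fertilize", amount=60.0,
                             method="deep", form="nitrate")
        apply_fertilizer(ev, grid, species, deep_band=(5.0, 10.0))
        bulk = species["nitrate"].bulk_concentration(grid)
        inside = (grid.z > 5.0) & (grid.z < 10.0)
        assert np.all(bulk[~inside] == 0.0)
        assert species["nitrate"].column_mass(grid) == pytest.approx(60.0)

    def test_fertigation_without_irrigation_fails(self):
        grid = make_column()
        grid.set_uniform_head(-100.0)
        ev = ManagementEvent(date(2000, 6, 1), "fertilize", amount=50.0,
                             method="fertigation", form="urea")
        with pytest.raises(ValueError):
            apply_fertilizer(ev, grid, self.make_species(grid),
                             irrigation_mm=0.0)

    def test_fertigation_concentration(self):
        grid = make_column()
        grid.set_uniform_head(-100.0)
        ev = ManagementEvent(date(2000, 6, 1), "fertilize", amount=50.0,
                             method="fertigation", form="nitrate")
        info = apply_fertilizer(ev, grid, self.make_species(grid),
                                irrigation_mm=50.0)
        # 50 kg/ha in 50 mm = 500 ug cm-2 in 5 cm of water = 100 ug cm-3
        assert info["fertigation_concentration"] == pytest.approx(100.0)

    def test_manure_goes_to_aom_with_cn(self):
        grid = make_column()
        grid.set_uniform_head(-100.0)
        pools = PoolState.from_soc(grid.n_nodes, 1.0, grid.bulk_density,
                                   TurnoverParams())
        c0, n0 = pools.column_totals(grid.dz)
        ev = ManagementEvent(date(2000, 4, 1), "fertilize", amount=40.0,
                             method="mix", form="manure", cn_ratio=15.0)
        apply_fertilizer(ev, grid, self.make_species(grid), pools=pools)
        c1, n1 = pools.column_totals(grid.dz)
        assert n1 - n0 == pytest.approx(40.0, rel=1e-9)
        assert c1 - c0 == pytest.approx(40.0 * 15.0, rel=1e-9)

    def test_unknown_method_rejected(self):
        grid = make_column()
        ev = ManagementEvent(date(2000, 4, 1), "fertilize", amount=10.0,
                             method="broadcast", form="urea")
        with pytest.raises(ValueError):
            apply_fertilizer(ev, grid, self.make_species(grid))

    def test_band_weights_sum_to_one(self):
        grid = make_column(dz=5.0, depth=100.0)
        w = band_weights(grid, 0.0, 17.0)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w[grid.z > 20.0] == 0.0)
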