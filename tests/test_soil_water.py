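"""Hydraulic functions, runoff, infiltration and the Richards solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from whcns.soil_water import (HydraulicParams, RichardsNonConvergence,
                              SoilGrid, SoilLayerSpec, conductivity,
                              green_ampt_cumulative, green_ampt_infiltrate,
                              internodal_fluxes, retention_head,
                              retention_theta, richards_step, scs_runoff,
                              validate_layers, wetting_front_suction)

TOPSOIL = HydraulicParams(theta_r=0.027, theta_s=0.385, alpha=0.021,
                          n=2.013, K_s=92.0)  # sandy topsoil fixture


class TestRetention:
    def test_saturation_limit(self, loam_params):
        assert retention_theta(0.0, loam_params) == loam_params.theta_s
        assert conductivity(0.0, loam_params) == pytest.approx(
            loam_params.K_s)

    def test_closed_form_value(self):
        # independent evaluation of the van Genuchten closed form at
        # h = -100 cm for the sandy topsoil parameter set
        h, p = -100.0, TOPSOIL
        m = 1.0 - 1.0 / p.n
        se = (1.0 + (p.alpha * abs(h)) ** p.n) ** (-m)
        expected = p.theta_r + (p.theta_s - p.theta_r) * se
        assert retention_theta(h, p) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.17945, abs=1e-4)

    @pytest.mark.parametrize("h", [-1.0, -10.0, -1e3, -1e5])
    def test_inverse_identity(self, h, loam_params):
        theta = retention_theta(h, loam_params)
        assert retention_head(theta, loam_params) == pytest.approx(
            h, rel=1e-9)

    def test_inversion_domain_error(self, loam_params):
        with pytest.raises(ValueError):
            retention_head(loam_params.theta_r, loam_params)
        with pytest.raises(ValueError):
            retention_head(loam_params.theta_s + 0.01, loam_params)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            HydraulicParams(theta_r=0.3, theta_s=0.2, alpha=0.02, n=1.5,
                            K_s=10.0)
        with pytest.raises(ValueError):
            HydraulicParams(theta_r=0.05, theta_s=0.4, alpha=0.02, n=0.9,
                            K_s=10.0)


class TestSCSRunoff:
    def test_zero_rain(self):
        assert scs_runoff(0.0, 75.0) == 0.0

    def test_below_initial_abstraction(self):
        # CN 75: S = 84.67 mm, Ia = 16.93 mm, so 10 mm produces nothing
        assert scs_runoff(10.0, 75.0) == 0.0

    def test_closed_form_value(self):
        S = 25400.0 / 75.0 - 254.0
        expected = (50.0 - 0.2 * S) ** 2 / (50.0 + 0.8 * S)
        assert scs_runoff(50.0, 75.0) == pytest.approx(expected)
        assert expected == pytest.approx(9.29, abs=0.01)

    @settings(deadline=None, max_examples=50)
    @given(p1=st.floats(0.0, 200.0), p2=st.floats(0.0, 200.0),
           cn=st.floats(40.0, 95.0))
    def test_monotone_in_precip_and_cn(self, p1, p2, cn):
        lo, hi = sorted((p1, p2))
        assert scs_runoff(hi, cn) >= scs_runoff(lo, cn)
        assert scs_runoff(hi, min(cn + 3.0, 99.0)) >= scs_runoff(hi, cn)

    def test_antecedent_classes_ordered(self):
        p = 40.0
        assert (scs_runoff(p, 75, "I") < scs_runoff(p, 75, "II")
                < scs_runoff(p, 75, "III"))


class TestGreenAmpt:
    def test_zero_supply(self, loam_params):
        assert green_ampt_infiltrate(0.0, 0.1, loam_params) == (0.0, 0.0)

    def test_small_supply_all_infiltrates(self, loam_params):
        inf, excess = green_ampt_infiltrate(5.0, 0.06, loam_params, dt=1.0)
        assert inf == pytest.approx(5.0)
        assert excess == 0.0

    def test_cumulative_matches_bisection_oracle(self):
        # K_s = 92 cm/d, dtheta = 0.3, psi = 20 cm, unlimited supply
        Ks, psi, dtheta, t = 92.0, 20.0, 0.3, 0.1
        pd = psi * dtheta

        def f(F):
            return F - pd * np.log1p(F / pd) - Ks * t

        lo, hi = 1e-9, 1000.0
        for _ in range(80):  # plain bisection, independent of brentq
            mid = 0.5 * (lo + hi)
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        oracle = 0.5 * (lo + hi)
        assert green_ampt_cumulative(t, Ks, psi, dtheta) == pytest.approx(
            oracle, abs=1e-6)

    def test_saturated_soil_caps_at_ks(self, loam_params):
        inf, excess = green_ampt_infiltrate(
            1e5, loam_params.theta_s, loam_params, dt=1.0)
        assert inf == pytest.approx(loam_params.K_s * 10.0)

    def test_wetting_front_suction_positive(self, loam_params):
        psi = wetting_front_suction(loam_params)
        assert 1.0 < psi < 200.0


class TestLayers:
    def test_non_contiguous_rejected(self, loam_params):
        a = SoilLayerSpec(0, 30, 1.4, 40, 40, 20, loam_params)
        b = SoilLayerSpec(40, 60, 1.4, 40, 40, 20, loam_params)
        with pytest.raises(ValueError):
            validate_layers([a, b])

    def test_texture_sum_enforced(self, loam_params):
        with pytest.raises(ValueError):
            SoilLayerSpec(0, 30, 1.4, 50, 40, 20, loam_params)


class TestRichards:
    def test_hydrostatic_profile_stationary(self, loam_column):
        loam_column.set_hydrostatic(-150.0)
        h0 = loam_column.h.copy()
        for _ in range(10):
            richards_step(loam_column, 1.0, top_flux=0.0,
                          bottom_condition="no_flux")
        assert np.max(np.abs(loam_column.h - h0)) < 1e-8

    def test_steady_flux_matches_darcy(self, loam_params):
        # constant influx with free drainage reaches a unit-gradient state
        # where K(h) = q; the analytic head follows by inverting K
        layer = SoilLayerSpec(0, 30, 1.4, 40, 40, 20, loam_params)
        grid = SoilGrid([layer], dz=2.0, profile_depth=30.0)
        grid.set_uniform_head(-50.0)
        q0 = 5.0
        for _ in range(400):
            res = richards_step(grid, 0.25, top_flux=q0,
                                bottom_condition="free_drainage",
                                max_iterations=60)
        assert res["bottom_flux"] == pytest.approx(q0, rel=1e-6)
        h_star = brentq(lambda h: conductivity(h, loam_params) - q0,
                        -1000.0, -1e-9)
        assert grid.h[grid.n_nodes // 2] == pytest.approx(h_star, rel=1e-4)

    def test_wetting_front_storage_ledger(self, loam_column):
        loam_column.set_uniform_head(-2000.0)
        s0 = loam_column.storage()
        influx = 0.0
        for _ in range(20):
            res = richards_step(loam_column, 0.1, top_flux=3.0,
                                bottom_condition="free_drainage",
                                max_iterations=60)
            influx += (res["top_flux"] - res["bottom_flux"]) * 0.1
        assert loam_column.storage() - s0 == pytest.approx(influx, abs=1e-8)
        # the front advances: upper nodes wetted, deep nodes untouched
        assert loam_column.theta[0] > 0.2
        assert loam_column.theta[-1] == pytest.approx(
            retention_theta(-2000.0, loam_column.layers[0].hydraulic),
            abs=1e-6)

    def test_theta_bounds_preserved(self, loam_column):
        loam_column.set_uniform_head(-300.0)
        for flux in (8.0, -0.5, 15.0, 0.0):
            richards_step(loam_column, 0.5, top_flux=flux,
                          bottom_condition="free_drainage",
                          max_iterations=80)
            assert np.all(loam_column.theta >= loam_column.theta_r - 1e-12)
            assert np.all(loam_column.theta <= loam_column.theta_s + 1e-12)

    def test_converges_to_hydrostatic_under_no_flux(self, loam_params):
        layer = SoilLayerSpec(0, 30, 1.4, 40, 40, 20, loam_params)
        grid = SoilGrid([layer], dz=5.0, profile_depth=30.0)
        grid.h = np.linspace(-400.0, -50.0, grid.n_nodes)
        grid.sync_theta()
        for _ in range(3000):
            richards_step(grid, 1.0, top_flux=0.0,
                          bottom_condition="no_flux", max_iterations=60)
        assert np.allclose(np.diff(grid.h) / grid.dz, 1.0, atol=1e-5)

    def test_grid_refinement_steady_flux(self, loam_params):
        layer = SoilLayerSpec(0, 30, 1.4, 40, 40, 20, loam_params)
        fluxes = []
        for dz in (5.0, 2.5):
            grid = SoilGrid([layer], dz=dz, profile_depth=30.0)
            grid.set_uniform_head(-100.0)
            for _ in range(600):
                res = richards_step(grid, 0.25, top_flux=2.0,
                                    bottom_condition="free_drainage",
                                    max_iterations=60)
            fluxes.append(res["bottom_flux"])
        assert fluxes[0] == pytest.approx(fluxes[1], rel=0.01)

    def test_internodal_fluxes_shape(self, loam_column):
        q = internodal_fluxes(loam_column, 1.0, 0.5)
        assert q.shape == (loam_column.n_nodes + 1,)
        assert q[0] == 1.0 and q[-1] == 0.5
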