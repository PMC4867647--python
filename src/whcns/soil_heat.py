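"""1-D soil temperature by conduction-convection.

The heat equation is advanced implicitly on the water grid with Dirichlet
boundaries: the surface temperature is damped toward a lagged mean as the
canopy closes (DNDC-style), and the bottom boundary is held at the long-term
mean air temperature. Convective transport by the day's water fluxes uses
first-order upwinding, so the scheme is monotone.

Thermal properties come from a de Vries-style volumetric mixing of mineral
solids, organic matter and water.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .soil_water import SoilGrid, _thomas

__all__ = ["ThermalState", "surface_temperature", "heat_step",
           "volumetric_heat_capacity", "thermal_conductivity"]

C_WATER = 4.18    # J cm-3 K-1
C_MINERAL = 1.93  # J cm-3 K-1 (per unit solids volume)
C_ORGANIC = 2.51  # J cm-3 K-1
PARTICLE_DENSITY = 2.65  # g cm-3


def volumetric_heat_capacity(theta: np.ndarray, bulk_density: np.ndarray,
                             organic_fraction: float = 0.02) -> np.ndarray:
    """Volumetric heat capacity (J cm-3 K-1) from solids and water content."""
    solids = bulk_density / PARTICLE_DENSITY
    mineral = solids * (1.0 - organic_fraction)
    organic = solids * organic_fraction
    return C_MINERAL * mineral + C_ORGANIC * organic + C_WATER * theta


def thermal_conductivity(theta: np.ndarray, clay_fraction: np.ndarray
                         ) -> np.ndarray:
    """Apparent thermal conductivity (J cm-1 d-1 K-1).

    Simple moisture-dependent mixing: dry-soil baseline rising with water
    content toward a saturated value, slightly lower for clayey material
    (quartz fraction effect). Magnitudes correspond to 0.2-1.8 W m-1 K-1.
    """
    lam_dry = 0.25 - 0.05 * clay_fraction   # W m-1 K-1
    lam_wet = 1.8 - 0.6 * clay_fraction
    lam = lam_dry + (lam_wet - lam_dry) * np.sqrt(np.clip(theta, 0.0, 1.0))
    # W m-1 K-1 -> J cm-1 d-1 K-1 : * 86400 s/d / 100 cm/m
    return lam * 864.0


@dataclass
class ThermalState:
    """Per-node soil temperature plus a lagged surface-air running mean."""

    temperature: np.ndarray
    running_mean_air: float = 10.0
    memory_days: float = 10.0

    @classmethod
    def uniform(cls, grid: SoilGrid, t0: float, mean_air: float | None = None):
        return cls(np.full(grid.n_nodes, float(t0)),
                   running_mean_air=t0 if mean_air is None else mean_air)

    def update_running_mean(self, tair: float) -> None:
        w = 1.0 / self.memory_days
        self.running_mean_air += w * (tair - self.running_mean_air)


def surface_temperature(tair_mean: float, lai: float,
                        running_mean: float | None = None,
                        damping: float = 0.2) -> float:
    """Soil surface temperature (deg C) from air temperature and canopy cover.

    Bare soil tracks the daily mean air temperature; with increasing LAI the
    canopy shades the surface and pulls it toward the lagged running mean of
    air temperature. The shading weight is 1 - exp(-damping * LAI).
    """
    if lai < 0.0:
        raise ValueError("LAI must be >= 0")
    if running_mean is None or lai == 0.0:
        shade = 0.0 if lai == 0.0 else 1.0 - np.exp(-damping * lai)
        ref = tair_mean if running_mean is None else running_mean
        return (1.0 - shade) * tair_mean + shade * ref
    shade = 1.0 - np.exp(-damping * lai)
    return (1.0 - shade) * tair_mean + shade * running_mean


def heat_step(state: ThermalState, grid: SoilGrid, water_fluxes: np.ndarray,
              t_top: float, t_bottom: float, dt: float,
              organic_fraction: float = 0.02) -> dict:
    """Advance conduction-convection heat transport by one implicit step.

    water_fluxes : Darcy flux at the n+1 cell faces (cm d-1, positive down),
        as returned by :func:`whcns.soil_water.internodal_fluxes`.
    Boundaries are Dirichlet at half a cell above the first node (t_top) and
    below the last node (t_bottom).

    Returns an energy audit dict (all in J cm-2).
    """
    T_old = state.temperature
    n = grid.n_nodes
    dz = grid.dz
    q = np.asarray(water_fluxes, dtype=float)
    Cv = volumetric_heat_capacity(grid.theta, grid.bulk_density,
                                  organic_fraction)
    lam = thermal_conductivity(grid.theta, grid.clay_fraction)
    lam_int = 0.5 * (lam[:-1] + lam[1:])

    a = np.zeros(n)
    b = Cv * dz / dt
    c = np.zeros(n)
    d = Cv * dz / dt * T_old

    # interior conduction
    w = lam_int / dz
    a[1:] -= w
    b[1:] += w
    b[:-1] += w
    c[:-1] -= w
    # interior convection, upwind in flux direction (energy flux q*Cw*T)
    qc = q[1:-1] * C_WATER
    down = qc > 0.0
    b[:-1] += np.where(down, qc, 0.0)
    c[:-1] += np.where(down, 0.0, qc)
    a[1:] -= np.where(down, qc, 0.0)
    b[1:] -= np.where(down, 0.0, qc)

    # top Dirichlet at dz/2 above node 0
    wt = lam[0] / (0.5 * dz)
    b[0] += wt
    d[0] += wt * t_top
    if q[0] > 0.0:  # infiltrating water enters at the surface temperature
        d[0] += q[0] * C_WATER * t_top
    else:            # upward outflow carries the node temperature
        b[0] -= q[0] * C_WATER

    # bottom Dirichlet at dz/2 below node n-1
    wb = lam[-1] / (0.5 * dz)
    b[-1] += wb
    d[-1] += wb * t_bottom
    if q[-1] > 0.0:  # drainage carries node temperature out
        b[-1] += q[-1] * C_WATER
    else:
        d[-1] -= q[-1] * C_WATER * t_bottom

    T_new = _thomas(a, b, c, d)

    energy_change = float(np.sum(Cv * (T_new - T_old)) * dz)
    state.temperature = T_new
    return {"energy_change": energy_change}
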