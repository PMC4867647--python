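"""Convection-dispersion transport of urea-N, ammonium-N and nitrate-N.

The retarded CDE

    d(theta*c + rho_b*s)/dt = d/dz(theta*D_sh*dc/dz) - d(q*c)/dz + phi

is advanced with fully implicit first-order upwind advection and implicit
dispersion (an M-matrix, hence unconditionally stable, monotone and
positivity preserving). Boundaries are third-type (Cauchy) flux conditions:
solute enters only with infiltrating water, and leaves the column with the
bottom drainage flux.

Adsorption uses a generalized isotherm s = Kd * c**beta (liquid c in
ug cm-3 water, s in ug g-1 soil); the default is linear (beta = 1) with
Kd > 0 for ammonium only. Concentration source/sink terms phi from the
nitrogen transformations are supplied per bulk soil volume (ug cm-3 d-1).

Unit conventions: 1 kg N ha-1 = 10 ug cm-2 of column cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .soil_water import SoilGrid, _thomas

__all__ = [
    "SoluteSpecies",
    "DispersionSpec",
    "dispersion_coefficient",
    "cde_step",
    "KG_HA_TO_UG_CM2",
]

KG_HA_TO_UG_CM2 = 10.0  # 1 kg ha-1 = 1e9 ug / 1e8 cm2


@dataclass
class SoluteSpecies:
    """One transported nitrogen species on the water grid.

    conc : liquid-phase concentration per node (ug N cm-3 of solution)
    d0 : molecular diffusion coefficient in free water (cm2 d-1)
    kd : adsorption distribution coefficient (cm3 g-1); nitrate and urea
        default to zero (transported unadsorbed)
    beta : isotherm nonlinearity exponent (1 = linear)
    """

    name: str
    conc: np.ndarray
    d0: float
    kd: float = 0.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in ("urea", "ammonium", "nitrate"):
            raise ValueError(f"unknown species {self.name!r}")
        self.conc = np.asarray(self.conc, dtype=float)
        if np.any(self.conc < 0.0):
            raise ValueError("concentrations must be >= 0")

    def sorbed(self, c: np.ndarray | None = None) -> np.ndarray:
        c = self.conc if c is None else c
        if self.kd == 0.0:
            return np.zeros_like(c)
        return self.kd * np.power(np.clip(c, 0.0, None), self.beta)

    def bulk_concentration(self, grid: SoilGrid) -> np.ndarray:
        """Total (liquid + adsorbed) N per bulk soil volume (ug cm-3)."""
        return grid.theta * self.conc + grid.bulk_density * self.sorbed()

    def column_mass(self, grid: SoilGrid) -> float:
        """Total column N (kg N ha-1)."""
        return float(np.sum(self.bulk_concentration(grid)) * grid.dz
                     / KG_HA_TO_UG_CM2)

    def add_bulk_mass(self, grid: SoilGrid, added: np.ndarray) -> None:
        """Add mass (ug N per cm3 bulk soil, per node) and re-equilibrate.

        The isotherm is preserved: new liquid concentration solves
        theta*c + rho_b*Kd*c**beta = previous total + added.
        """
        total = self.bulk_concentration(grid) + np.asarray(added, dtype=float)
        if np.any(total < -1e-9):
            raise ValueError("mass removal exceeds available solute")
        self.conc = _liquid_from_total(np.clip(total, 0.0, None), grid, self)


def _liquid_from_total(total: np.ndarray, grid: SoilGrid,
                       species: SoluteSpecies) -> np.ndarray:
    if species.kd == 0.0:
        return total / grid.theta
    rbkd = grid.bulk_density * species.kd
    if species.beta == 1.0:
        return total / (grid.theta + rbkd)
    # Newton iteration on theta*c + rbkd*c^beta - total = 0
    c = total / (grid.theta + rbkd)
    for _ in range(50):
        f = grid.theta * c + rbkd * np.power(c, species.beta) - total
        fp = grid.theta + rbkd * species.beta * np.power(
            np.clip(c, 1e-30, None), species.beta - 1.0)
        step = f / fp
        c = np.clip(c - step, 0.0, None)
        if np.max(np.abs(step)) < 1e-12:
            break
    return c


@dataclass(frozen=True)
class DispersionSpec:
    """Hydrodynamic dispersion settings (longitudinal dispersivity in cm)."""

    dispersivity: float = 3.0

    def __post_init__(self) -> None:
        if self.dispersivity < 0.0:
            raise ValueError("dispersivity must be >= 0")


def dispersion_coefficient(theta, theta_s, q, d0: float,
                           dispersivity: float = 3.0):
    """Hydrodynamic dispersion coefficient D_sh (cm2 d-1).

    D_sh = D0 * tau + D_L * |q| / theta with the Millington-Quirk
    tortuosity tau = theta^(7/3) / theta_s^2.
    """
    theta = np.asarray(theta, dtype=float)
    theta_s = np.asarray(theta_s, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(theta <= 0.0):
        raise ValueError("theta must be positive")
    tau = theta ** (7.0 / 3.0) / theta_s**2
    D = d0 * tau + dispersivity * np.abs(q) / theta
    return D if D.ndim else float(D)


def cde_step(grid: SoilGrid, species: SoluteSpecies,
             water_fluxes: np.ndarray, theta_old: np.ndarray, dt: float,
             sink_source_profile: np.ndarray | None = None,
             top_solute_concentration: float = 0.0,
             dispersion: DispersionSpec = DispersionSpec(),
             theta_new: np.ndarray | None = None) -> dict:
    """Advance one species through one implicit transport step.

    Parameters
    ----------
    water_fluxes : face Darcy fluxes (n+1 values, cm d-1, positive down)
        from the same sub-step's Richards solution.
    theta_old : water contents before that Richards step; ``grid.theta``
        holds the new ones.
    sink_source_profile : transformation source (+) / sink (-) per node in
        ug N cm-3 bulk soil d-1, applied as an explicit term.
    top_solute_concentration : concentration of the infiltrating water
        (ug cm-3), e.g. for fertigation (Cauchy inflow boundary).

    Returns dict with ``leaching`` (kg N ha-1 over the step, positive out the
    bottom), ``surface_influx`` (kg N ha-1) and ``mass_error`` (kg N ha-1).
    """
    n = grid.n_nodes
    dz = grid.dz
    q = np.asarray(water_fluxes, dtype=float)
    phi = (np.zeros(n) if sink_source_profile is None
           else np.asarray(sink_source_profile, dtype=float))
    c_old = species.conc.copy()
    theta_old = np.asarray(theta_old, dtype=float)
    theta_new = grid.theta if theta_new is None else np.asarray(theta_new, float)
    mass_old = (theta_old * c_old
                + grid.bulk_density * species.sorbed(c_old))

    # face dispersion from upstream-averaged theta and the face flux
    theta_face = 0.5 * (theta_new[:-1] + theta_new[1:])
    ths_face = 0.5 * (grid.theta_s[:-1] + grid.theta_s[1:])
    D_face = dispersion_coefficient(theta_face, ths_face, q[1:-1], species.d0,
                                    dispersion.dispersivity)
    wd = theta_face * D_face / dz  # dispersive conductance per face

    c = c_old.copy()
    n_picard = 1 if species.beta == 1.0 else 5
    for _ in range(n_picard):
        rbkd_eff = grid.bulk_density * _isotherm_slope(species, c)
        a = np.zeros(n)
        b = (theta_new + rbkd_eff) * dz / dt
        cc = np.zeros(n)
        d = mass_old * dz / dt + phi * dz
        d += (rbkd_eff * c - grid.bulk_density * species.sorbed(c)
              + 0.0) * dz / dt if species.beta != 1.0 else 0.0

        # interior faces: advection upwind + dispersion implicit
        qf = q[1:-1]
        down = qf > 0.0
        b[:-1] += np.where(down, qf, 0.0) + wd
        cc[:-1] += np.where(down, 0.0, qf) - wd
        a[1:] += -np.where(down, qf, 0.0) - wd
        b[1:] += -np.where(down, 0.0, qf) + wd

        # top Cauchy: inflow at prescribed concentration, no dispersive flux
        influx_rate = max(q[0], 0.0) * top_solute_concentration
        d[0] += influx_rate
        if q[0] < 0.0:
            pass  # evaporation carries no solute out

        # bottom Cauchy: advective outflow at node concentration
        if q[-1] > 0.0:
            b[-1] += q[-1]
        # upward inflow from below is assumed solute-free

        c = _thomas(a, b, cc, d)

    # The transport operator itself is monotone; explicit transformation
    # sinks evaluated at day-start concentrations can undershoot zero by a
    # rounding-level amount once transport has moved mass within the day.
    # Tolerate and clip only that; anything larger is a genuine bug.
    scale = max(1.0, float(np.max(np.abs(c_old))))
    if np.min(c) < -1e-3 * scale:
        raise RuntimeError(
            f"{species.name}: negative concentration {np.min(c):.3e} "
            "after transport step (scheme should be positivity preserving)")
    clipped = float(np.sum(np.clip(-c, 0.0, None) * theta_new) * dz)
    c = np.clip(c, 0.0, None)

    mass_new = theta_new * c + grid.bulk_density * species.sorbed(c)
    leach_rate = q[-1] * c[-1] if q[-1] > 0.0 else 0.0
    d_mass = float(np.sum(mass_new - mass_old) * dz)
    balance = (influx_rate - leach_rate) * dt + float(np.sum(phi) * dz * dt)
    species.conc = c
    return {
        "leaching": leach_rate * dt / KG_HA_TO_UG_CM2,
        "surface_influx": influx_rate * dt / KG_HA_TO_UG_CM2,
        "mass_error": (d_mass - balance) / KG_HA_TO_UG_CM2,
        "clipped": clipped / KG_HA_TO_UG_CM2,
    }


def _isotherm_slope(species: SoluteSpecies, c: np.ndarray) -> np.ndarray:
    if species.kd == 0.0:
        return np.zeros_like(c)
    if species.beta == 1.0:
        return np.full_like(c, species.kd)
    return species.kd * species.beta * np.power(
        np.clip(c, 1e-30, None), species.beta - 1.0)


# ---------------------------------------------------------------------------
# Fertilizer placement
# ---------------------------------------------------------------------------

def band_weights(grid: SoilGrid, z_top: float, z_bottom: float) -> np.ndarray:
    """Fraction of a uniform [z_top, z_bottom] application received by each
    node cell (sums to 1)."""
    if z_bottom <= z_top:
        raise ValueError("band bottom must be below band top")
    lo = grid.z - grid.dz / 2.0
    hi = grid.z + grid.dz / 2.0
    overlap = np.clip(np.minimum(hi, z_bottom) - np.maximum(lo, z_top),
                      0.0, None)
    total = overlap.sum()
    if total <= 0.0:
        raise ValueError("application band lies outside the profile")
    return overlap / total

FERTILIZER_METHODS = ("surface", "deep", "mix", "fertigation")
MINERAL_FORMS = ("urea", "ammonium", "nitrate")
ORGANIC_FORMS = ("manure", "straw")


def apply_fertilizer(event, grid: SoilGrid, species: dict,
                     pools=None, irrigation_mm: float = 0.0,
                     deep_band: tuple[float, float] = (5.0, 10.0),
                     plough_depth: float = 20.0,
                     carbon_fraction: float = 0.45) -> dict:
    """Place a fertilization/amendment event into the profile.

    Methods: ``surface`` incorporates uniformly into the top 1 cm; ``deep``
    into the configured band (default 5-10 cm); ``mix`` through the plough
    layer; ``fertigation`` dissolves the amount in the day's irrigation
    water (requires irrigation that day) and is returned as a surface-water
    concentration for the transport boundary instead of being placed.

    Mineral forms go to their solute species; ``manure``/``straw`` go to
    the added-organic-matter pools with the event's C/N ratio (event amount
    is kg N ha-1; carbon is N * C/N, converted with the dry-matter carbon
    fraction only for bookkeeping of amendment mass elsewhere).

    Returns dict with ``fertigation_concentration`` (ug N cm-3 of
    irrigation water, 0 unless fertigation) and ``n_added`` (kg N ha-1).
    """
    method = getattr(event, "method", "surface") or "surface"
    form = getattr(event, "form", "ammonium") or "ammonium"
    amount = float(event.amount)  # kg N ha-1
    if amount < 0.0:
        raise ValueError("fertilizer amount must be >= 0")
    if method not in FERTILIZER_METHODS:
        raise ValueError(f"unknown fertilization method {method!r}")
    if amount == 0.0:
        return {"fertigation_concentration": 0.0, "n_added": 0.0}

    if form in ORGANIC_FORMS:
        if pools is None:
            raise ValueError("organic amendment requires pool state")
        cn = float(getattr(event, "cn_ratio", None) or
                   (15.0 if form == "manure" else 80.0))
        depth = float(getattr(event, "incorporation_depth", None)
                      or plough_depth)
        w = band_weights(grid, 0.0, depth)
        carbon_bulk = amount * cn * KG_HA_TO_UG_CM2 * w / grid.dz
        nodes = np.nonzero(w > 0.0)[0]
        pools.add_aom(nodes, carbon_bulk[nodes], cn_ratio=cn,
                      fast_fraction=0.8 if form == "manure" else 0.5)
        return {"fertigation_concentration": 0.0, "n_added": amount,
                "c_added": amount * cn}

    if form not in MINERAL_FORMS:
        raise ValueError(f"unknown fertilizer form {form!r}")
    target = species[form]

    if method == "fertigation":
        if irrigation_mm <= 0.0:
            raise ValueError("fertigation requires same-day irrigation")
        # kg ha-1 dissolved in irrigation_mm of water:
        # ug cm-2 / (0.1 cm mm-1 * mm) of water depth
        conc = amount * KG_HA_TO_UG_CM2 / (irrigation_mm * 0.1)
        return {"fertigation_concentration": conc, "n_added": amount}

    if method == "surface":
        band = (0.0, 1.0)
    elif method == "deep":
        band = deep_band
    else:  # mix
        band = (0.0, plough_depth)
    w = band_weights(grid, *band)
    added_bulk = amount * KG_HA_TO_UG_CM2 * w / grid.dz
    target.add_bulk_mass(grid, added_bulk)
    return {"fertigation_concentration": 0.0, "n_added": amount}
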