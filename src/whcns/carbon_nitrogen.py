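"""Soil organic matter turnover and inorganic nitrogen transformations.

Organic matter is split into six pools in the DAISY tradition: native soil
organic matter (SOM1 slow, SOM2 fast), soil microbial biomass (SMB1 slow,
SMB2 fast) and added organic matter (AOM1 slow, AOM2 fast). Every pool
decays by first-order kinetics, zeta_p = k_p * C_p, with the actual rate
coefficient obtained from the standard-condition coefficient multiplied by
abiotic modifiers (temperature and moisture for all pools, clay protection
for native SOM). Decomposition fluxes are routed to the microbial pools
with a substrate-utilisation efficiency below one; the remainder evolves as
CO2. Microbial death returns carbon to SOM2. Net N mineralization follows
from the C/N bookkeeping of all fluxes; a negative net rate (immobilization)
is capped at the mineral N actually available by scaling the whole
turnover step down proportionally.

Inorganic transformations: first-order urea hydrolysis scaled by
water-filled pore space; ammonia volatilization driven by the
temperature-dependent NH3/NH4+ equilibrium fraction and confined to a
shallow surface zone; Michaelis-Menten nitrification with temperature and
moisture modifiers; and denitrification proportional to the CO2 evolution
rate (potential rate alpha_d * S_CO2), throttled by a moisture function and
capped at K_d times the nitrate pool.

Units: concentrations ug cm-3 bulk soil, rates ug cm-3 d-1, temperatures
deg C, pressure head cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "POOLS",
    "PoolState",
    "TurnoverParams",
    "InorganicNParams",
    "modifier_temperature",
    "modifier_pressure_head",
    "modifier_clay",
    "turnover_step",
    "urea_hydrolysis",
    "ammonia_volatilization",
    "nitrification",
    "denitrification",
    "nitrification_modifier_temperature",
    "nitrification_modifier_head",
    "denitrification_modifier_theta",
]

POOLS = ("SOM1", "SOM2", "SMB1", "SMB2", "AOM1", "AOM2")

# Carbon routing: each pool's decomposition flux feeds one target pool at
# the given efficiency; the remainder is respired as CO2. Microbial death
# (the d* share of the SMB rate) transfers to SOM2 without respiration loss.
ROUTING = {
    "SOM1": "SMB1",
    "SOM2": "SMB1",
    "AOM1": "SMB1",
    "AOM2": "SMB2",
    "SMB1": "SOM2",
    "SMB2": "SOM2",
}


@dataclass
class TurnoverParams:
    """Standard-condition rate coefficients (d-1) and routing constants.

    Defaults follow the published DAISY parameterisation: very slow native
    SOM1, faster SOM2, microbial pools with separate death and maintenance
    coefficients, and added-organic-matter pools turning over in months
    (AOM1) to weeks (AOM2). Substrate-utilisation efficiency applies to all
    decomposition fluxes entering microbial biomass.
    """

    k_som1: float = 2.7e-6
    k_som2: float = 1.4e-4
    death_smb1: float = 1.85e-4
    maint_smb1: float = 1.8e-3
    death_smb2: float = 1.0e-2
    maint_smb2: float = 1.0e-2
    k_aom1: float = 5.0e-3
    k_aom2: float = 5.0e-2
    efficiency: float = 0.60
    cn_smb: float = 6.7
    cn_som: float = 11.0
    temperature_optimum: float = 20.0
    clay_protection_slope: float = 2.0
    clay_protection_floor: float = 0.2

    def rate(self, pool: str) -> float:
        return {
            "SOM1": self.k_som1, "SOM2": self.k_som2,
            "SMB1": self.death_smb1 + self.maint_smb1,
            "SMB2": self.death_smb2 + self.maint_smb2,
            "AOM1": self.k_aom1, "AOM2": self.k_aom2,
        }[pool]

    def death_fraction(self, pool: str) -> float:
        """Share of the SMB rate that is death (transfer) vs maintenance."""
        if pool == "SMB1":
            return self.death_smb1 / (self.death_smb1 + self.maint_smb1)
        if pool == "SMB2":
            return self.death_smb2 / (self.death_smb2 + self.maint_smb2)
        return 0.0


@dataclass
class InorganicNParams:
    """Inorganic N kinetics.

    vn_star : maximum nitrification rate (ug cm-3 d-1)
    kn : nitrification half-saturation constant (ug cm-3)
    kd : denitrification proportionality cap (d-1)
    alpha_d : potential denitrification per unit CO2-C evolution
        (g gas-N per g CO2-C)
    k_urea : urea hydrolysis rate constant (d-1)
    k_vol : surface volatilization rate scale (d-1)
    vol_depth : depth (cm) below which no volatilization occurs
    """

    vn_star: float = 5.0
    kn: float = 50.0
    kd: float = 0.1
    alpha_d: float = 0.1
    k_urea: float = 0.4
    k_vol: float = 2.0
    vol_depth: float = 10.0


@dataclass
class PoolState:
    """Carbon mass and C/N ratio of the six organic pools per node.

    carbon : array (6, n_nodes), ug C per cm3 bulk soil
    cn : array (6, n_nodes), C/N ratio of each pool
    """

    carbon: np.ndarray
    cn: np.ndarray

    @classmethod
    def from_soc(cls, n_nodes: int, soc_percent: np.ndarray,
                 bulk_density: np.ndarray, params: TurnoverParams,
                 fractions: dict[str, float] | None = None) -> "PoolState":
        """Initialise native pools from soil organic carbon content (%)."""
        fr = {"SOM1": 0.80, "SOM2": 0.18, "SMB1": 0.015, "SMB2": 0.005,
              "AOM1": 0.0, "AOM2": 0.0}
        if fractions:
            fr.update(fractions)
        total = (np.broadcast_to(np.asarray(soc_percent, float), (n_nodes,))
                 / 100.0 * np.asarray(bulk_density, float) * 1.0e6)
        carbon = np.zeros((len(POOLS), n_nodes))
        cn = np.ones((len(POOLS), n_nodes))
        for i, p in enumerate(POOLS):
            carbon[i] = fr[p] * total
            cn[i] = params.cn_smb if p.startswith("SMB") else params.cn_som
        return cls(carbon, cn)

    def index(self, pool: str) -> int:
        return POOLS.index(pool)

    def total_carbon(self) -> np.ndarray:
        return self.carbon.sum(axis=0)

    def total_nitrogen(self) -> np.ndarray:
        return (self.carbon / self.cn).sum(axis=0)

    def column_totals(self, dz: float) -> tuple[float, float]:
        """(C, N) column totals in kg ha-1 (1 ug cm-2 = 0.1 kg ha-1)."""
        return (float(self.total_carbon().sum() * dz / 10.0),
                float(self.total_nitrogen().sum() * dz / 10.0))

    def add_aom(self, nodes: np.ndarray, carbon_added: np.ndarray,
                cn_ratio: float, fast_fraction: float = 0.5) -> None:
        """Add fresh organic matter (ug C cm-3 per listed node).

        Carbon is split between AOM1 (slow) and AOM2 (fast); the pool C/N
        is the mass-weighted mean of old and added material.
        """
        for pool, frac in (("AOM1", 1.0 - fast_fraction),
                           ("AOM2", fast_fraction)):
            i = self.index(pool)
            add_c = frac * np.asarray(carbon_added, float)
            old_c = self.carbon[i, nodes]
            old_n = old_c / self.cn[i, nodes]
            new_n = old_n + add_c / cn_ratio
            self.carbon[i, nodes] = old_c + add_c
            with np.errstate(divide="ignore", invalid="ignore"):
                self.cn[i, nodes] = np.where(
                    new_n > 0.0, (old_c + add_c) / new_n, cn_ratio)


# ---------------------------------------------------------------------------
# Abiotic rate modifiers (all in [0, 1])
# ---------------------------------------------------------------------------

def modifier_temperature(t, optimum: float = 20.0):
    """Turnover temperature function: 0 at/below 0 C, linear to 1 at the
    optimum, capped at 1 above it."""
    t = np.asarray(t, dtype=float)
    f = np.clip(t / optimum, 0.0, 1.0)
    f = np.where(t <= 0.0, 0.0, f)
    return f if f.ndim else float(f)


def modifier_pressure_head(h):
    """Turnover moisture function of pressure head, peaking near field
    capacity (pF 1.5-2.5), reduced when saturated (poor aeration) and
    falling to zero in air-dry soil (pF 6.5)."""
    h = np.asarray(h, dtype=float)
    pf = np.where(h < -1e-12, np.log10(np.clip(-h, 1e-12, None)), -np.inf)
    f = np.empty_like(pf)
    f = np.where(pf <= 1.0, 0.6, 1.0)
    rise = (pf > 1.0) & (pf < 1.5)
    f = np.where(rise, 0.6 + 0.4 * (pf - 1.0) / 0.5, f)
    fall = (pf > 2.5) & (pf < 6.5)
    f = np.where(fall, 1.0 - (pf - 2.5) / 4.0, f)
    f = np.where(pf >= 6.5, 0.0, f)
    return f if f.ndim else float(f)


def modifier_clay(clay_fraction, slope: float = 2.0, floor: float = 0.2):
    """Clay protection of native SOM: 1 in sand, decreasing linearly with
    clay fraction down to a floor."""
    clay = np.asarray(clay_fraction, dtype=float)
    f = np.clip(1.0 - slope * clay, floor, 1.0)
    return f if f.ndim else float(f)


def nitrification_modifier_temperature(t):
    """Nitrifier activity: zero at/below 0 C, optimum plateau 25-35 C,
    suppressed above 45 C."""
    t = np.asarray(t, dtype=float)
    f = np.clip(t / 25.0, 0.0, 1.0)
    f = np.where(t > 35.0, np.clip(1.0 - (t - 35.0) / 10.0, 0.0, 1.0), f)
    f = np.where(t <= 0.0, 0.0, f)
    return f if f.ndim else float(f)


def nitrification_modifier_head(h):
    """Nitrification moisture response: strongly reduced in saturated soil
    (oxygen limitation), optimal near field capacity, zero when air-dry."""
    h = np.asarray(h, dtype=float)
    pf = np.where(h < -1e-12, np.log10(np.clip(-h, 1e-12, None)), -np.inf)
    f = np.where(pf <= 1.0, 0.2, 1.0)
    rise = (pf > 1.0) & (pf < 1.7)
    f = np.where(rise, 0.2 + 0.8 * (pf - 1.0) / 0.7, f)
    fall = (pf > 2.5) & (pf < 6.0)
    f = np.where(fall, 1.0 - (pf - 2.5) / 3.5, f)
    f = np.where(pf >= 6.0, 0.0, f)
    return f if f.ndim else float(f)


def denitrification_modifier_theta(theta, theta_s, wfps_threshold: float = 0.7):
    """Anaerobiosis factor: zero below a water-filled-pore-space threshold,
    rising quadratically to 1 at saturation."""
    wfps = np.asarray(theta, dtype=float) / np.asarray(theta_s, dtype=float)
    x = np.clip((wfps - wfps_threshold) / (1.0 - wfps_threshold), 0.0, 1.0)
    f = x**2
    return f if f.ndim else float(f)


# ---------------------------------------------------------------------------
# Organic turnover
# ---------------------------------------------------------------------------

def turnover_step(pools: PoolState, temperature, head, clay_fraction,
                  dt: float, params: TurnoverParams | None = None,
                  mineral_n_available: np.ndarray | None = None,
                  active: np.ndarray | None = None) -> dict:
    """Advance all six pools by ``dt`` days.

    temperature, head, clay_fraction : per-node arrays (or scalars).
    mineral_n_available : mineral N (ug cm-3) that immobilization may draw
        on; when the step's net demand exceeds it, all fluxes are scaled
        down proportionally.
    active : boolean node mask of the microbially active zone (default all).

    Returns dict with per-node ``co2`` (ug C cm-3 evolved over the step),
    ``s_min`` (net N mineralization, ug N cm-3 over the step, negative =
    immobilization) and the ``scaling`` factor applied (1 = uncapped).
    """
    if params is None:
        params = TurnoverParams()
    n = pools.carbon.shape[1]
    T = np.broadcast_to(np.asarray(temperature, float), (n,))
    h = np.broadcast_to(np.asarray(head, float), (n,))
    clay = np.broadcast_to(np.asarray(clay_fraction, float), (n,))
    mask = np.ones(n, bool) if active is None else np.asarray(active, bool)

    f_T = modifier_temperature(T, params.temperature_optimum)
    f_h = modifier_pressure_head(h)
    f_clay = modifier_clay(clay, params.clay_protection_slope,
                           params.clay_protection_floor)

    # actual first-order coefficients per pool per node
    k = np.zeros((len(POOLS), n))
    for i, p in enumerate(POOLS):
        mod = f_T * f_h
        if p.startswith("SOM"):
            mod = mod * f_clay
        k[i] = params.rate(p) * mod
    k[:, ~mask] = 0.0

    # exponential within-step decay so pure decay is exact
    outflux = pools.carbon * (1.0 - np.exp(-k * dt))

    influx = np.zeros_like(outflux)
    co2 = np.zeros(n)
    n_release = np.zeros(n)
    n_demand = np.zeros(n)
    for i, p in enumerate(POOLS):
        target = ROUTING[p]
        j = pools.index(target)
        if p.startswith("SMB"):
            # death share transfers to SOM2; maintenance share respires
            fd = params.death_fraction(p)
            transfer = fd * outflux[i]
            co2 += (1.0 - fd) * outflux[i]
            influx[j] += transfer
            n_demand += transfer / pools.cn[j]
        else:
            co2 += (1.0 - params.efficiency) * outflux[i]
            influx[j] += params.efficiency * outflux[i]
            n_demand += params.efficiency * outflux[i] / pools.cn[j]
        n_release += outflux[i] / pools.cn[i]

    s_min = n_release - n_demand

    scaling = np.ones(n)
    if mineral_n_available is not None:
        avail = np.asarray(mineral_n_available, float)
        deficit = -s_min - avail
        need = -s_min
        over = (s_min < 0.0) & (deficit > 0.0)
        scaling = np.where(over, np.clip(avail / np.where(need > 0, need, 1.0),
                                         0.0, 1.0), 1.0)
        outflux = outflux * scaling
        influx = influx * scaling
        co2 = co2 * scaling
        s_min = s_min * scaling

    pools.carbon = pools.carbon - outflux + influx
    return {"co2": co2, "s_min": s_min, "scaling": scaling}


# ---------------------------------------------------------------------------
# Inorganic N transformations
# ---------------------------------------------------------------------------

def urea_hydrolysis(n_urea, wfps, k_urea: float = 0.4, dt: float = 1.0):
    """First-order urea hydrolysis scaled by water-filled pore space.

    Returns the amount converted to ammonium over ``dt`` (same units as
    ``n_urea``); with constant WFPS = 1 the urea pool decays as
    exp(-k_urea * t).
    """
    n_urea = np.asarray(n_urea, dtype=float)
    wfps = np.clip(np.asarray(wfps, dtype=float), 0.0, 1.0)
    delta = n_urea * (1.0 - np.exp(-k_urea * wfps * dt))
    return delta if delta.ndim else float(delta)


def _nh3_fraction(pH, t):
    """Equilibrium NH3 fraction of total ammoniacal N (Emerson pKa)."""
    pka = 0.09018 + 2729.92 / (np.asarray(t, float) + 273.15)
    return 1.0 / (1.0 + 10.0 ** (pka - np.asarray(pH, float)))


def ammonia_volatilization(n_am, pH, t, depth, dt: float = 1.0,
                           params: InorganicNParams | None = None):
    """Ammonia loss (same units as ``n_am``) over ``dt``.

    The rate is k_vol times the equilibrium NH3 fraction (increasing with
    pH and temperature) times a depth attenuation that falls linearly to
    zero at ``vol_depth``; the loss never exceeds the ammonium present.
    """
    if params is None:
        params = InorganicNParams()
    n_am = np.asarray(n_am, dtype=float)
    fz = np.clip(1.0 - np.asarray(depth, float) / params.vol_depth, 0.0, 1.0)
    rate = params.k_vol * _nh3_fraction(pH, t) * fz
    delta = n_am * (1.0 - np.exp(-rate * dt))
    return delta if delta.ndim else float(delta)


def nitrification(n_am, t, h, params: InorganicNParams | None = None,
                  dt: float = 1.0):
    """Michaelis-Menten NH4 -> NO3 conversion over ``dt``.

    rate = Vn* * N_am / (Kn + N_am) * Fn(T) * Fn(h), capped at the
    ammonium present.
    """
    if params is None:
        params = InorganicNParams()
    n_am = np.asarray(n_am, dtype=float)
    rate = (params.vn_star * n_am / (params.kn + n_am)
            * nitrification_modifier_temperature(t)
            * nitrification_modifier_head(h))
    delta = np.minimum(rate * dt, n_am)
    return delta if delta.ndim else float(delta)


def denitrification(s_co2, n_ni, theta, theta_s,
                    params: InorganicNParams | None = None, dt: float = 1.0):
    """NO3 -> gaseous N loss over ``dt``.

    The potential rate is alpha_d * S_CO2 (linear in the CO2 evolution
    rate); the actual rate is min(F_d(theta) * potential, K_d * N_ni) and
    never exceeds the nitrate present.
    """
    if params is None:
        params = InorganicNParams()
    n_ni = np.asarray(n_ni, dtype=float)
    potential = params.alpha_d * np.asarray(s_co2, dtype=float)
    actual = np.minimum(denitrification_modifier_theta(theta, theta_s)
                        * potential, params.kd * n_ni)
    delta = np.minimum(actual * dt, n_ni)
    return delta if delta.ndim else float(delta)
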