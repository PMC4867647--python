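"""Generic daily crop growth model.

Development is driven by thermal time in two phases: sowing to emergence
(heat requirement linear in sowing depth) and emergence to maturity (Tsum).
Gross canopy assimilation integrates a saturating leaf light response over
the exponential light profile (extinction coefficient Ke) and is scaled by
the water and nitrogen stress factors; after maintenance and growth
respiration the increment is partitioned to root, leaf, stem and storage
organ with stage-dependent coefficients. LAI follows leaf mass through a
specific leaf area that declines with development. Root depth follows a
Verhulst (logistic) trajectory anchored at (tR_min, xR_min) and
(tR_med, xR_med) with asymptote xR_max, frozen while the crop is dormant
(five consecutive days of sub-zero mean air temperature; growth resumes
after five consecutive days above zero).

Root water uptake uses a Feddes pressure-head stress function with the
compensation mechanism of a critical water-stress index omega_c: when the
root-zone weighted stress index omega reaches omega_c, the full
transpiration demand is met by shifting uptake toward unstressed nodes;
below it, actual transpiration is (omega/omega_c) * Tp. Nitrogen uptake is
the minimum of crop demand and root-zone mineral N, drawn from ammonium
and nitrate in proportion to their availability.

Units: masses kg DM ha-1, N kg N ha-1, depths cm, time d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .evapotranspiration import KcCurve
from .soil_water import SoilGrid

__all__ = [
    "FeddesParams",
    "CropParams",
    "CropState",
    "emergence_requirement",
    "develop",
    "root_depth",
    "root_water_uptake",
    "nitrogen_stress",
    "nitrogen_uptake",
    "grow",
]

CO2_TO_CH2O = 30.0 / 44.0

# default stage-dependent dry matter partition (stage, root, leaf, stem, storage)
DEFAULT_PARTITION = (
    (0.00, 0.50, 0.35, 0.15, 0.00),
    (0.25, 0.30, 0.40, 0.30, 0.00),
    (0.45, 0.15, 0.25, 0.50, 0.10),
    (0.65, 0.05, 0.05, 0.25, 0.65),
    (0.80, 0.00, 0.00, 0.05, 0.95),
    (1.00, 0.00, 0.00, 0.00, 1.00),
)


@dataclass(frozen=True)
class FeddesParams:
    """Pressure-head thresholds (cm) of the root water stress response:
    zero uptake above h1 (anoxia) and below h4 (wilting), optimal between
    h2 and h3."""

    h1: float = -1.0
    h2: float = -25.0
    h3: float = -600.0
    h4: float = -15000.0

    def alpha(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        a = np.zeros_like(h)
        seg1 = (h < self.h1) & (h >= self.h2)
        a = np.where(seg1, (self.h1 - h) / (self.h1 - self.h2), a)
        a = np.where((h < self.h2) & (h >= self.h3), 1.0, a)
        seg3 = (h < self.h3) & (h >= self.h4)
        a = np.where(seg3, (h - self.h4) / (self.h3 - self.h4), a)
        return a


@dataclass(frozen=True)
class CropParams:
    """Parameter set for one crop (see module docstring for the model)."""

    name: str
    tbase: float                 # deg C
    tsum: float                  # deg C d, emergence -> maturity
    ke: float                    # canopy extinction coefficient
    kc: KcCurve
    sla_max: float               # m2 kg-1 at emergence
    sla_min: float               # m2 kg-1 at maturity
    amax: float                  # kg CO2 ha-1 h-1, leaf-level light-saturated
    r_max: float                 # cm, absolute cap on rooting depth
    emergence_a: float = 50.0    # deg C d intercept of the emergence requirement
    emergence_b: float = 10.0    # deg C d per cm sowing depth
    xr_min: float = 5.0          # cm
    xr_med: float = 45.0         # cm
    xr_max: float = 90.0         # cm
    tr_min: float = 0.0          # d after emergence
    tr_med: float = 40.0         # d after emergence
    omega_c: float = 0.5         # critical water stress index
    feddes: FeddesParams = FeddesParams()
    partition: tuple = DEFAULT_PARTITION
    # initial light-use efficiency of the leaf response: ~12 g CO2 per MJ
    # absorbed PAR (quantum-yield scale) = 120 kg CO2 ha-1 h-1 per MJ m-2 h-1
    light_use_eff: float = 120.0
    yg: float = 0.7              # growth conversion efficiency, kg DM / kg CH2O
    maint_coefs: tuple = (0.03, 0.015, 0.010, 0.010)  # leaf, stem, root, storage
    q10: float = 2.0
    nnc_emergence: float = 4.5   # critical N concentration (%) at emergence
    nnc_maturity: float = 1.0    # critical N concentration (%) at maturity
    dilution_rate: float = 3.0   # shape of the exponential dilution curve
    mnc_fraction: float = 0.5    # minimum N concentration as share of critical
    max_uptake_rate: float = 6.0  # kg N ha-1 d-1
    initial_mass: float = 50.0   # kg DM ha-1 at emergence
    stress_combination: str = "min"  # "min" or "product"

    def __post_init__(self) -> None:
        if self.tsum <= 0.0 or self.sla_min > self.sla_max:
            raise ValueError("need Tsum > 0 and SLA_min <= SLA_max")
        if not (self.xr_min <= self.xr_med <= self.xr_max <= self.r_max):
            raise ValueError("root depth anchors must be ordered and <= R_max")
        if not 0.0 < self.omega_c <= 1.0:
            raise ValueError("omega_c must lie in (0, 1]")

    def sla(self, stage: float) -> float:
        s = min(max(stage, 0.0), 1.0)
        return self.sla_max + (self.sla_min - self.sla_max) * s

    def partition_at(self, stage: float) -> np.ndarray:
        """(root, leaf, stem, storage) fractions, normalised to sum 1."""
        tab = np.asarray(self.partition, dtype=float)
        fr = np.array([np.interp(stage, tab[:, 0], tab[:, 1 + k])
                       for k in range(4)])
        total = fr.sum()
        return fr / total if total > 0.0 else np.array([0, 0, 0, 1.0])

    def critical_n(self, stage: float) -> float:
        """Critical (dilution-curve) N concentration, % of dry mass."""
        s = min(max(stage, 0.0), 1.0)
        span = self.nnc_emergence - self.nnc_maturity
        decay = ((math.exp(-self.dilution_rate * s)
                  - math.exp(-self.dilution_rate))
                 / (1.0 - math.exp(-self.dilution_rate)))
        return self.nnc_maturity + span * decay

    def minimum_n(self, stage: float) -> float:
        return self.mnc_fraction * self.critical_n(stage)


@dataclass
class CropState:
    """Prognostic crop variables; stage is 0..1 sowing->emergence mapped to
    [0, 1) and 1..2 emergence->maturity mapped via thermal time."""

    sowing_depth: float = 3.0
    emerged: bool = False
    mature: bool = False
    thermal_time_1: float = 0.0   # deg C d since sowing
    thermal_time_2: float = 0.0   # deg C d since emergence (dormancy excluded)
    days_since_emergence: float = 0.0
    growing_days: float = 0.0     # root-growth clock (dormancy excluded)
    mass: np.ndarray = field(default_factory=lambda: np.zeros(4))  # root, leaf, stem, storage
    lai: float = 0.0
    root_depth_cm: float = 0.0
    n_content: float = 0.0        # kg N ha-1 in the crop
    cf_w: float = 1.0
    cf_n: float = 1.0
    dormant: bool = False
    cold_days: int = 0
    warm_days: int = 0
    yield_kg_ha: float | None = None

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    @property
    def anc_percent(self) -> float:
        """Actual crop N concentration (% of dry mass)."""
        dm = self.total_mass
        return 100.0 * self.n_content / dm if dm > 0.0 else 0.0

    def stage(self, params: CropParams) -> float:
        """Relative development stage in [0, 2]."""
        if not self.emerged:
            req = emergence_requirement(self.sowing_depth,
                                        params.emergence_a, params.emergence_b)
            return min(self.thermal_time_1 / req, 1.0) if req > 0 else 1.0
        return 1.0 + min(self.thermal_time_2 / params.tsum, 1.0)


def emergence_requirement(sowing_depth: float, a: float, b: float) -> float:
    """Thermal-time requirement for emergence, linear in sowing depth."""
    if sowing_depth <= 0.0:
        raise ValueError("sowing depth must be positive")
    return a + b * sowing_depth


def develop(state: CropState, tmean: float, params: CropParams,
            dt: float = 1.0) -> None:
    """Accrue thermal time and update dormancy/emergence/maturity flags."""
    # 5-day dormancy bookkeeping for overwintering crops
    if tmean < 0.0:
        state.cold_days += 1
        state.warm_days = 0
        if state.cold_days >= 5:
            state.dormant = True
    else:
        state.warm_days += 1
        state.cold_days = 0
        if state.warm_days >= 5:
            state.dormant = False

    if state.mature:
        return
    dd = max(tmean - params.tbase, 0.0) * dt
    if not state.emerged:
        state.thermal_time_1 += dd
        req = emergence_requirement(state.sowing_depth, params.emergence_a,
                                    params.emergence_b)
        if state.thermal_time_1 >= req:
            state.emerged = True
            state.mass = params.initial_mass * np.array([0.3, 0.5, 0.2, 0.0])
            state.lai = (state.mass[1] * params.sla(0.0)) * 1e-4
            state.root_depth_cm = params.xr_min
            state.n_content = (params.critical_n(0.0) / 100.0
                               * params.initial_mass)
        return
    state.days_since_emergence += dt
    if not state.dormant:
        state.thermal_time_2 += dd
        state.growing_days += dt
    if state.thermal_time_2 >= params.tsum:
        state.mature = True
        state.yield_kg_ha = float(state.mass[3])


def root_depth(t_growing: float, params: CropParams,
               dormant: bool = False) -> float:
    """Logistic root depth (cm) at root-clock time ``t_growing`` (days of
    active growth since emergence, dormant days excluded).

    Anchored so xR(tR_min) = xR_min and xR(tR_med) = xR_med, approaching
    xR_max; capped at R_max.
    """
    t = max(t_growing, params.tr_min)
    A = params.xr_max / params.xr_min - 1.0
    ratio = A * params.xr_med / (params.xr_max - params.xr_med)
    r = math.log(ratio) / (params.tr_med - params.tr_min)
    xr = params.xr_max / (1.0 + A * math.exp(-r * (t - params.tr_min)))
    return min(xr, params.r_max)


def root_distribution(grid: SoilGrid, root_depth_cm: float) -> np.ndarray:
    """Normalised root density b(z) per node (integral over depth = 1).

    Triangular profile decreasing linearly from the surface to zero at the
    rooting front.
    """
    if root_depth_cm <= 0.0:
        return np.zeros(grid.n_nodes)
    b = np.clip(1.0 - grid.z / root_depth_cm, 0.0, None)
    total = b.sum() * grid.dz
    return b / total if total > 0.0 else b


def root_water_uptake(tp_cm: float, grid: SoilGrid, root_depth_cm: float,
                      feddes: FeddesParams = FeddesParams(),
                      omega_c: float = 0.5):
    """Compensated root water uptake.

    Returns (Ta in cm d-1, per-node volumetric sink in d-1, cf_w).
    """
    if tp_cm < 0.0:
        raise ValueError("Tp must be >= 0")
    if root_depth_cm <= 0.0 or tp_cm == 0.0:
        return 0.0, np.zeros(grid.n_nodes), 1.0 if tp_cm == 0.0 else 0.0
    b = root_distribution(grid, root_depth_cm)
    aw = feddes.alpha(grid.h)
    weighted = aw * b
    omega = float(weighted.sum() * grid.dz)  # uncompensated Ta / Tp
    if omega <= 0.0:
        return 0.0, np.zeros(grid.n_nodes), 0.0
    ta = tp_cm if omega >= omega_c else (omega / omega_c) * tp_cm
    sink = ta * weighted / (weighted.sum() * grid.dz)
    cf_w = ta / tp_cm
    return float(ta), sink, float(cf_w)


def nitrogen_stress(anc: float, nnc: float, mnc: float) -> float:
    """CERES-style N stress factor from actual/critical/minimum N
    concentrations (%), clamped to [0, 1]."""
    if mnc >= nnc:
        raise ValueError("need minimum N concentration < critical")
    return min(max((anc - mnc) / (nnc - mnc), 0.0), 1.0)


def nitrogen_uptake(demand_kg_ha: float, grid: SoilGrid,
                    nh4_bulk: np.ndarray, no3_bulk: np.ndarray,
                    root_depth_cm: float):
    """Actual N uptake = min(demand, root-zone mineral N).

    nh4_bulk / no3_bulk : mineral N per bulk soil volume (ug cm-3).
    Uptake is distributed over nodes proportionally to root density times
    total mineral concentration, capped at each node's stock, and split
    between ammonium and nitrate in proportion to availability.

    Returns (uptake_kg_ha, d_nh4, d_no3) with the removals in ug cm-3.
    """
    if demand_kg_ha < 0.0:
        raise ValueError("demand must be >= 0")
    n = grid.n_nodes
    d_nh4 = np.zeros(n)
    d_no3 = np.zeros(n)
    if demand_kg_ha == 0.0 or root_depth_cm <= 0.0:
        return 0.0, d_nh4, d_no3
    b = root_distribution(grid, root_depth_cm)
    total_bulk = np.clip(nh4_bulk, 0.0, None) + np.clip(no3_bulk, 0.0, None)
    in_zone = b > 0.0
    available = float(total_bulk[in_zone].sum() * grid.dz / 10.0)  # kg ha-1
    uptake = min(demand_kg_ha, available)
    if uptake <= 0.0:
        return 0.0, d_nh4, d_no3
    weights = b * total_bulk
    remaining = uptake * 10.0  # ug cm-2
    removal = np.zeros(n)
    for _ in range(20):
        wsum = weights.sum()
        if wsum <= 0.0 or remaining <= 1e-12:
            break
        want = remaining * weights / wsum / grid.dz  # ug cm-3
        take = np.minimum(want, total_bulk - removal)
        removal += take
        remaining -= float(take.sum() * grid.dz)
        weights = np.where(total_bulk - removal <= 1e-12, 0.0, weights)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_nh4 = np.where(total_bulk > 0.0,
                            np.clip(nh4_bulk, 0.0, None) / total_bulk, 0.0)
    d_nh4 = removal * frac_nh4
    d_no3 = removal - d_nh4
    actual = uptake - remaining / 10.0
    return float(actual), d_nh4, d_no3


def gross_assimilation(params: CropParams, lai: float, radiation: float,
                       daylength: float) -> float:
    """Daily gross canopy CO2 assimilation (kg CO2 ha-1 d-1), unstressed.

    Five-point Gauss integration of the saturating leaf light response
    AMAX * (1 - exp(-eff * I_abs / AMAX)) over the canopy light profile
    I_abs(L) = Ke * I0 * exp(-Ke * L), with I0 the mean daytime PAR flux
    (half of global radiation spread over the daylength).
    """
    if lai <= 0.0 or radiation <= 0.0 or daylength <= 0.0:
        return 0.0
    i0 = 0.5 * radiation / daylength  # MJ PAR m-2 h-1
    # 5-point Gauss-Legendre on [0, LAI]
    xg = np.array([0.0469101, 0.2307653, 0.5, 0.7692347, 0.9530899])
    wg = np.array([0.1184634, 0.2393143, 0.2844444, 0.2393143, 0.1184634])
    L = xg * lai
    i_abs = params.ke * i0 * np.exp(-params.ke * L)
    leaf = params.amax * (1.0 - np.exp(-params.light_use_eff * i_abs
                                       / params.amax))
    return float((leaf * wg).sum() * lai * daylength)


def grow(state: CropState, params: CropParams, radiation: float,
         daylength: float, tmean: float, cf_w: float, cf_n: float,
         dt: float = 1.0) -> float:
    """One day of biomass accumulation; returns net growth (kg DM ha-1).

    Gross assimilation is scaled by the combined water/N stress factor,
    converted CO2 -> CH2O, charged maintenance (temperature-dependent Q10)
    and growth respiration, and partitioned by development stage.
    """
    if not state.emerged or state.mature or state.dormant:
        return 0.0
    stress = (min(cf_w, cf_n) if params.stress_combination == "min"
              else cf_w * cf_n)
    stage2 = min(state.thermal_time_2 / params.tsum, 1.0)
    gross_co2 = gross_assimilation(params, state.lai, radiation, daylength)
    gross = gross_co2 * CO2_TO_CH2O * stress
    q10f = params.q10 ** ((tmean - 25.0) / 10.0)
    organs = state.mass[[1, 2, 0, 3]]  # leaf, stem, root, storage order
    maintenance = float((np.asarray(params.maint_coefs) * organs).sum()) * q10f
    net = max(gross - maintenance, 0.0) * params.yg * dt
    fr_root, fr_leaf, fr_stem, fr_storage = params.partition_at(stage2)
    state.mass = state.mass + net * np.array(
        [fr_root, fr_leaf, fr_stem, fr_storage])
    state.lai = state.mass[1] * params.sla(stage2) * 1e-4
    state.cf_w, state.cf_n = cf_w, cf_n
    return net
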