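"""Model evaluation statistics and a one-at-a-time sensitivity harness.

The four agreement statistics between a simulated series S and an observed
series O of length n:

    ME   = mean(S - O)                        (bias, units of the variable)
    RMSE = sqrt(mean((S - O)^2))
    IA   = 1 - sum((S-O)^2) / sum((|S-Obar| + |O-Obar|)^2)   (Willmott, [0,1])
    NSE  = 1 - sum((S-O)^2) / sum((O-Obar)^2)  (Nash-Sutcliffe, <= 1)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PairedSeries", "mean_bias", "rmse", "index_of_agreement",
           "nash_sutcliffe", "evaluate", "sensitivity_scan"]


@dataclass(frozen=True)
class PairedSeries:
    """Simulated/observed value pairs of one variable."""

    simulated: np.ndarray
    observed: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.simulated, dtype=float)
        o = np.asarray(self.observed, dtype=float)
        if s.shape != o.shape or s.ndim != 1:
            raise ValueError("simulated and observed must be equal-length 1-D")
        object.__setattr__(self, "simulated", s)
        object.__setattr__(self, "observed", o)

    @property
    def n(self) -> int:
        return len(self.observed)


def mean_bias(series: PairedSeries) -> float:
    return float(np.mean(series.simulated - series.observed))


def rmse(series: PairedSeries) -> float:
    return float(np.sqrt(np.mean((series.simulated - series.observed) ** 2)))


def index_of_agreement(series: PairedSeries) -> float:
    if series.n < 2:
        raise ValueError("IA needs at least 2 pairs")
    o_bar = np.mean(series.observed)
    num = np.sum((series.simulated - series.observed) ** 2)
    den = np.sum((np.abs(series.simulated - o_bar)
                  + np.abs(series.observed - o_bar)) ** 2)
    if den == 0.0:
        return 1.0  # all values identical and equal to the mean
    return float(1.0 - num / den)


def nash_sutcliffe(series: PairedSeries) -> float:
    if series.n < 2:
        raise ValueError("NSE needs at least 2 pairs")
    o_bar = np.mean(series.observed)
    den = np.sum((series.observed - o_bar) ** 2)
    if den == 0.0:
        raise ValueError("NSE undefined for zero observed variance")
    num = np.sum((series.simulated - series.observed) ** 2)
    return float(1.0 - num / den)


def evaluate(series: PairedSeries) -> dict:
    """All four statistics for one paired series."""
    return {
        "n": series.n,
        "ME": mean_bias(series),
        "RMSE": rmse(series),
        "IA": index_of_agreement(series),
        "NSE": nash_sutcliffe(series),
    }


def sensitivity_scan(run_fn, base_params: dict[str, float],
                     delta: float = 0.1) -> pd.DataFrame:
    """One-at-a-time +-delta (default +-10%) parameter perturbation scan.

    run_fn(params: dict) -> dict of scalar output variables. Each listed
    parameter is perturbed up and down by ``delta`` relative while all
    others stay at base values; the table reports the signed relative
    change of every output (%), with failed runs flagged.

    Returns a tidy DataFrame with columns parameter, direction, output,
    base_value, perturbed_value, change_percent, failed.
    """
    base_out = run_fn(dict(base_params))
    rows = []
    for name, value in base_params.items():
        for sign, tag in ((1.0, "+10%"), (-1.0, "-10%")):
            params = dict(base_params)
            params[name] = value * (1.0 + sign * delta)
            try:
                out = run_fn(params)
                failed = False
            except Exception:
                out = {k: np.nan for k in base_out}
                failed = True
            for key, base_val in base_out.items():
                pert = out.get(key, np.nan)
                if failed or not np.isfinite(pert):
                    change = np.nan
                elif base_val == 0.0:
                    change = 0.0 if pert == 0.0 else np.inf
                else:
                    change = 100.0 * (pert - base_val) / base_val
                rows.append({
                    "parameter": name,
                    "direction": tag,
                    "output": key,
                    "base_value": base_val,
                    "perturbed_value": pert,
                    "change_percent": change,
                    "failed": failed,
                })
    return pd.DataFrame(rows)
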