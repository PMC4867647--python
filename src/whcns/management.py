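"""Dated management events: sowing, harvest, irrigation, fertilization,
organic amendment, tillage/residue incorporation.

Irrigation supports the eight FAO-56 application methods. In this 1-D
column each method is represented by the area-average applied depth plus a
wetted-fraction multiplier describing how concentrated the local wetting is
(1.0 for full-cover methods; fractional for furrow and trickle variants —
the column total is always conserved), and a flag saying whether the
surface-runoff routine applies to the applied water.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date

__all__ = ["ManagementEvent", "IRRIGATION_METHODS", "apply_irrigation",
           "schedule_check"]

EVENT_KINDS = ("sow", "harvest", "irrigate", "fertilize", "amend", "till")

# method -> (wetted fraction, runoff routine applies)
IRRIGATION_METHODS = {
    "precipitation": (1.0, True),
    "sprinkler": (1.0, False),
    "basin": (1.0, False),
    "border": (1.0, False),
    "furrow_narrow": (0.8, False),
    "furrow_wide": (0.6, False),
    "alternate_furrow": (0.5, False),
    "trickle": (0.3, False),
}


@dataclass(frozen=True)
class ManagementEvent:
    """One dated field operation.

    amount : mm of water (irrigate), kg N ha-1 (fertilize), or kg N ha-1 of
        amendment N (amend; carbon follows from cn_ratio).
    method : irrigation or fertilization method tag (closed vocabularies).
    form : fertilizer form — urea / ammonium / nitrate / manure / straw.
    """

    date: Date
    kind: str
    amount: float = 0.0
    method: str | None = None
    form: str | None = None
    crop: str | None = None
    sowing_depth: float | None = None      # cm
    cn_ratio: float | None = None
    incorporation_depth: float | None = None  # cm

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.amount < 0.0:
            raise ValueError("event amount must be >= 0")
        if self.kind == "irrigate":
            method = self.method or "basin"
            if method not in IRRIGATION_METHODS:
                raise ValueError(f"unknown irrigation method {method!r}")
        if self.kind == "sow" and not self.crop:
            raise ValueError("sow event requires a crop name")


def apply_irrigation(event: ManagementEvent) -> dict:
    """Resolve an irrigation event into surface water supply terms.

    Returns dict with ``supply_mm`` (area-average depth added to the day's
    surface water), ``wetted_fraction``, ``local_depth_mm`` (depth over the
    wetted fraction; total conserved) and ``runoff_applies``.
    """
    if event.kind != "irrigate":
        raise ValueError("not an irrigation event")
    method = event.method or "basin"
    fraction, runoff_applies = IRRIGATION_METHODS[method]
    return {
        "supply_mm": event.amount,
        "wetted_fraction": fraction,
        "local_depth_mm": event.amount / fraction if fraction > 0 else 0.0,
        "runoff_applies": runoff_applies,
    }


def schedule_check(events: list[ManagementEvent],
                   window: tuple[Date, Date] | None = None) -> list[str]:
    """Validate an event plan; raises ValueError on structural errors and
    returns a list of warnings.

    Rejected: unsorted dates, harvest with no preceding sowing, fertigation
    without same-day irrigation. Warned: events outside the simulation
    window.
    """
    warnings: list[str] = []
    last_date = None
    crop_present = False
    irrigation_days = {e.date for e in events
                       if e.kind == "irrigate" and e.amount > 0.0}
    for e in events:
        if last_date is not None and e.date < last_date:
            raise ValueError(f"events not sorted by date at {e.date}")
        last_date = e.date
        if e.kind == "sow":
            if crop_present:
                raise ValueError(f"{e.date}: sowing while a crop is present")
            crop_present = True
        elif e.kind == "harvest":
            if not crop_present:
                raise ValueError(f"{e.date}: harvest before any sowing")
            crop_present = False
        elif e.kind == "fertilize" and e.method == "fertigation":
            if e.date not in irrigation_days:
                raise ValueError(
                    f"{e.date}: fertigation without same-day irrigation")
        if window is not None and not window[0] <= e.date <= window[1]:
            warnings.append(f"{e.date}: {e.kind} outside simulation window")
    return warnings
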