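"""Verdicts of study results against named stability and impurity limits.

Limits covered (all configurable, since pharmacopoeial limits change):

* YCD band — 95-105% of the study compound remaining at the end of the
  sequential scenario (UK NHS protocol for aseptically prepared injectables).
* 10% degradation rule — >= 90% remaining, accepted in some jurisdictions;
  evaluated both at the scenario end and as time-to-threshold.
* Pyridine impurity — 0.5% w/w (BP/EP), 0.4% w/w (USP, sodium carbonate
  formulation), 0.3% w/w (USP, arginine formulation), the former USP
  1.1 mg/mL in-solution maximum, the 2 mg/day permitted daily exposure
  (PDE) and the pragmatic 100 mg/day standard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .delivery import DeliveryResult, pyridine_percent_ww
from .kinetics import ScenarioResult, time_to_threshold


class ComplianceError(ValueError):
    pass


class ComplianceLimits(BaseModel):
    ycd_band: tuple[float, float] = (95.0, 105.0)
    degradation_limit_pct: float = Field(default=10.0, gt=0)
    pyridine_ww_bp_ep_pct: float = Field(default=0.5, gt=0)
    pyridine_ww_usp_carbonate_pct: float = Field(default=0.4, gt=0)
    pyridine_ww_usp_arginine_pct: float = Field(default=0.3, gt=0)
    pyridine_conc_former_usp_mg_per_ml: float = Field(default=1.1, gt=0)
    pyridine_pde_mg_per_day: float = Field(default=2.0, gt=0)
    pyridine_pragmatic_mg_per_day: float = Field(default=100.0, gt=0)

    @model_validator(mode="after")
    def _validate_band(self) -> "ComplianceLimits":
        lo, hi = self.ycd_band
        if not (0 < lo < hi):
            raise ValueError("ycd_band must satisfy 0 < lower < upper")
        return self


Direction = Literal["le", "ge", "within_band"]


def verdict(observed: float, limit, direction: Direction) -> str:
    """Pure pass/fail verdict of an observed value against a limit."""
    if direction == "le":
        return "pass" if observed <= limit else "fail"
    if direction == "ge":
        return "pass" if observed >= limit else "fail"
    if direction == "within_band":
        lo, hi = limit
        return "pass" if lo <= observed <= hi else "fail"
    raise ComplianceError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class ComplianceRow:
    analyte: str
    device: str
    dose_label: str
    limit_name: str
    observed: Optional[float]
    units: str
    limit_value: str
    direction: str
    verdict: str        # pass | fail | not-evaluable
    margin: Optional[float]  # signed distance to the limit; positive = inside


@dataclass(frozen=True)
class ComplianceReport:
    rows: list[ComplianceRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])


def _band_margin(observed: float, band: tuple[float, float]) -> float:
    lo, hi = band
    return min(observed - lo, hi - observed)


def evaluate_limits(
    scenario: ScenarioResult | None,
    delivery: DeliveryResult | None,
    limits: ComplianceLimits,
    ceftazidime_dose_mg: float | None = None,
    max_pyridine_conc_mg_per_ml: float | None = None,
) -> ComplianceReport:
    """Evaluate one (device, dose) study result against every configured limit.

    ``scenario`` is the active-compound percent-remaining scenario (YCD and
    10%-rule verdicts); ``delivery`` the cumulative pyridine delivery (PDE,
    pragmatic and % w/w verdicts); ``max_pyridine_conc_mg_per_ml`` the peak
    in-reservoir pyridine concentration (former USP limit).  A limit whose
    input is missing yields a ``not-evaluable`` row rather than a silent
    drop.
    """
    rows: list[ComplianceRow] = []
    device = (scenario or delivery).device if (scenario or delivery) else "?"
    dose = (scenario or delivery).dose_label if (scenario or delivery) else "?"

    def add(analyte, name, observed, units, limit_value, direction, margin):
        if observed is None:
            rows.append(ComplianceRow(analyte, device, dose, name, None, units,
                                      str(limit_value), direction, "not-evaluable", None))
        else:
            rows.append(ComplianceRow(analyte, device, dose, name, float(observed), units,
                                      str(limit_value), direction,
                                      verdict(observed, limit_value, direction), margin))

    # --- active compound stability -------------------------------------
    if scenario is not None:
        end_pct = scenario.end_percent
        add(scenario.analyte, "ycd_95_105_end_of_scenario", end_pct, "% remaining",
            limits.ycd_band, "within_band", _band_margin(end_pct, limits.ycd_band))
        ten_limit = 100.0 - limits.degradation_limit_pct
        add(scenario.analyte, "degradation_10pct_end_of_running", end_pct, "% remaining",
            ten_limit, "ge", end_pct - ten_limit)
        # time-to-threshold form of the same rule: pass iff the threshold is
        # not crossed before the scenario horizon
        t_cross = time_to_threshold(scenario, ten_limit)
        horizon = scenario.storage_h + scenario.running_h
        rows.append(ComplianceRow(
            scenario.analyte, device, dose, "degradation_10pct_time_to_threshold",
            t_cross if t_cross is not None else horizon, "h (global)",
            f">= {horizon} h (scenario horizon)", "ge",
            "pass" if t_cross is None or t_cross >= horizon else "fail",
            (t_cross - horizon) if t_cross is not None else 0.0,
        ))
    else:
        add("?", "ycd_95_105_end_of_scenario", None, "% remaining", limits.ycd_band, "within_band", None)
        add("?", "degradation_10pct_end_of_running", None, "% remaining",
            100.0 - limits.degradation_limit_pct, "ge", None)

    # --- pyridine impurity ---------------------------------------------
    total = delivery.total_delivered_mg if delivery is not None else None
    add("pyridine", "pde_2mg_daily", total, "mg/day",
        limits.pyridine_pde_mg_per_day, "le",
        None if total is None else limits.pyridine_pde_mg_per_day - total)
    add("pyridine", "pragmatic_100mg_daily", total, "mg/day",
        limits.pyridine_pragmatic_mg_per_day, "le",
        None if total is None else limits.pyridine_pragmatic_mg_per_day - total)

    ww = None
    if total is not None and ceftazidime_dose_mg:
        ww = pyridine_percent_ww(total, ceftazidime_dose_mg)
    for name, lim in (
        ("ww_bp_ep_0.5pct_delivered_over_dose", limits.pyridine_ww_bp_ep_pct),
        ("ww_usp_carbonate_0.4pct_delivered_over_dose", limits.pyridine_ww_usp_carbonate_pct),
        ("ww_usp_arginine_0.3pct_delivered_over_dose", limits.pyridine_ww_usp_arginine_pct),
    ):
        add("pyridine", name, ww, "% w/w", lim, "le", None if ww is None else lim - ww)

    add("pyridine", "former_usp_1.1_mg_per_ml_max_concentration",
        max_pyridine_conc_mg_per_ml, "mg/mL",
        limits.pyridine_conc_former_usp_mg_per_ml, "le",
        None if max_pyridine_conc_mg_per_ml is None
        else limits.pyridine_conc_former_usp_mg_per_ml - max_pyridine_conc_mg_per_ml)

    return ComplianceReport(rows=rows)


def render_report(
    report: ComplianceReport,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("csv", "json"),
) -> list[Path]:
    """Write the compliance report as CSV and/or JSON; deterministic output."""
    supported = {"csv", "json"}
    unknown = set(formats) - supported
    if unknown:
        raise ComplianceError(
            f"unknown format(s) {sorted(unknown)}; supported: {sorted(supported)}"
        )
    if not report.rows:
        raise ComplianceError("empty compliance report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if "csv" in formats:
        path = out_dir / "compliance_report.csv"
        report.to_frame().to_csv(path, index=False)
        written.append(path)
    if "json" in formats:
        path = out_dir / "compliance_report.json"
        path.write_text(json.dumps([asdict(r) for r in report.rows], indent=2))
        written.append(path)
    return written
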