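"""Percent-remaining series, per-phase linear regression, storage-scenario
simulation and time-to-threshold.

The analysis layer deliberately mirrors how sequential-stability studies are
evaluated in practice: concentrations are normalised to 100% at time zero,
each temperature phase gets an ordinary least-squares line
``C_i = a * t_i + b`` on phase-local time, and arbitrary fridge->in-use
storage scenarios are simulated by chaining the fitted slopes into a
continuous piecewise-linear trajectory anchored at 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm


class KineticsError(ValueError):
    pass


@dataclass(frozen=True)
class PercentRemainingSeries:
    """Percent of time-zero concentration over the study, one key."""

    analyte: str
    device: str
    dose_label: str
    points: pd.DataFrame  # columns time_h, phase, percent, sd, n_replicates
    baseline_concentration_mg_per_ml: float
    baseline_rule: str


@dataclass(frozen=True)
class PhaseRegression:
    """OLS line value = slope * t_local + intercept for one
    analyte/device/dose/phase, with t_local in hours since phase start."""

    analyte: str
    device: str
    dose_label: str
    phase: str
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    n_points: int
    residual_sd: float
    scale: str      # "percent" or "concentration"
    time_unit: str = "h"


@dataclass(frozen=True)
class ScenarioResult:
    """Piecewise-linear percent-remaining prediction for a storage scenario."""

    analyte: str
    device: str
    dose_label: str
    storage_h: float
    running_h: float
    storage_slope: float    # %/h
    running_slope: float    # %/h
    threshold_crossings: dict[float, float | None]

    @property
    def handoff_percent(self) -> float:
        return 100.0 + self.storage_slope * self.storage_h

    @property
    def end_percent(self) -> float:
        return self.handoff_percent + self.running_slope * self.running_h

    def percent_at(self, t_global_h: float | np.ndarray) -> np.ndarray | float:
        t = np.asarray(t_global_h, dtype=float)
        storage = 100.0 + self.storage_slope * np.minimum(t, self.storage_h)
        running = self.running_slope * np.clip(t - self.storage_h, 0.0, self.running_h)
        out = storage + running
        return float(out) if np.isscalar(t_global_h) else out

    def trajectory(self, step_h: float = 1.0) -> pd.DataFrame:
        total = self.storage_h + self.running_h
        grid = np.arange(0.0, total + step_h / 2, step_h)
        grid = np.unique(np.append(grid, [self.storage_h, total]))
        return pd.DataFrame({
            "time_h": grid,
            "percent_remaining": self.percent_at(grid),
            "phase": np.where(grid <= self.storage_h, "storage", "running"),
        })


def _mean_duplicates(samples: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Average duplicate aliquots within each replicate device x timepoint."""
    return (
        samples.groupby(
            ["analyte", "device", "dose_label", "replicate", "time_h", "phase"],
            as_index=False, sort=True,
        )[value_col]
        .mean()
    )


def percent_remaining(
    samples: pd.DataFrame,
    baseline_rule: str = "measured_t0",
    value_col: str = "measured_mg_per_ml",
    nominal_by_key: Mapping[tuple[str, str], float] | None = None,
) -> dict[tuple[str, str, str], PercentRemainingSeries]:
    """Percent-remaining series per (analyte, device, dose).

    Duplicates are averaged within each replicate device, each replicate is
    normalised to its own baseline (the earliest timepoint under
    ``baseline_rule="measured_t0"``, or the nominal concentration under
    ``"nominal"``), and the mean and SD are taken across replicate devices.
    Percent at the baseline time is therefore exactly 100 with SD 0 under
    the default rule.
    """
    if baseline_rule not in ("measured_t0", "nominal"):
        raise KineticsError(f"unknown baseline_rule {baseline_rule!r}")
    per_rep = _mean_duplicates(samples, value_col)
    out: dict[tuple[str, str, str], PercentRemainingSeries] = {}
    t0 = per_rep["time_h"].min()
    for (analyte, device, dose), group in per_rep.groupby(
        ["analyte", "device", "dose_label"], sort=True
    ):
        pieces = []
        baselines = []
        for rep, rep_group in group.groupby("replicate", sort=True):
            rep_group = rep_group.sort_values("time_h")
            if baseline_rule == "measured_t0":
                at_t0 = rep_group.loc[rep_group["time_h"] == t0, value_col]
                if at_t0.empty:
                    raise KineticsError(
                        f"missing baseline (t={t0} h) sample for "
                        f"({analyte}, {device}, {dose}, replicate {rep})"
                    )
                baseline = float(at_t0.mean())
            else:
                if nominal_by_key is None:
                    raise KineticsError("nominal baseline_rule needs nominal_by_key")
                baseline = nominal_by_key[(analyte, dose)]
            if baseline <= 0:
                raise KineticsError(
                    f"non-positive baseline for ({analyte}, {device}, {dose})"
                )
            baselines.append(baseline)
            rep_pct = rep_group.assign(percent=100.0 * rep_group[value_col] / baseline)
            pieces.append(rep_pct[["time_h", "phase", "percent"]])
        stacked = pd.concat(pieces)
        points = (
            stacked.groupby(["time_h", "phase"], as_index=False, sort=True)
            .agg(percent=("percent", "mean"), sd=("percent", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0), n_replicates=("percent", "size"))
            .sort_values("time_h", ignore_index=True)
        )
        out[(analyte, device, dose)] = PercentRemainingSeries(
            analyte=analyte,
            device=device,
            dose_label=dose,
            points=points,
            baseline_concentration_mg_per_ml=float(np.mean(baselines)),
            baseline_rule=baseline_rule,
        )
    return out


def fit_phase_regression(
    samples: pd.DataFrame,
    analyte: str,
    device: str,
    dose_label: str,
    phase: str,
    scale: str = "percent",
    phase_start_h: float | None = None,
    value_col: str = "measured_mg_per_ml",
    max_time_h: float | None = None,
) -> PhaseRegression:
    """OLS fit of concentration (or percent of baseline) against phase-local
    time for one analyte/device/dose/phase.

    Duplicates are averaged per replicate device; all replicate points are
    pooled into one regression.  ``phase_start_h`` defaults to the earliest
    sampled time in the phase for that key.  ``max_time_h`` (global hours)
    optionally restricts the fit window.
    """
    if scale not in ("percent", "concentration"):
        raise KineticsError(f"unknown scale {scale!r}")
    per_rep = _mean_duplicates(samples, value_col)
    sel = per_rep[
        (per_rep["analyte"] == analyte)
        & (per_rep["device"] == device)
        & (per_rep["dose_label"] == dose_label)
        & (per_rep["phase"] == phase)
    ].copy()
    if max_time_h is not None:
        sel = sel[sel["time_h"] <= max_time_h]
    if sel.empty:
        raise KineticsError(f"no samples for ({analyte}, {device}, {dose_label}, {phase})")

    if scale == "percent":
        t0 = per_rep["time_h"].min()
        base = per_rep[
            (per_rep["analyte"] == analyte)
            & (per_rep["device"] == device)
            & (per_rep["dose_label"] == dose_label)
            & (per_rep["time_h"] == t0)
        ].set_index("replicate")[value_col]
        if (base <= 0).any():
            raise KineticsError(
                f"non-positive baseline for ({analyte}, {device}, {dose_label}); "
                "fit on the concentration scale instead"
            )
        sel["value"] = [
            100.0 * row[value_col] / base.loc[row["replicate"]]
            for _, row in sel.iterrows()
        ]
    else:
        sel["value"] = sel[value_col]

    if phase_start_h is None:
        phase_start_h = float(sel["time_h"].min())
    sel["t_local"] = sel["time_h"] - phase_start_h

    if sel["time_h"].nunique() < 2:
        raise KineticsError(
            f"need >= 2 distinct timepoints in phase {phase!r}, got {sel['time_h'].nunique()}"
        )
    if np.isclose(sel["t_local"].var(), 0.0):
        raise KineticsError("zero variance in time; cannot fit regression")

    X = sm.add_constant(sel["t_local"].to_numpy())
    # a two-point fit has zero residual degrees of freedom: SEs are undefined
    # (reported as 0) rather than a warning storm
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = sm.OLS(sel["value"].to_numpy(), X).fit()
        intercept, slope = fit.params
        if fit.df_resid > 0:
            intercept_se, slope_se = fit.bse
            resid_sd = float(np.sqrt(fit.scale))
        else:
            intercept_se = slope_se = resid_sd = 0.0
    return PhaseRegression(
        analyte=analyte,
        device=device,
        dose_label=dose_label,
        phase=phase,
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(slope_se),
        intercept_se=float(intercept_se),
        n_points=int(len(sel)),
        residual_sd=resid_sd,
        scale=scale,
    )


def fit_all_regressions(
    samples: pd.DataFrame,
    scale: str = "percent",
    phase_starts: Mapping[str, float] | None = None,
    value_col: str = "measured_mg_per_ml",
) -> dict[tuple[str, str, str, str], PhaseRegression]:
    """Fit every (analyte, device, dose, phase) regression in a dataset."""
    keys = samples[["analyte", "device", "dose_label", "phase"]].drop_duplicates()
    out = {}
    for analyte, device, dose, phase in keys.itertuples(index=False):
        start = phase_starts.get(phase) if phase_starts else None
        out[(analyte, device, dose, phase)] = fit_phase_regression(
            samples, analyte, device, dose, phase,
            scale=scale, phase_start_h=start, value_col=value_col,
        )
    return out


def simulate_scenario(
    fridge_reg: PhaseRegression,
    inuse_reg: PhaseRegression,
    storage_h: float,
    running_h: float,
    thresholds: Iterable[float] = (95.0, 90.0),
) -> ScenarioResult:
    """Predict percent remaining over an arbitrary fridge-then-running
    scenario from the two fitted phase slopes.

    The storage segment anchors at 100% at t = 0 with the fridge slope; the
    running segment continues from the storage-end value with the in-use
    slope (both fitted intercepts are discarded: the observed trajectories
    are continuous, and chaining intercepts would create a jump at the
    handoff).  Threshold crossings are solved analytically on the
    piecewise-linear prediction.
    """
    if fridge_reg.scale != inuse_reg.scale:
        raise KineticsError("both regressions must share a scale")
    if fridge_reg.scale != "percent":
        raise KineticsError("scenario simulation requires percent-scale regressions")
    if storage_h < 0 or running_h < 0:
        raise KineticsError("storage_h and running_h must be >= 0")
    if fridge_reg.slope > 0 or inuse_reg.slope > 0:
        import logging
        logging.getLogger(__name__).warning(
            "positive slope (apparent gain): fridge %.4g, in-use %.4g %%/h",
            fridge_reg.slope, inuse_reg.slope,
        )
    scenario = ScenarioResult(
        analyte=fridge_reg.analyte,
        device=fridge_reg.device,
        dose_label=fridge_reg.dose_label,
        storage_h=storage_h,
        running_h=running_h,
        storage_slope=fridge_reg.slope,
        running_slope=inuse_reg.slope,
        threshold_crossings={},
    )
    crossings = {
        float(thr): time_to_threshold(scenario, float(thr)) for thr in thresholds
    }
    object.__setattr__(scenario, "threshold_crossings", crossings)
    return scenario


def time_to_threshold(scenario: ScenarioResult, threshold: float) -> float | None:
    """Smallest global time at which predicted percent remaining drops to or
    below the threshold; ``None`` if never crossed within the horizon.

    Solved in closed form on the two linear segments.
    """
    if not (0.0 < threshold < 100.0):
        raise KineticsError("threshold must be in (0, 100) percent")
    segments = [
        (0.0, scenario.storage_h, 100.0, scenario.storage_slope),
        (scenario.storage_h, scenario.storage_h + scenario.running_h,
         scenario.handoff_percent, scenario.running_slope),
    ]
    for t_start, t_end, p_start, slope in segments:
        if p_start <= threshold:
            return t_start
        if slope < 0:
            t_cross = t_start + (threshold - p_start) / slope
            if t_cross <= t_end:
                return float(t_cross)
    return None


def line_time_to_threshold(slope: float, threshold: float, start_percent: float = 100.0) -> float | None:
    """Time for a single line from ``start_percent`` to reach the threshold."""
    if not (0.0 < threshold < 100.0):
        raise KineticsError("threshold must be in (0, 100) percent")
    if start_percent <= threshold:
        return 0.0
    if slope >= 0:
        return None
    return (threshold - start_percent) / slope


def regression_to_dict(reg: PhaseRegression) -> dict:
    return {
        "analyte": reg.analyte,
        "device": reg.device,
        "dose_label": reg.dose_label,
        "phase": reg.phase,
        "slope": reg.slope,
        "intercept": reg.intercept,
        "slope_se": reg.slope_se,
        "intercept_se": reg.intercept_se,
        "n_points": reg.n_points,
        "residual_sd": reg.residual_sd,
        "scale": reg.scale,
        "time_unit": reg.time_unit,
    }
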