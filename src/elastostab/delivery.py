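"""Cumulative impurity mass delivered to the patient during the running phase.

The device infuses at flow rate ``f`` (mL/h) while pyridine keeps forming in
the reservoir; its concentration during the running phase is described by the
fitted line ``C(t) = a*t + b`` on the concentration scale.  The delivered
mass is accumulated in small time increments (1 min by default):

    delivered_i = C(t_{i-1}) * f * dt          (mass leaving in increment i)
    V_i         = V_{i-1} - f * dt             (reservoir bookkeeping)

so the cumulative total approximates f * integral_0^T C(t) dt, for which a
closed form exists and serves as the test oracle.  An alternative "literal"
mode accumulates C_i * V_i with the remaining reservoir volume instead of
the infused volume; it is retained for transparency but is not a delivered
mass (see the methods note).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DeviceSpec, derive_flow_rate
from .kinetics import PhaseRegression

logger = logging.getLogger(__name__)


class DeliveryError(ValueError):
    pass


@dataclass(frozen=True)
class DeliveryResult:
    device: str
    dose_label: str
    flow_rate_ml_per_h: float
    dt_min: float
    n_increments: int
    t_min: np.ndarray               # end of each increment, minutes
    concentration_mg_per_ml: np.ndarray  # evaluated at increment start
    volume_ml: np.ndarray           # remaining reservoir volume V_i
    delivered_increment_mg: np.ndarray
    cumulative_mg: np.ndarray
    total_delivered_mg: float
    mode: str = "flow"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_min": self.t_min,
            "C_mg_per_ml": self.concentration_mg_per_ml,
            "V_ml": self.volume_ml,
            "delivered_mg": self.delivered_increment_mg,
            "cumulative_mg": self.cumulative_mg,
        })


def predict_pyridine_concentration(reg: PhaseRegression, t_min: float) -> float:
    """Regression-predicted pyridine concentration (mg/mL) at ``t_min``
    minutes after the start of the running phase.

    The regression must be on the concentration scale with time in hours;
    negative predictions are clamped to zero (and logged) since the model is
    only an empirical line.
    """
    if reg.scale != "concentration":
        raise DeliveryError(
            "pyridine delivery needs a concentration-scale regression, "
            f"got scale={reg.scale!r}"
        )
    c = reg.slope * (t_min / 60.0) + reg.intercept
    if c < 0:
        logger.warning("negative predicted concentration %.4g mg/mL at t=%.1f min; clamped to 0", c, t_min)
        return 0.0
    return float(c)


def cumulative_delivered(
    reg: PhaseRegression,
    device: DeviceSpec,
    dose_label: str | None = None,
    duration_h: float = 24.0,
    dt_min: float = 1.0,
    mode: str = "flow",
) -> DeliveryResult:
    """Incremental cumulative pyridine mass delivered over the running phase.

    Concentration is evaluated at the start of each increment
    (left-endpoint rule); the infused volume per increment is ``f * dt``.
    The duration may not exceed the reservoir emptying time ``V0 / f``.
    """
    if mode not in ("flow", "literal"):
        raise DeliveryError(f"unknown mode {mode!r}; use 'flow' or 'literal'")
    f = derive_flow_rate(device)
    if f <= 0:
        raise DeliveryError("flow rate must be > 0")
    if dt_min <= 0:
        raise DeliveryError("dt_min must be > 0")
    v0 = device.nominal_fill_volume_ml
    emptying_h = v0 / f
    if duration_h > emptying_h * (1 + 1e-12):
        raise DeliveryError(
            f"duration {duration_h} h exceeds reservoir emptying time "
            f"{emptying_h} h for device {device.name!r}"
        )

    n = int(round(duration_h * 60.0 / dt_min))
    if not np.isclose(n * dt_min, duration_h * 60.0):
        raise DeliveryError("duration_h must be an integer number of dt_min increments")
    dt_h = dt_min / 60.0
    t_end_min = (np.arange(n, dtype=float) + 1.0) * dt_min
    t_start_min = t_end_min - dt_min

    a, b = reg.slope, reg.intercept
    if reg.scale != "concentration":
        raise DeliveryError("regression must be on the concentration scale")
    c_start = np.maximum(a * (t_start_min / 60.0) + b, 0.0)
    n_clamped = int((a * (t_start_min / 60.0) + b < 0).sum())
    if n_clamped:
        logger.warning("clamped %d negative concentration predictions to 0", n_clamped)

    volume = v0 - f * dt_h * (np.arange(n, dtype=float) + 1.0)
    volume = np.maximum(volume, 0.0)

    if mode == "flow":
        delivered = c_start * f * dt_h
    else:  # literal running sum of C_i * V_i, as sometimes printed
        c_end = np.maximum(a * (t_end_min / 60.0) + b, 0.0)
        delivered = c_end * volume
    cumulative = np.cumsum(delivered)
    return DeliveryResult(
        device=device.name,
        dose_label=dose_label or reg.dose_label,
        flow_rate_ml_per_h=f,
        dt_min=dt_min,
        n_increments=n,
        t_min=t_end_min,
        concentration_mg_per_ml=c_start,
        volume_ml=volume,
        delivered_increment_mg=delivered,
        cumulative_mg=cumulative,
        total_delivered_mg=float(cumulative[-1]) if n else 0.0,
        mode=mode,
    )


def closed_form_delivered(a: float, b: float, f: float, duration_h: float) -> float:
    """Analytic f * integral_0^T max(a*t + b, 0) dt in mg.

    Oracle for the incremental sum; handles the clamped (negative
    concentration) region piecewise.
    """
    if duration_h < 0:
        raise DeliveryError("duration must be >= 0")
    T = duration_h

    def _integral(lo: float, hi: float) -> float:
        return a * (hi**2 - lo**2) / 2.0 + b * (hi - lo)

    if a == 0:
        return f * max(b, 0.0) * T
    root = -b / a
    if a > 0:
        lo = min(max(root, 0.0), T) if b < 0 else 0.0
        return f * _integral(lo, T) if lo < T else 0.0
    # a < 0: positive before the root
    hi = min(max(root, 0.0), T)
    return f * _integral(0.0, hi) if hi > 0 else 0.0


def pyridine_percent_ww(pyridine_mg: float, ceftazidime_dose_mg: float) -> float:
    """Pyridine mass as percent w/w of the ceftazidime dose."""
    if ceftazidime_dose_mg <= 0:
        raise DeliveryError("ceftazidime dose must be > 0")
    return 100.0 * pyridine_mg / ceftazidime_dose_mg
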