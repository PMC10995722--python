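"""Weighted quadratic HPLC calibration, back-calculation and QC statistics.

The assay's numeric layer: a quadratic response curve
``response = c2*x^2 + c1*x + c0`` fitted by weighted least squares with
1/x^2 weighting (low calibrators get proportionally greater influence, the
bioanalytical standard), inverted for back-calculation of sample
concentrations, plus precision (%CV) and accuracy (% bias) summaries of
quality-control replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


class CalibrationError(ValueError):
    pass


class OutOfRangeError(CalibrationError):
    """Response outside the calibrated image; the caller should dilute the
    sample (e.g. factor 10 or 5) and re-assay."""


@dataclass(frozen=True)
class CalibrationCurve:
    analyte: str
    c0: float
    c1: float
    c2: float
    weighting_exponent: int
    calibrator_levels: tuple[float, ...]
    r_squared: float          # on weighted residuals (canonical)
    r_squared_unweighted: float
    valid_range: tuple[float, float]

    def predict(self, concentration: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(concentration, dtype=float)
        y = self.c2 * x**2 + self.c1 * x + self.c0
        return float(y) if np.isscalar(concentration) else y


def fit_calibration(
    concentrations,
    responses,
    analyte: str,
    weighting_exponent: int = -2,
) -> CalibrationCurve:
    """Fit the weighted quadratic calibration curve.

    Requires >= 4 distinct positive concentration levels (1/x^2 weights are
    undefined at zero).  The fitted curve must be strictly increasing over
    the calibrated range, else the calibration is rejected: a non-monotone
    curve would make back-calculation ambiguous.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise CalibrationError("concentrations and responses must align")
    if np.any(x <= 0):
        raise CalibrationError("calibrator concentrations must be > 0 for 1/x^2 weighting")
    levels = np.unique(x)
    if levels.size < 4:
        raise CalibrationError(
            f"need >= 4 distinct calibrator levels, got {levels.size}"
        )

    weights = x**weighting_exponent
    X = np.column_stack([np.ones_like(x), x, x**2])
    fit = sm.WLS(y, X, weights=weights).fit()
    c0, c1, c2 = fit.params

    yhat = X @ fit.params
    r2_w = _r_squared(y, yhat, weights)
    r2_u = _r_squared(y, yhat, np.ones_like(y))

    lo, hi = float(levels.min()), float(levels.max())
    # derivative 2*c2*x + c1 is linear: positivity at both ends suffices
    if (2 * c2 * lo + c1) <= 0 or (2 * c2 * hi + c1) <= 0:
        raise CalibrationError(
            f"{analyte}: fitted curve not strictly increasing over [{lo}, {hi}] mg/mL; "
            "calibration rejected"
        )
    return CalibrationCurve(
        analyte=analyte,
        c0=float(c0),
        c1=float(c1),
        c2=float(c2),
        weighting_exponent=weighting_exponent,
        calibrator_levels=tuple(float(v) for v in levels),
        r_squared=r2_w,
        r_squared_unweighted=r2_u,
        valid_range=(lo, hi),
    )


def _r_squared(y, yhat, w) -> float:
    ybar = np.average(y, weights=w)
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    if ss_tot == 0:
        return 1.0
    return max(0.0, min(1.0, 1.0 - ss_res / ss_tot))


def back_calculate(curve: CalibrationCurve, response: float) -> float:
    """Invert the calibration curve for one instrument response.

    The curve is strictly increasing over ``valid_range``, so the inverse is
    the unique quadratic root inside the range.  A response outside the image
    of the range raises :class:`OutOfRangeError`.
    """
    lo, hi = curve.valid_range
    y_lo, y_hi = curve.predict(lo), curve.predict(hi)
    tol = 1e-9 * max(abs(y_lo), abs(y_hi), 1.0)
    if not (y_lo - tol <= response <= y_hi + tol):
        raise OutOfRangeError(
            f"{curve.analyte}: response {response:g} outside calibrated image "
            f"[{y_lo:g}, {y_hi:g}]; dilute and re-assay"
        )
    if curve.c2 == 0:
        return (response - curve.c0) / curve.c1
    disc = curve.c1**2 - 4 * curve.c2 * (curve.c0 - response)
    if disc < 0:
        raise CalibrationError("no real root for response; curve inconsistent")
    sq = math.sqrt(disc)
    roots = [(-curve.c1 + sq) / (2 * curve.c2), (-curve.c1 - sq) / (2 * curve.c2)]
    span = hi - lo
    inside = [r for r in roots if lo - 1e-9 * span <= r <= hi + 1e-9 * span]
    if not inside:
        raise OutOfRangeError(
            f"{curve.analyte}: no root of response {response:g} inside valid range"
        )
    # monotone curve: at most one root in range; duplicates only at the
    # discriminant's double root
    return float(min(inside, key=lambda r: abs(r - (lo + hi) / 2)))


@dataclass(frozen=True)
class QcSummary:
    analyte: str
    nominal_mg_per_ml: float
    n: int
    precision_pct_cv: float | None
    accuracy_pct_bias: float        # signed; report abs() in summaries
    flag: str = ""


def qc_statistics(qc: pd.DataFrame) -> list[QcSummary]:
    """Precision and accuracy per analyte x nominal level.

    Expects columns ``analyte``, ``nominal_mg_per_ml``, ``measured_mg_per_ml``
    (an optional ``batch`` column is ignored for pooled statistics).
    Precision is 100*SD/mean (sample SD); accuracy is the signed
    100*(mean - nominal)/nominal.  Groups with n < 2 get precision ``None``
    and a flag rather than a silent drop.
    """
    required = {"analyte", "nominal_mg_per_ml", "measured_mg_per_ml"}
    missing = required - set(qc.columns)
    if missing:
        raise CalibrationError(f"QC table missing columns {sorted(missing)}")
    out: list[QcSummary] = []
    for (analyte, nominal), group in qc.groupby(["analyte", "nominal_mg_per_ml"], sort=True):
        values = group["measured_mg_per_ml"].to_numpy(dtype=float)
        n = values.size
        mean = float(values.mean())
        accuracy = 100.0 * (mean - nominal) / nominal
        if n >= 2:
            precision = 100.0 * float(values.std(ddof=1)) / mean
            flag = ""
        else:
            precision = None
            flag = "precision undefined (n < 2)"
        out.append(QcSummary(str(analyte), float(nominal), int(n), precision, accuracy, flag))
    return out


def curve_to_dict(curve: CalibrationCurve) -> dict:
    return {
        "analyte": curve.analyte,
        "coefficients": {"c0": curve.c0, "c1": curve.c1, "c2": curve.c2},
        "weighting_exponent": curve.weighting_exponent,
        "calibrator_levels": list(curve.calibrator_levels),
        "r_squared": curve.r_squared,
        "r_squared_unweighted": curve.r_squared_unweighted,
        "valid_range": list(curve.valid_range),
    }
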