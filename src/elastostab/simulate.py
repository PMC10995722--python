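"""Forward simulation of ground-truth concentrations and noisy measurements.

The generator produces the data the analysis layer assumes: per-phase
degradation of ceftazidime and avibactam (first-order by default, optionally
piecewise-linear), pyridine formed stoichiometrically from degraded
ceftazidime, and multiplicative log-normal measurement noise with a shared
per-device component.  Truth trajectories are continuous at phase boundaries
and mass-balanced, so downstream fits can be checked for exact parameter
recovery.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .config import CEFTAZIDIME_MOLAR_MASS, PYRIDINE_MOLAR_MASS
from .design import StudyDesign, build_design, enumerate_samples

logger = logging.getLogger(__name__)

DATASET_COLUMNS = [
    "device",
    "dose_label",
    "replicate",
    "time_h",
    "phase",
    "duplicate_index",
    "analyte",
    "true_mg_per_ml",
    "measured_mg_per_ml",
]


class KineticTruth(BaseModel):
    """Ground-truth degradation mechanism for the simulator.

    ``rates_per_h`` maps analyte -> phase label -> rate: a first-order rate
    constant (/h) under ``model_form="first_order"``, or a linear loss rate
    in percent of the initial concentration per hour under
    ``model_form="linear"``.  Pyridine is released from degraded ceftazidime
    at ``pyridine_molar_yield`` moles per mole (hydrolytic release of the
    pyridinium moiety), on top of ``pyridine_baseline_mg_per_ml``.
    """

    model_form: Literal["first_order", "linear"] = "first_order"
    rates_per_h: dict[str, dict[str, float]]
    dose_rate_multipliers: dict[str, float] = Field(default_factory=dict)
    pyridine_molar_yield: float = Field(default=1.0, ge=0.0, le=1.0)
    pyridine_baseline_mg_per_ml: float = Field(default=0.0, ge=0.0)
    ceftazidime_molar_mass_g_per_mol: float = Field(default=CEFTAZIDIME_MOLAR_MASS, gt=0)
    pyridine_molar_mass_g_per_mol: float = Field(default=PYRIDINE_MOLAR_MASS, gt=0)

    @model_validator(mode="after")
    def _validate_rates(self) -> "KineticTruth":
        for analyte, by_phase in self.rates_per_h.items():
            for phase, rate in by_phase.items():
                if rate < 0:
                    raise ValueError(f"negative rate for {analyte}/{phase}")
            # default scenario: warmer in-use phase degrades at least as fast
            if "fridge" in by_phase and "in_use" in by_phase:
                if by_phase["in_use"] < by_phase["fridge"]:
                    raise ValueError(
                        f"{analyte}: in_use rate must be >= fridge rate"
                    )
        for label, mult in self.dose_rate_multipliers.items():
            if mult < 0:
                raise ValueError(f"negative dose multiplier for {label!r}")
        return self

    def rate(self, analyte: str, phase: str, dose_label: str | None = None) -> float:
        base = self.rates_per_h.get(analyte, {}).get(phase, 0.0)
        mult = self.dose_rate_multipliers.get(dose_label, 1.0) if dose_label else 1.0
        return base * mult


class NoiseModel(BaseModel):
    """Multiplicative log-normal measurement noise.

    ``assay_cv`` is the per-sample analytical CV per analyte; the
    ``inter_device_cv`` component is drawn once per replicate device (per
    analyte) and shared by all its samples.  Log-normal factors have mean
    exactly 1, so the noise is unbiased and positivity is guaranteed.
    """

    assay_cv: dict[str, float] = Field(
        default_factory=lambda: {"ceftazidime": 0.019, "avibactam": 0.019, "pyridine": 0.017}
    )
    inter_device_cv: float = Field(default=0.0, ge=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "NoiseModel":
        for analyte, cv in self.assay_cv.items():
            if cv < 0:
                raise ValueError(f"negative assay_cv for {analyte!r}")
        return self


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Mean-one log-normal multiplier with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else np.float64(1.0)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def _phase_exposure(design: StudyDesign, time_h: float) -> list[tuple[str, float]]:
    """Time spent in each phase by global time ``time_h``."""
    out = []
    for label, (start, end) in design.phase_windows().items():
        dt = min(time_h, end) - start
        if dt > 0 or (dt == 0 and start == 0.0):
            out.append((label, max(dt, 0.0)))
    return out


def true_concentration(
    design: StudyDesign,
    truth: KineticTruth,
    analyte: str,
    dose_label: str,
    time_h: float,
) -> float:
    """Noiseless concentration of one analyte at a global time.

    First-order form accumulates the exponent phase-piecewise
    (C = C0 * exp(-sum_p k_p * t_p)); linear form accumulates percent loss
    piecewise-linearly, clamped at zero.  Pyridine is the stoichiometric
    conversion of degraded ceftazidime plus the baseline.  Either way the
    trajectory is continuous at phase boundaries.
    """
    dose = next(d for d in design.dose_levels if d.label == dose_label)
    if analyte == "pyridine":
        c0 = dose.nominal_concentration_mg_per_ml("ceftazidime")
        c_now = true_concentration(design, truth, "ceftazidime", dose_label, time_h)
        degraded = c0 - c_now
        released = (
            truth.pyridine_molar_yield
            * degraded
            * truth.pyridine_molar_mass_g_per_mol
            / truth.ceftazidime_molar_mass_g_per_mol
        )
        return truth.pyridine_baseline_mg_per_ml + released

    c0 = dose.nominal_concentration_mg_per_ml(analyte)
    exposure = _phase_exposure(design, time_h)
    if truth.model_form == "first_order":
        exponent = sum(truth.rate(analyte, p, dose_label) * dt for p, dt in exposure)
        return c0 * math.exp(-exponent)
    lost_pct = sum(truth.rate(analyte, p, dose_label) * dt for p, dt in exposure)
    if lost_pct > 100.0:
        logger.warning(
            "linear loss for %s/%s exceeds 100%% at t=%s h; clamping to 0",
            analyte, dose_label, time_h,
        )
        lost_pct = 100.0
    return c0 * (1.0 - lost_pct / 100.0)


def simulate_truth(design: StudyDesign, truth: KineticTruth) -> pd.DataFrame:
    """True concentrations for every manifest slot and analyte.

    Returns the manifest crossed with the three analytes and a
    ``true_mg_per_ml`` column.
    """
    manifest = enumerate_samples(design)
    frames = []
    for analyte in ("ceftazidime", "avibactam", "pyridine"):
        frame = manifest.copy()
        frame["analyte"] = analyte
        # concentration depends only on (analyte, dose, time): compute per
        # unique pair and broadcast
        conc = {
            (dl, t): true_concentration(design, truth, analyte, dl, t)
            for dl in {d.label for d in design.dose_levels}
            for t in {tp for tp, _ in design.timepoints()}
        }
        frame["true_mg_per_ml"] = [
            conc[(row.dose_label, row.time_h)] for row in frame.itertuples()
        ]
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    # stable ordering: device, dose, replicate, time, duplicate, analyte
    out["analyte"] = pd.Categorical(out["analyte"], categories=list(("ceftazidime", "avibactam", "pyridine")))
    out = out.sort_values(
        ["device", "dose_label", "replicate", "time_h", "duplicate_index", "analyte"],
        kind="stable",
    ).reset_index(drop=True)
    out["analyte"] = out["analyte"].astype(str)
    return out


def apply_noise(truth_records: pd.DataFrame, noise: NoiseModel) -> pd.DataFrame:
    """Add a ``measured_mg_per_ml`` column: true x device factor x assay factor.

    Device factors are drawn once per (device, dose, replicate, analyte) and
    shared within that replicate device; assay factors are i.i.d. per sample.
    Deterministic for a fixed seed and input ordering.
    """
    rng = np.random.default_rng(noise.seed)
    out = truth_records.copy()

    device_keys = (
        out[["device", "dose_label", "replicate", "analyte"]]
        .drop_duplicates()
        .sort_values(["device", "dose_label", "replicate", "analyte"], kind="stable")
    )
    device_factor = {
        tuple(row): float(_lognormal_factor(rng, noise.inter_device_cv))
        for row in device_keys.itertuples(index=False)
    }
    dev = np.array([
        device_factor[(r.device, r.dose_label, r.replicate, r.analyte)]
        for r in out.itertuples()
    ])
    cv_by_analyte = out["analyte"].map(lambda a: noise.assay_cv.get(a, 0.0)).to_numpy()
    sigma = np.sqrt(np.log1p(cv_by_analyte**2))
    assay = np.exp(rng.normal(size=len(out)) * sigma - 0.5 * sigma**2)

    measured = out["true_mg_per_ml"].to_numpy() * dev * assay
    n_neg = int((measured < 0).sum())
    if n_neg:
        logger.warning("clamping %d negative measured concentrations to 0", n_neg)
        measured = np.clip(measured, 0.0, None)
    out["measured_mg_per_ml"] = measured
    return out


def simulate_study(
    config: dict,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full simulation from a study config.

    Returns the tidy dataset (one row per slot per analyte, manifest size x 3
    rows) and a truth sidecar dict recording the generating parameters for
    parameter-recovery tests.  When ``out_dir`` is given, writes
    ``dataset.csv`` and ``truth.json`` there.
    """
    design = build_design(config["design"])
    truth = KineticTruth(**config["truth"])
    noise = NoiseModel(**config["noise"])

    records = apply_noise(simulate_truth(design, truth), noise)
    sidecar = {
        "truth": truth.model_dump(),
        "noise": noise.model_dump(),
        "n_slots": len(records) // 3,
        "n_rows": len(records),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        try:
            out_dir.mkdir(parents=True, exist_ok=True)
            records.to_csv(out_dir / "dataset.csv", index=False)
            (out_dir / "truth.json").write_text(json.dumps(sidecar, indent=2))
        except OSError as exc:
            raise OSError(f"failed writing simulation output under {out_dir}: {exc}") from exc
    return records, sidecar
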