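"""Factorial structure of a sequential-stability study.

A study exposes antibiotic-filled elastomeric devices to an ordered sequence
of temperature phases (refrigerated storage followed by an in-use phase at
body-adjacent temperature) and samples each device at scheduled offsets on a
single global clock in hours since device filling.  This module defines the
validated domain types (device, dose level, temperature phase, study design)
and enumerates the deterministic sample manifest.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

ANALYTES = ("ceftazidime", "avibactam", "pyridine")

MANIFEST_COLUMNS = [
    "device",
    "dose_label",
    "replicate",
    "time_h",
    "phase",
    "duplicate_index",
]


class DesignError(ValueError):
    """Raised when a study configuration violates a structural invariant."""


class DeviceSpec(BaseModel):
    """An elastomeric infuser: balloon reservoir delivering at nominally
    constant flow.

    The flow rate is derived as fill volume / delivery duration unless an
    explicit labelled flow rate overrides it (real devices carry labelled
    flow rates that differ from the fill/duration arithmetic).
    """

    name: str
    nominal_fill_volume_ml: float = Field(gt=0)
    nominal_duration_h: float = Field(gt=0)
    flow_rate_override_ml_per_h: Optional[float] = Field(default=None, gt=0)

    @property
    def flow_rate_ml_per_h(self) -> float:
        if self.flow_rate_override_ml_per_h is not None:
            return self.flow_rate_override_ml_per_h
        return self.nominal_fill_volume_ml / self.nominal_duration_h


def derive_flow_rate(device: DeviceSpec) -> float:
    """Flow rate in mL/h: the override when present, else fill/duration."""
    return device.flow_rate_ml_per_h


class DoseLevel(BaseModel):
    """One ceftazidime/avibactam dose level filled into a device reservoir."""

    label: str
    ceftazidime_mg: float = Field(gt=0)
    avibactam_mg: float = Field(gt=0)
    fill_volume_ml: float = Field(gt=0)

    def nominal_concentration_mg_per_ml(self, analyte: str) -> float:
        if analyte == "ceftazidime":
            return self.ceftazidime_mg / self.fill_volume_ml
        if analyte == "avibactam":
            return self.avibactam_mg / self.fill_volume_ml
        if analyte == "pyridine":
            return 0.0
        raise DesignError(f"unknown analyte {analyte!r}")


class TemperaturePhase(BaseModel):
    """A contiguous temperature condition with its sampling schedule.

    ``sampling_offsets_h`` are on the global study clock.  Temperature is
    metadata only: kinetic rates downstream are phase-indexed, never computed
    from temperature.
    """

    label: str
    temperature_c: float
    duration_h: float = Field(gt=0)
    sampling_offsets_h: list[float]

    @model_validator(mode="after")
    def _offsets_increasing(self) -> "TemperaturePhase":
        off = self.sampling_offsets_h
        if any(b <= a for a, b in zip(off, off[1:])):
            raise DesignError(
                f"phase {self.label!r}: sampling_offsets_h must be strictly increasing"
            )
        return self


class StudyDesign(BaseModel):
    """Full factorial design: devices x dose levels x replicates x timepoints
    x duplicate samples, over an ordered list of contiguous phases."""

    devices: list[DeviceSpec]
    dose_levels: list[DoseLevel]
    replicates_per_cell: int = Field(ge=1)
    samples_per_timepoint: int = Field(ge=1)
    phases: list[TemperaturePhase]

    @model_validator(mode="after")
    def _validate_phases(self) -> "StudyDesign":
        if not self.devices:
            raise DesignError("devices must be non-empty")
        if not self.dose_levels:
            raise DesignError("dose_levels must be non-empty")
        if not self.phases:
            raise DesignError("phases must be non-empty")
        start = 0.0
        for phase in self.phases:
            end = start + phase.duration_h
            for t in phase.sampling_offsets_h:
                inside = (start <= t <= end) if start == 0.0 else (start < t <= end)
                if not inside:
                    raise DesignError(
                        f"phase {phase.label!r}: sampling offset {t} h outside "
                        f"phase window ({start}, {end}] h"
                    )
            start = end
        return self

    # -- derived views ---------------------------------------------------

    def phase_windows(self) -> dict[str, tuple[float, float]]:
        """Global [start, end] window per phase label, phases chained
        contiguously from t = 0."""
        windows: dict[str, tuple[float, float]] = {}
        start = 0.0
        for phase in self.phases:
            windows[phase.label] = (start, start + phase.duration_h)
            start += phase.duration_h
        return windows

    def phase_of(self, time_h: float) -> str:
        """Phase label owning a global time.  The first phase owns its closed
        window including both endpoints; later phases own (start, end], so a
        boundary sample belongs to the earlier phase."""
        for i, (label, (start, end)) in enumerate(self.phase_windows().items()):
            if (start <= time_h <= end) if i == 0 else (start < time_h <= end):
                return label
        raise DesignError(f"time {time_h} h outside all phase windows")

    def timepoints(self) -> list[tuple[float, str]]:
        """All (global time, phase label) sampling points, time-ordered."""
        return [
            (t, phase.label) for phase in self.phases for t in phase.sampling_offsets_h
        ]

    @property
    def n_timepoints(self) -> int:
        return sum(len(p.sampling_offsets_h) for p in self.phases)


def build_design(config: dict) -> StudyDesign:
    """Build and validate a :class:`StudyDesign` from a structured config.

    Expected keys: ``devices``, ``dose_levels``, ``phases``,
    ``replicates_per_cell``, ``samples_per_timepoint``.  Validation errors
    name the offending field.
    """
    try:
        return StudyDesign(
            devices=[DeviceSpec(**d) for d in config["devices"]],
            dose_levels=[DoseLevel(**d) for d in config["dose_levels"]],
            phases=[TemperaturePhase(**p) for p in config["phases"]],
            replicates_per_cell=config["replicates_per_cell"],
            samples_per_timepoint=config["samples_per_timepoint"],
        )
    except KeyError as exc:
        raise DesignError(f"config missing required key {exc.args[0]!r}") from exc


def enumerate_samples(design: StudyDesign) -> pd.DataFrame:
    """Enumerate the full sample manifest as a tidy frame.

    One row per sample slot; ordering is deterministic
    (device, dose, replicate, time, duplicate), so the manifest CSV is
    byte-identical across runs for a fixed config.
    """
    rows = []
    timepoints = design.timepoints()
    for device in design.devices:
        for dose in design.dose_levels:
            for rep in range(1, design.replicates_per_cell + 1):
                for time_h, phase in timepoints:
                    for dup in range(1, design.samples_per_timepoint + 1):
                        rows.append(
                            (device.name, dose.label, rep, time_h, phase, dup)
                        )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
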