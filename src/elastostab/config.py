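"""Default study configuration and YAML/JSON config loading.

The default config encodes the reference sequential-stability design: two
elastomeric device types (Easypump, Dosi-Fuser; 240 mL delivered over 24 h),
three ceftazidime/avibactam dose levels (1500/375, 3000/750, 6000/1500 mg in
240 mL), triplicate devices sampled in duplicate at 12 timepoints across a
14-day fridge phase (2-8 degC) and a 24 h in-use phase at 32 degC.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

# Literature molar masses (g/mol); not measured in this package.
CEFTAZIDIME_MOLAR_MASS = 546.58
PYRIDINE_MOLAR_MASS = 79.10

FRIDGE_OFFSETS_H = [0.0, 24.0, 48.0, 96.0, 168.0, 240.0, 336.0]
IN_USE_OFFSETS_H = [340.0, 344.0, 348.0, 356.0, 360.0]


def default_design_config() -> dict:
    """Reference study design: 2 devices x 3 doses x 3 replicates x
    12 timepoints x duplicate sampling = 432 sample slots."""
    return {
        "devices": [
            {"name": "Easypump", "nominal_fill_volume_ml": 240.0, "nominal_duration_h": 24.0},
            {"name": "Dosi-Fuser", "nominal_fill_volume_ml": 240.0, "nominal_duration_h": 24.0},
        ],
        "dose_levels": [
            {"label": "low", "ceftazidime_mg": 1500.0, "avibactam_mg": 375.0, "fill_volume_ml": 240.0},
            {"label": "intermediate", "ceftazidime_mg": 3000.0, "avibactam_mg": 750.0, "fill_volume_ml": 240.0},
            {"label": "high", "ceftazidime_mg": 6000.0, "avibactam_mg": 1500.0, "fill_volume_ml": 240.0},
        ],
        "phases": [
            {
                "label": "fridge",
                "temperature_c": 5.0,
                "duration_h": 336.0,
                "sampling_offsets_h": FRIDGE_OFFSETS_H,
            },
            {
                "label": "in_use",
                "temperature_c": 32.0,
                "duration_h": 24.0,
                "sampling_offsets_h": IN_USE_OFFSETS_H,
            },
        ],
        "replicates_per_cell": 3,
        "samples_per_timepoint": 2,
    }


def default_truth_config() -> dict:
    """Illustrative first-order degradation scenario.

    Rate constants are chosen so noiseless endpoints land in realistic
    windows (~75-85% ceftazidime and ~83-93% avibactam remaining after
    336 h fridge + 24 h at 32 degC); they are config values, not claims
    about any particular product.  Dose-rate multipliers reproduce the
    faster apparent loss at higher concentration.
    """
    return {
        "model_form": "first_order",
        "rates_per_h": {
            "ceftazidime": {"fridge": 3.8e-4, "in_use": 3.5e-3},
            "avibactam": {"fridge": 2.0e-4, "in_use": 2.0e-3},
        },
        "dose_rate_multipliers": {"low": 1.0, "intermediate": 1.1, "high": 1.2},
        "pyridine_molar_yield": 1.0,
        "pyridine_baseline_mg_per_ml": 0.0,
        "ceftazidime_molar_mass_g_per_mol": CEFTAZIDIME_MOLAR_MASS,
        "pyridine_molar_mass_g_per_mol": PYRIDINE_MOLAR_MASS,
    }


def default_noise_config() -> dict:
    # Assay CVs match the validated HPLC precision (1.9% ceftazidime and
    # avibactam, 1.7% pyridine); inter-device CV is a modest between-unit
    # preparation effect.
    return {
        "assay_cv": {"ceftazidime": 0.019, "avibactam": 0.019, "pyridine": 0.017},
        "inter_device_cv": 0.01,
        "seed": 0,
    }


def default_study_config() -> dict:
    return {
        "design": default_design_config(),
        "truth": default_truth_config(),
        "noise": default_noise_config(),
        "scenario": {"storage_h": 72.0, "running_h": 24.0, "thresholds": [95.0, 90.0]},
        "delivery": {"duration_h": 24.0, "dt_min": 1.0},
    }


def load_config(path: str | Path) -> dict:
    """Load a study config from YAML or JSON, merged over the defaults."""
    path = Path(path)
    text = path.read_text()
    loaded = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    config = default_study_config()
    _deep_update(config, loaded or {})
    return config


def _deep_update(base: dict, other: dict) -> None:
    for key, value in other.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = copy.deepcopy(value)
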