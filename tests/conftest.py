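import pytest

from elastostab.config import default_study_config
from elastostab.design import build_design
from elastostab.simulate import KineticTruth, NoiseModel, apply_noise, simulate_truth


@pytest.fixture
def default_config():
    return default_study_config()


@pytest.fixture
def default_design(default_config):
    return build_design(default_config["design"])


def linear_truth_config() -> dict:
    """Piecewise-linear ground truth: the form the regression layer fits
    exactly, used for parameter-recovery and scenario-exactness tests."""
    return {
        "model_form": "linear",
        "rates_per_h": {
            # percent of initial concentration lost per hour
            "ceftazidime": {"fridge": 0.03, "in_use": 0.30},
            "avibactam": {"fridge": 0.02, "in_use": 0.20},
        },
        "dose_rate_multipliers": {"low": 1.0, "intermediate": 1.1, "high": 1.2},
        "pyridine_molar_yield": 1.0,
        "pyridine_baseline_mg_per_ml": 0.0,
    }


@pytest.fixture(scope="session")
def noiseless_linear_dataset():
    """Full default design simulated under linear truth with zero noise."""
    cfg = default_study_config()
    design = build_design(cfg["design"])
    truth = KineticTruth(**linear_truth_config())
    noise = NoiseModel(assay_cv={a: 0.0 for a in ("ceftazidime", "avibactam", "pyridine")},
                       inter_device_cv=0.0, seed=0)
    records = apply_noise(simulate_truth(design, truth), noise)
    return design, truth, records


@pytest.fixture(scope="session")
def noisy_default_dataset():
    """Full default design under first-order truth and default noise."""
    cfg = default_study_config()
    design = build_design(cfg["design"])
    truth = KineticTruth(**cfg["truth"])
    noise = NoiseModel(**{**cfg["noise"], "seed": 7})
    records = apply_noise(simulate_truth(design, truth), noise)
    return design, truth, records
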