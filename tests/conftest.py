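from pathlib import Path

import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from digilabor.cleaning import clean_sessions
from digilabor.pipeline import PipelineConfig, _cleaning_config_with_labels
from digilabor.simulate import GeneratorConfig, generate_sessions

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference_projections() -> pd.DataFrame:
    """Published reference labor-projection table (tidy form, 312 cells)."""
    return pd.read_csv(DATA_DIR / "reference_projections.csv")


@pytest.fixture(scope="session")
def default_sessions():
    """Default synthetic sessions with ground-truth labels (fixed seed)."""
    return generate_sessions(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_outcome(default_sessions):
    """Cleaning outcome on the default synthetic fixture.

    Reporter and workflow exclusions come from the ground-truth labels,
    standing in for the human investigation that identifies them on
    real data.
    """
    sessions, labels = default_sessions
    config = _cleaning_config_with_labels(PipelineConfig(), labels, sessions)
    return clean_sessions(sessions, config)


@pytest.fixture()
def anomaly_free_config():
    """Generator configuration with every anomaly channel switched off."""
    return GeneratorConfig(
        n_technicians=10,
        sessions_per_technician=20,
        setback_probability=0.0,
        swap_error_probability=0.0,
        outlier_probability=0.0,
        fraudulent_reporter_count=0,
        workflow_entry_count=0,
        seed=11,
    )
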