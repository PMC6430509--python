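import hypothesis
import pytest

from sbipy import SimulationConfig, simulate_dataset
from sbipy.pipeline import run_pipeline_frames

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")

#: one seed for the shared default survey used across the suite
DEFAULT_SEED = 20130515


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic survey: 13 fields, 51 samples, 2000 ASVs."""
    return simulate_dataset(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    """Full pipeline result on the default survey."""
    ds = default_dataset
    return run_pipeline_frames(ds.feature_table, ds.metadata, ds.weather, ds.taxonomy)
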