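import numpy as np
import pytest

from neuroproxy.pipeline import PipelineConfig
from neuroproxy.synthdata import SimulationConfig, generate_subject


def quiet_sim(**kw) -> SimulationConfig:
    """Small, artifact-free simulation config for fast tests."""
    defaults = dict(n_subjects=1, block_length=12.0, montage="mini",
                    blink_rate=0.0, emg_rate=0.0, ecg_rate=0.0, seed=123)
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def mini_recording():
    """One fast synthetic subject (known IAF, no artifacts)."""
    return generate_subject(quiet_sim(subject_iaf=10.0), 0)


@pytest.fixture(scope="session")
def mini_pipeline_config():
    return PipelineConfig(sim=quiet_sim(subject_iaf=10.0), step=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
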