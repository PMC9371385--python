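import numpy as np
import pytest

import skidetect as sk


@pytest.fixture(scope="session")
def two_run_session():
    """Small session with two well-separated runs, generated once."""
    spec = sk.SessionSpec(
        duration=420.0,
        runs=(sk.RunSpec(60.0, 60.0, turn_frequency=0.7), sk.RunSpec(240.0, 50.0, turn_frequency=1.1)),
        sample_rate=100.0,
        seed=7,
    )
    recording, truth = sk.generate_session(spec)
    return spec, recording, truth


@pytest.fixture(scope="session")
def two_run_result(two_run_session):
    """Default pipeline run on the two-run session."""
    _, recording, _ = two_run_session
    return sk.run_pipeline(recording, sk.PipelineConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
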