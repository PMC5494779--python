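import pytest
from hypothesis import settings

import echopress as ep
from echopress.config import PipelineConfig
from echopress.pipeline import run_analysis

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cal():
    """Default linear IOP -> impedance map between the measured endpoints."""
    return ep.IOPCalibration()


@pytest.fixture(scope="session")
def constants():
    """Stack constants (Z0, A0, posterior gain) from the endpoint calibration."""
    return ep.calibrate_stack_constants()


@pytest.fixture(scope="session")
def tspec():
    return ep.TransducerSpec()


@pytest.fixture
def aspec_quiet():
    """Noiseless acquisition for deterministic oracle checks."""
    return ep.AcquisitionSpec(noise_sd=0.0)


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at the default design (5 IOP x 3 repeats x 10 A-lines)."""
    return run_analysis(PipelineConfig(seed=42))


@pytest.fixture(scope="session")
def seed_sweep():
    """Twenty full pipeline runs at default noise, seeds 0..19."""
    return [run_analysis(PipelineConfig(seed=s)) for s in range(20)]
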