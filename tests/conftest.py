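import numpy as np
import pytest

from patbp.pipeline import PipelineConfig, process_record
from patbp.simulate import SimConfig, generate_record


def noiseless_config(**overrides) -> SimConfig:
    """Constant-BP, zero-noise study conditions used by exactness tests."""
    base = dict(
        duration_s=300.0,
        noise_sd=0.0,
        abp_noise_sd=0.0,
        baseline_wander_amp=0.0,
        pat_noise_sd=0.0,
        pat_drift_sd=0.0,
        ptt_noise_sd=0.0,
        ptt_drift_sd=0.0,
        seed=1,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def short_gate_config() -> PipelineConfig:
    """Pipeline defaults with the duration gate matched to short test records."""
    return PipelineConfig(gate_min_duration_min=2.0)


@pytest.fixture(scope="session")
def clean_record_truth():
    return generate_record(noiseless_config())


@pytest.fixture(scope="session")
def noisy_record_truth():
    return generate_record(SimConfig(duration_s=300.0, seed=7))


@pytest.fixture(scope="session")
def noisy_extraction(noisy_record_truth, short_gate_config):
    record, truth = noisy_record_truth
    return process_record(record, short_gate_config), truth


@pytest.fixture(scope="session")
def clean_extraction(clean_record_truth, short_gate_config):
    record, truth = clean_record_truth
    return process_record(record, short_gate_config), truth


def valid_beats(result):
    return [b for b in result.beats if b.valid]
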