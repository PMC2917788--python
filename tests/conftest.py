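from dataclasses import replace

import numpy as np
import pytest

from fepsp.io import TraceMeta, Trace
from fepsp.protocol import ProtocolSpec
from fepsp.synth import SynthParams, get_preset


def noiseless(params: SynthParams) -> SynthParams:
    """Strip every stochastic tier from a parameter set."""
    return replace(params, noise_sd_mV=0.0, trial_cv=0.0, slice_cv_fast=0.0,
                   slice_cv_nmda=0.0, slice_cv_common=0.0, nmda_log_shift=None)


@pytest.fixture(scope="session")
def control_params() -> SynthParams:
    return noiseless(get_preset("control"))


@pytest.fixture(scope="session")
def protocol() -> ProtocolSpec:
    return ProtocolSpec()


@pytest.fixture(scope="session")
def short_protocol() -> ProtocolSpec:
    """Simulates only the analysed last-3-min window of each epoch."""
    return ProtocolSpec(baseline_min=3, gaba_block_min=3, full_block_min=3)


def flat_trace(n: int = 1300, dt: float = 0.1, stim: float = 10.0,
               value: float = 0.0) -> Trace:
    return Trace(voltage_mV=np.full(n, value), sampling_interval_ms=dt,
                 stimulus_time_ms=stim, meta=TraceMeta("flat"))
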