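import numpy as np
import pytest

from eidecomp import Condition, ReversalPotentials, SweepSet, TimeBase
from eidecomp.core_io import average_repeats, subtract_background
from eidecomp.synthetic_data import (DEFAULT_TIMEBASE, NoiseModel,
                                     default_kernels, kernel_waveform,
                                     simulate_voltage_clamp)


@pytest.fixture
def analysis_timebase():
    """Standard analysis grid: [-100, 100] ms at 0.1 ms."""
    return DEFAULT_TIMEBASE


@pytest.fixture
def post_timebase():
    """Post-stimulus-only grid [0, 100] ms at 0.1 ms."""
    return TimeBase(0.0, 0.1, 1001)


@pytest.fixture
def aip_kernels():
    return default_kernels(Condition.AIP)


@pytest.fixture
def aip_truth(aip_kernels, analysis_timebase):
    """Ground-truth (G_exc, G_inh) traces for the neocortical pathway."""
    exc, inh = aip_kernels
    return (kernel_waveform(exc, analysis_timebase),
            kernel_waveform(inh, analysis_timebase))


@pytest.fixture
def noisefree_sweepset(aip_truth, analysis_timebase):
    gexc, ginh = aip_truth
    return simulate_voltage_clamp(gexc, ginh, analysis_timebase,
                                  noise=NoiseModel(current_sd_pA=0.0))


def preprocess(sweepset: SweepSet) -> SweepSet:
    """Background subtraction then repeat averaging (no cropping)."""
    sub = SweepSet([subtract_background(s) for s in sweepset.sweeps],
                   sweepset.condition, dict(sweepset.metadata))
    return average_repeats(sub)


@pytest.fixture
def reversals():
    return ReversalPotentials()
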