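import numpy as np
import pytest

from ecvtask import io as eio
from ecvtask import pipeline
from ecvtask.sequence import (GridSpec, SequenceParams, TissueParams,
                              build_dictionary, compute_t1_basis)


@pytest.fixture(scope="session")
def seq():
    return SequenceParams()


@pytest.fixture(scope="session")
def seq_small():
    """Short sequence for cheap brute-force checks."""
    return SequenceParams(matrix=32, readouts_per_period=64,
                          recovery_period=448.0, n_ir_pulses=4)


@pytest.fixture(scope="session")
def tissue():
    return TissueParams(t1_pre=1600.0, t1_post=800.0, m0=1.0, alpha=5.0, b=-1.0)


@pytest.fixture(scope="session")
def small_dictionary(seq):
    return build_dictionary(GridSpec.reduced(21, 5, 5), seq)


@pytest.fixture(scope="session")
def t1_basis(small_dictionary):
    return compute_t1_basis(small_dictionary, rank=12)


@pytest.fixture(scope="session")
def tiny_cfg():
    return eio.tiny_config(seed=5)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cfg):
    return pipeline.simulate(tiny_cfg)


def brute_force_block(t1, alpha_deg, b, m0, m_init, seq):
    """Independent per-TR stepping oracle for the IR-FLASH block.

    Inversion scales m by (1+2b); readout n at (n-1)*TR after inversion;
    excitation scales longitudinal magnetization by cos(alpha); relaxation
    toward m0 with E1 between excitations.
    """
    import math

    e1 = math.exp(-seq.tr / t1)
    a = math.radians(alpha_deg)
    m = (1.0 + 2.0 * b) * m_init
    signals = []
    trace = []
    for _ in range(seq.readouts_per_period):
        trace.append(m)
        signals.append(math.sin(a) * m)
        m = m * math.cos(a)
        m = m0 * (1.0 - e1) + e1 * m
    t_tail = seq.recovery_period - (seq.readouts_per_period - 1) * seq.tr
    # undo the last TR relaxation, apply the true tail relaxation instead
    m_after_exc = (m - m0 * (1.0 - e1)) / e1
    e1t = math.exp(-t_tail / t1)
    m_end = m0 * (1.0 - e1t) + e1t * m_after_exc
    return np.array(trace), np.array(signals), m_end
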