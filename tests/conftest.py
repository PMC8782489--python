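import numpy as np
import pytest

import groovetherm as gt


@pytest.fixture(scope="session")
def seq1_traj():
    """Ideal AT-rich (10% GC) duplex fixture, one noiseless frame."""
    return gt.gen_ideal_duplex_traj(gt.SEQ1_AT_RICH)


@pytest.fixture(scope="session")
def seq1_pairing(seq1_traj):
    return seq1_traj.meta["pairing"]


@pytest.fixture(scope="session")
def seq1_frames(seq1_traj, seq1_pairing):
    return gt.compute_bp_frames(seq1_traj, seq1_pairing)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
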