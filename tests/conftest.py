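import numpy as np
import pytest

from engramnet.connectivity import build_connectivity
from engramnet.experiments import train_single_stimulus, train_two_stimuli
from engramnet.measures import detect_assembly
from engramnet.params import ModelParams


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def small_params():
    """A 6x6 memory grid with 12 inputs: same dynamics, much cheaper."""
    return ModelParams(nM=36, grid_shape=(6, 6), nI=12, fanin=4, radius=1.5)


@pytest.fixture(scope="session")
def small_conn(small_params):
    return build_connectivity(small_params, np.random.default_rng(0))


@pytest.fixture(scope="session")
def trained_batch(default_params):
    """Ten single-stimulus trainings (fresh wiring per seed) shared by the
    acceptance checks on assembly size, wiring statistics and recall."""
    out = []
    for seed in range(1, 11):
        record, conn, s1 = train_single_stimulus(seed, default_params)
        ha = detect_assembly(record, conn, s1, "test1")
        out.append({"seed": seed, "record": record, "conn": conn,
                    "stimulus": s1, "assembly": ha})
    return out


@pytest.fixture(scope="session")
def two_stimulus_batch(default_params):
    """Full two-phase runs at disparities 1.0 and 0.2, ten seeds each."""
    out = {}
    for disparity in (1.0, 0.2):
        runs = []
        for seed in range(1, 11):
            record, conn, s1, s2 = train_two_stimuli(seed, disparity,
                                                     default_params)
            runs.append({"seed": seed, "record": record, "conn": conn,
                         "s1": s1, "s2": s2})
        out[disparity] = runs
    return out
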