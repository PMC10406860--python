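import numpy as np
import pytest

from wfrquant.protocols import (
    CONDENSED,
    SPARSE,
    NoiseSpec,
    ScenarioSpec,
    default_truth,
)
from wfrquant.ratio import aggregate_trials, session_fc, sum_frames
from wfrquant.synthetic import generate_session

FRAME = (64, 64)
PIXEL_AREA = (7.0 / 64) ** 2


@pytest.fixture(scope="session")
def silent_scenario():
    return ScenarioSpec(1, "baseline", noise=NoiseSpec.silent())


@pytest.fixture(scope="session")
def truth64():
    return default_truth(FRAME)


@pytest.fixture(scope="session")
def noisefree_sparse(silent_scenario, truth64):
    """Aggregated FC series of a noise-free sparse session (2 trials)."""
    stack, record = generate_session(
        SPARSE, silent_scenario, truth64, n_trials=2, frame_size=FRAME, seed=1
    )
    agg = aggregate_trials(session_fc(sum_frames(stack, 5)))
    return agg, record


@pytest.fixture(scope="session")
def noisefree_condensed(silent_scenario):
    truth = default_truth(FRAME, "condensed")
    stack, record = generate_session(
        CONDENSED, silent_scenario, truth, n_trials=2, frame_size=FRAME, seed=1
    )
    agg = aggregate_trials(session_fc(sum_frames(stack, 5)))
    return agg, record
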