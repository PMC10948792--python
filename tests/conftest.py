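import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from emocue.tables import PriorVector, ProbabilityTable

settings.register_profile(
    "emocue",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("emocue")

THREE_EMOTIONS = ("anger", "fear", "happiness")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_prior():
    return PriorVector(THREE_EMOTIONS, np.array([0.5, 0.25, 0.25]))


def random_table(rng, n_stimuli=20, emotions=THREE_EMOTIONS, concentration=1.0):
    values = rng.dirichlet(np.full(len(emotions), concentration), size=n_stimuli)
    ids = [f"s{i:03d}" for i in range(n_stimuli)]
    return ProbabilityTable(ids, emotions, values)


def make_ratings(rows):
    """Long-format frame from (pid, sid, condition, emotion, presence, intensity)."""
    return pd.DataFrame(
        rows,
        columns=["participant_id", "stimulus_id", "condition", "emotion",
                 "presence", "intensity"],
    )
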