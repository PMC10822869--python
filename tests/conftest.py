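import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from emodo import core_data, model, synthgen

settings.register_profile(
    "default", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def index():
    return model.ConditionIndex.standard()


@pytest.fixture(scope="session")
def small_index():
    return model.ConditionIndex.standard(("Anger", "Fear"))


@pytest.fixture(scope="session")
def small_dataset(small_index):
    """20 participants, 2 emotions, a few SPQ completers; paper-like truth."""
    spec = synthgen.DesignSpec(n_dop=10, n_nop=10, emotions=("Anger", "Fear"),
                               spq_completers=(6, 5), seed=42)
    ds, truth = synthgen.simulate_study(spec, preset="paper-like")
    return ds, truth, spec


@pytest.fixture(scope="session")
def tiny_dataset(index):
    """Five hand-written trials over the full index, no SPQ."""
    df = pd.DataFrame({
        "participant_id": ["p1", "p1", "p1", "p2", "p2"],
        "group": ["DOP", "DOP", "DOP", "NOP", "NOP"],
        "feedback": ["NoFeedback", "NoFeedback", "Feedback",
                     "NoFeedback", "Feedback"],
        "emotion": ["Anger", "Fear", "Anger", "Happiness", "Sadness"],
        "actor_id": [1, 2, 3, 4, 5],
        "trial_index": [1, 2, 3, 4, 5],
        "rt_seconds": [10.0, 5.0, 2.5, 7.5, 10.0 / np.e],
        "correct": [1, 0, 1, 1, 0],
    })
    return core_data.Dataset(trials=df)
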