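import numpy as np
import pytest

from graspfuse import (
    TrialSpec,
    make_templates,
    synth_emg_trial,
    synth_mvc,
    synth_trial,
)


@pytest.fixture(scope="session")
def templates():
    return make_templates(13, 12, seed=7)


@pytest.fixture(scope="session")
def template(templates):
    return templates[4]  # gesture 5


@pytest.fixture(scope="session")
def emg_trial(template):
    spec = TrialSpec(gesture_id=5, seed=3)
    return synth_emg_trial(spec, template)


@pytest.fixture(scope="session")
def multimodal_trial(template):
    spec = TrialSpec(gesture_id=5, seed=3)
    return synth_trial(spec, template)


@pytest.fixture(scope="session")
def mvc_trial(template):
    return synth_mvc(template, seed=9)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
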