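import logging
import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import enmpipe as ep

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# sklearn convergence chatter is irrelevant to the assertions here
warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)
logging.getLogger("enmpipe").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_scene():
    """A 40x40 synthetic environment shared across tests (read-only)."""
    return ep.generate_env(n_rows=40, n_cols=40, seed=7)


@pytest.fixture(scope="session")
def strong_spec(small_scene):
    """A rare, steep, climate-driven virtual species on the shared scene."""
    return ep.strong_species(small_scene)


@pytest.fixture(scope="session")
def small_score_stacks(small_scene):
    """PCA score stacks (current only) for the shared scene."""
    settings_ = ep.RunSettings(seed=0)
    _, _, stacks = ep.build_score_stacks(small_scene.stack, {}, settings_)
    return stacks
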