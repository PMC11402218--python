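import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from wfopto import preprocess
from wfopto.synth import SimConfig, generate_session

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

# ridge path / dff warnings about skipped zero-variance targets are expected
# on tiny fixtures; keep test output readable
warnings.filterwarnings("ignore", message=".*zero test variance.*")


@pytest.fixture(scope="session")
def small_session():
    """16x16, 80-trial default-noise session shared across tests."""
    cfg = SimConfig(n_pixels_y=16, n_pixels_x=16, n_trials=80, seed=42)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def small_dff(small_session):
    return preprocess.compute_dff(small_session.stack, small_session.trials)


@pytest.fixture(scope="session")
def opto_session():
    """32x32 session with global-excitation optogenetics."""
    cfg = SimConfig(n_pixels_y=32, n_pixels_x=32, n_trials=200, seed=7,
                    opto_regime="global_excite")
    return generate_session(cfg)


@pytest.fixture(scope="session")
def opto_dff(opto_session):
    return preprocess.compute_dff(opto_session.stack, opto_session.trials)


def make_trials(outcomes, sides=None, opto=None):
    """Minimal schema-complete trial table from outcome labels."""
    n = len(outcomes)
    if sides is None:
        sides = ["contra" if i % 2 == 0 else "ipsi" for i in range(n)]
    lick_side = [s if o == "correct" else
                 (None if o == "omission" else ("ipsi" if s == "contra" else "contra"))
                 for o, s in zip(outcomes, sides)]
    return pd.DataFrame({
        "trial_id": np.arange(n),
        "stimulus_side": sides,
        "first_lick_side": lick_side,
        "first_lick_time": [np.nan if o == "omission" else 2.1 for o in outcomes],
        "outcome": outcomes,
        "opto": opto if opto is not None else ["off"] * n,
        "session_id": "t",
    })
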