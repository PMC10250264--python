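import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import flankrel as fr

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params():
    return fr.GenerativeParams(seed=20260924, n_participants=60)


@pytest.fixture(scope="session")
def trials(default_params):
    """A moderate two-session dataset under the default generative profile."""
    return fr.simulate_dataset(default_params)


@pytest.fixture(scope="session")
def flagged(trials):
    return fr.flag_rt_exclusions(trials)


@pytest.fixture(scope="session")
def scores(flagged):
    s, dropped = fr.score_dataset(flagged)
    assert len(dropped) == 0
    return s


@pytest.fixture(scope="session")
def calibrated_params():
    """Default generative profile with sd_effect set so the ground-truth
    reliability of the 160-trial flanker effect is 0.60."""
    base = fr.GenerativeParams(seed=0, n_participants=200)
    return fr.with_true_reliability(base, 0.6, trials_per_condition=160,
                                    n_sim=3000)


def make_trials(rows):
    """Minimal hand-built trial table; rows are dicts overriding defaults."""
    base = {
        "participant": 1, "group": "g", "session": 1, "block": "main1",
        "trial": 0, "condition": "congruent", "direction": "left",
        "fixation_ms": 500, "rt_ms": 400.0, "correct": True,
    }
    out = []
    for i, r in enumerate(rows):
        row = dict(base)
        row.update(r)
        row["trial"] = r.get("trial", i)
        out.append(row)
    return pd.DataFrame(out)
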