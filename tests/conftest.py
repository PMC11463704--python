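import numpy as np
import pandas as pd
import pytest

from splitprev import (PopulationModel, builtin_design, draw_population,
                       simulate_trials)
from splitprev.designs import ConditionLevel, StudyDesign


@pytest.fixture(scope="session")
def exp1a():
    return builtin_design("exp1a")


@pytest.fixture(scope="session")
def mini_design():
    """A 2-level catch-trial design small enough for exhaustive checks."""
    levels = (
        ConditionLevel((("frame_speed", 10.0),), 12, 4),
        ConditionLevel((("frame_speed", 30.0),), 12, 4),
    )
    return StudyDesign("mini", 3, levels, "commission", "frame_speed")


@pytest.fixture(scope="session")
def mini_trials(mini_design):
    model = PopulationModel(gamma=0.5, commission_mean=0.05, seed=11)
    profiles = draw_population(model, mini_design, seed=11)
    return simulate_trials(profiles, mini_design, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def hand_trials(rows, design_id="mini"):
    """Build a trial table from (participant, level, type, response) tuples."""
    recs = []
    for i, (pid, level, ttype, resp) in enumerate(rows):
        recs.append({
            "participant_id": pid,
            "design_id": design_id,
            "trial_index": i,
            "trial_type": ttype,
            "level_index": level,
            "frame_speed": 10.0 if level == 0 else 30.0,
            "flash_opacity": pd.NA,
            "attention_block": pd.NA,
            "n_presented": 0 if ttype == "catch" else 1,
            "response": resp,
        })
    return pd.DataFrame.from_records(recs)
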