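import numpy as np
import pandas as pd
import pytest

import gaitasym as g
from gaitasym.simulate import GaitProfile


@pytest.fixture(scope="session")
def mouse_profile():
    return GaitProfile.mouse()


@pytest.fixture(scope="session")
def noiseless_trial():
    """One zero-noise symmetric mouse trial (all four limbs)."""
    prof = GaitProfile.mouse().noiseless()
    return g.generate_trial(prof, n_strides=20, seed=11)


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_trial):
    return g.build_dataset(noiseless_trial)


@pytest.fixture(scope="session")
def unilateral_cohort():
    """Seeded unilateral-lesion cohort: baseline + lesioned conditions."""
    prof, conds = g.scenario("unilateral")
    return g.make_cohort(prof, n_subjects=12, conditions=conds,
                         n_trials=4, strides_per_trial=12, seed=3)


@pytest.fixture(scope="session")
def unilateral_dataset(unilateral_cohort):
    return g.filter_speed_range(g.build_dataset(unilateral_cohort), 3, 16)


def simple_events(rows):
    """rows: (limb, position, stance_onset, swing_onset)."""
    return pd.DataFrame(
        [
            {
                "subject_id": "s1",
                "condition": "baseline",
                "trial_id": "t1",
                "limb": limb,
                "position": x,
                "stance_onset": st,
                "swing_onset": sw,
            }
            for limb, x, st, sw in rows
        ]
    )
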