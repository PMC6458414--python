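import numpy as np
import pandas as pd
import pytest

import latflow as lf


@pytest.fixture(scope="session")
def person_effect_dataset():
    """One-factor (stable person effect) LI data, n = 60, reliability ~0.64."""
    gen = lf.GenerativeParams.person_effect(sd_person=0.8, sd_error=0.6)
    return lf.simulate_li_dataset(gen, 60, seed=202)


@pytest.fixture(scope="session")
def quiet_recording():
    """Noise-free six-task recording with the default evoked amplitudes."""
    plan = lf.RecordingPlan(noise_sd_cm_s=0.0)
    return plan, lf.simulate_recording(plan, seed=7)


@pytest.fixture()
def toy_epoch():
    """A hand-built 825-sample epoch on the standard peristimulus grid."""
    def make(left=None, right=None, task="B"):
        n = 825
        times = -7.0 + np.arange(n) / 25.0
        left = np.full(n, 100.0) if left is None else np.asarray(left, float)
        right = np.full(n, 100.0) if right is None else np.asarray(right, float)
        return lf.TrialEpoch(task=task, trial_index=1, times=times,
                             left=left.copy(), right=right.copy())
    return make


@pytest.fixture(scope="session")
def small_table():
    """A complete 20-subject table with mild task differences."""
    gen = lf.GenerativeParams.task_effect()
    return lf.simulate_li_dataset(gen, 20, seed=5).table
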