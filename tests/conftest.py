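import numpy as np
import pytest

from melaphase.profile_core import SampleSeries, PMOL_PER_L
from melaphase.synthetic_data import SubjectScenario, simulate_subject

#: One seed for every seeded test in the suite.
SEED = 20260925


@pytest.fixture(scope="session")
def noiseless_subject():
    """Three noiseless days with 0.15 h/day drift (period 24.15 h)."""
    sc = SubjectScenario(noise_cv=0.0, seed=SEED, subject_id="NL1")
    return simulate_subject(sc)


@pytest.fixture(scope="session")
def noisy_day():
    """One day with the default 10% assay noise."""
    sc = SubjectScenario(noise_cv=0.10, amplitude_scale=1.5, n_days=1,
                         seed=SEED, subject_id="NY1")
    return simulate_subject(sc)[0][0]


@pytest.fixture()
def square_pulse():
    """Hourly square-ish pulse: 0 outside [22, 30], 100 inside, 25 samples
    on [13, 37]."""
    t = np.arange(13.0, 38.0, 1.0)
    c = np.where((t >= 22) & (t <= 30), 100.0, 0.0)
    return SampleSeries("sq", 1, t, c, PMOL_PER_L)
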