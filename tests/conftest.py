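import pytest
from hypothesis import settings

import cypscreen as cs

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def score_records():
    """A labeled synthetic reference set, capped for training."""
    recs = cs.generate_scores(cs.ScoreGenConfig(n=2000, seed=11))
    return cs.cap_scores(recs)


@pytest.fixture(scope="session")
def labels(score_records):
    return [r.label is cs.Label.INHIBITOR for r in score_records]


@pytest.fixture(scope="session")
def reported_thresholds():
    """The published threshold set of the CYP1A1 screening model."""
    return cs.ThresholdSet(t_sab=-23.0, t_ob=-3.29, t_sob=-27.0, t_wob=-19.0)


@pytest.fixture(scope="session")
def kinetics_plate():
    return cs.generate_kinetics(cs.KineticsGenConfig(seed=5))
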