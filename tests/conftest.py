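import logging

import pytest

from hrvfatigue.pipeline import features_from_recordings
from hrvfatigue.synthetic import CohortConfig, generate_cohort

logging.getLogger("hrvfatigue").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def shifted_features():
    """Feature matrix of a small shifted cohort (3+3 subjects, 20 min,
    changepoint at minute 10, perfect raters): both labels present for both
    sexes, alert/fatigued distributions separated as calibrated."""
    cfg = CohortConfig(
        n_male=3, n_female=3, duration_s=1200.0, fatigue_onset_s=600.0,
        rater_error_rate=0.0, seed=11,
    )
    features, _ = features_from_recordings(generate_cohort(cfg), duration_s=1200.0)
    return features
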