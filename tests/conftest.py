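import numpy as np
import pandas as pd
import pytest

from ebmseq import alteration, synthetic


@pytest.fixture(scope="session")
def recovery_cohort():
    """Standard noisy cohort: 20 events, 200 patients, steep onsets."""
    cfg = synthetic.recovery_config(seed=11)
    cohort, gt = synthetic.generate_cohort(cfg)
    return cfg, cohort, gt


@pytest.fixture(scope="session")
def fitted_weights(recovery_cohort):
    cfg, cohort, gt = recovery_cohort
    model = alteration.fit_normative(cohort[cohort["group"] == "control"])
    w = alteration.compute_weights(cohort[cohort["group"] == "patient"], model)
    return w


@pytest.fixture(scope="session")
def guttman_cohort():
    """Noise-free nested-pattern cohort: every patient is a prefix of the order."""
    cfg = synthetic.guttman_config(n_events=12, n_patients=120, seed=4)
    cohort, gt = synthetic.generate_cohort(cfg)
    w = synthetic.binary_alteration_matrix(cohort, cfg)
    return cfg, cohort, gt, w


@pytest.fixture
def binary_fixture():
    """10 patients x 6 events, hand-fixed binary weights for counting oracles."""
    rng = np.random.default_rng(2024)
    w = pd.DataFrame(
        (rng.random((10, 6)) < np.linspace(0.8, 0.2, 6)[None, :]).astype(float),
        columns=[f"e{i}" for i in range(6)],
        index=[f"p{i}" for i in range(10)],
    )
    return w
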