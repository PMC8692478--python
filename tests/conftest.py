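import numpy as np
import pytest

import bgpredict as bp
from bgpredict.model import ModelConfig
from bgpredict.pipeline import RunConfig, preprocess_patient, _patient_windows
from bgpredict.tcn import TCNConfig


@pytest.fixture(scope="session")
def cohort():
    return bp.sample_cohort(3, 11)


@pytest.fixture(scope="session")
def short_series(cohort):
    """Three days of one virtual patient (noise-free truth included)."""
    return bp.simulate_patient(cohort[0], 3)


@pytest.fixture(scope="session")
def tiny_config():
    """A small but structurally complete model configuration."""
    return ModelConfig(p1=12, p2=4, p3=12, p4=12, f=3,
                       tcn=TCNConfig(n_filters=8, dilations=(1, 2),
                                     spatial_dropout_rate=0.1),
                       max_epochs=5, early_stop_patience=5, train_stride=2,
                       seed=3)


@pytest.fixture(scope="session")
def tiny_patient_windows(cohort, tiny_config):
    """(train, test, scaler) windows of a 3-day patient for the tiny model."""
    series = bp.simulate_patient(cohort[1], 3)
    run_cfg = RunConfig(n_days=3)
    train_segs, test_segs, scaler = preprocess_patient(series, run_cfg)
    train_w, test_w = _patient_windows(train_segs, test_segs, scaler,
                                       tiny_config)
    return train_w, test_w, scaler


def assert_series_equal(a, b):
    np.testing.assert_array_equal(a.cgm, b.cgm)
    np.testing.assert_array_equal(a.basal, b.basal)
    np.testing.assert_array_equal(a.bolus, b.bolus)
    np.testing.assert_array_equal(a.carbs, b.carbs)
    assert a.calibrations == b.calibrations
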