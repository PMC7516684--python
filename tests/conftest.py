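import pytest

from gaitsole import (
    SegmentationConfig,
    TrialMeta,
    default_control_config,
    default_patient_config,
    simulate_tug_trial,
)


def noise_free(config_factory, **kw):
    kw.setdefault("pressure_noise_sd_Ncm2", 0.0)
    kw.setdefault("accel_noise_sd", 0.0)
    kw.setdefault("gyro_noise_sd", 0.0)
    return config_factory(**kw)


@pytest.fixture(scope="session")
def control_trial_noise_free():
    cfg = noise_free(default_control_config)
    return simulate_tug_trial(cfg, seed=11)


@pytest.fixture(scope="session")
def control_trial_default_noise():
    return simulate_tug_trial(default_control_config(), seed=12)


@pytest.fixture(scope="session")
def patient_trial_default_noise():
    meta = TrialMeta(subject_id="P01", group="patient", affected_side="left")
    cfg = default_patient_config("left")
    trial, truth = simulate_tug_trial(cfg, seed=13, meta=meta)
    return trial, truth, cfg


@pytest.fixture
def seg_cfg():
    return SegmentationConfig()
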