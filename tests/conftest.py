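import numpy as np
import pytest

from mvep_adapt import (CalibrationConfig, DriftModel, ParadigmConfig,
                        PreprocessConfig, WaveModel, preprocess_session,
                        simulate_session)


@pytest.fixture(scope="session")
def toy_features():
    """Linearly separable 2-D toy set: class 0 around (-1,-1), class 1
    around (1,1)."""
    rng = np.random.default_rng(7)
    n = 30
    x0 = rng.normal(-1.0, 0.2, size=(n, 2))
    x1 = rng.normal(1.0, 0.2, size=(n, 2))
    X = np.vstack([x0, x1])
    y = np.array([0] * n + [1] * n)
    return X, y


@pytest.fixture(scope="session")
def small_paradigm():
    return ParadigmConfig(n_blocks=12)


@pytest.fixture(scope="session")
def small_subject(small_paradigm):
    """A 12-block stable training session and a 12-block drifting test
    session, preprocessed to per-block button averages."""
    wave = WaveModel()
    train = simulate_session(small_paradigm, wave, DriftModel(kind="none"),
                             seed=11)
    test = simulate_session(
        small_paradigm, wave,
        DriftModel(kind="linear", magnitude=0.02,
                   aspects=("latency", "topography")),
        seed=12)
    pre = PreprocessConfig()
    averaged_train, _ = preprocess_session(train, pre)
    averaged_test, _ = preprocess_session(test, pre)
    return {
        "train": train,
        "test": test,
        "averaged_train": averaged_train,
        "averaged_test": averaged_test,
        "targets": test.target_buttons,
    }


@pytest.fixture()
def default_cfg():
    return CalibrationConfig()


@pytest.fixture(scope="session")
def tiny_study():
    from mvep_adapt.experiments import drift_recovery_study
    return drift_recovery_study(n_seeds=2, base_seed=77)
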