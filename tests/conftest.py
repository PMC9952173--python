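import numpy as np
import pytest

from tstn_bci import ErdModel, PreprocConfig, SessionSpec, assemble_epochs, preprocess
from tstn_bci.synth import generate_session


@pytest.fixture(scope="session")
def preproc_cfg():
    return PreprocConfig()


@pytest.fixture(scope="session")
def small_aomi():
    """20-trial AO+MI session generated at 250 Hz: (raw, timeline, labels)."""
    spec = SessionSpec(session_kind="ao_mi", n_trials=20,
                       sampling_rate=250.0, seed=42)
    return generate_session(spec, ErdModel(erd_depth=0.4))


@pytest.fixture(scope="session")
def small_aomi_epochs(small_aomi, preproc_cfg):
    raw, timeline, _ = small_aomi
    return assemble_epochs(preprocess(raw, preproc_cfg), timeline, preproc_cfg)


@pytest.fixture(scope="session")
def full_aomi_epochs(preproc_cfg):
    """The full calibration-session design: 300 trials (150 left / 150 right),
    yielding 900 training epochs (300 per class) plus the 300-epoch
    feedback-free MI test set.  Generated at 250 Hz."""
    spec = SessionSpec(session_kind="ao_mi", n_trials=300,
                       sampling_rate=250.0, seed=2024)
    raw, timeline, _ = generate_session(spec, ErdModel(erd_depth=0.4))
    return assemble_epochs(preprocess(raw, preproc_cfg), timeline, preproc_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
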