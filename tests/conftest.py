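import numpy as np
import pytest

from murisleep import PhotoperiodSchedule
from murisleep import sigproc, staging, synth


@pytest.fixture(scope="session")
def schedule():
    return PhotoperiodSchedule()


@pytest.fixture(scope="session")
def state_specs():
    return synth.default_state_specs()


@pytest.fixture(scope="session")
def scored_session(schedule, state_specs):
    """A 4-h synthetic recording with truth hypnogram, features and fitted
    templates, shared across staging/metrics tests."""
    light, dark = synth.default_transition_matrices()
    hyp = synth.simulate_hypnogram(schedule, light, dark, duration_hours=4, seed=11)
    rec = synth.synthesize_signals(hyp, state_specs, fs=100.0, seed=12)
    feats = sigproc.extract_features(rec, condition=False)
    templates = staging.fit_templates(feats)
    return {
        "hypnogram": hyp,
        "recording": rec,
        "features": feats,
        "templates": templates,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
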