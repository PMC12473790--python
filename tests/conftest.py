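import numpy as np
import pytest

from cate.synth import SynthConfig, generate_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def tiny_corpus():
    """Small, fast corpus: 2 subjects, 6 trials, 8 channels."""
    cfg = SynthConfig(
        n_subjects=2,
        n_trials_per_subject=6,
        samples_per_trial=8,
        n_channels=8,
        noise_sd=0.3,
        seed=7,
    )
    return generate_corpus(cfg)
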