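import numpy as np
import pytest

from sleepentrain.synth import CohortConfig


@pytest.fixture
def small_cfg() -> CohortConfig:
    """A fast cohort: 4 words (1 once + 1 repeated per half), short tail."""
    return CohortConfig(n_participants=3, n_words=4, n_repeats=2,
                        lead_in=6.0, tail=4.0, seed=11)


@pytest.fixture
def clean_cfg() -> CohortConfig:
    """Noise-free generator: evoked components only, every trial entrained,
    no trial-to-trial variability."""
    return CohortConfig(n_participants=2, n_words=4, n_repeats=2,
                        lead_in=6.0, tail=4.0, seed=7,
                        noise_sd=0.0, spont_so_rate=0.0,
                        evoked_amp_within_sd=0.0, entrain_prob=1.0,
                        spindle_amp=0.0, evoked_amp_sd=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
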