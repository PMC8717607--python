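import numpy as np
import pytest
from hypothesis import settings

from mudia.acquisition import build_window_scheme
from mudia.synthdata import SimConfig, generate_proteome

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    """The study's 59-window overlapped DIA scheme."""
    return build_window_scheme(436, 900, 8, 12)


@pytest.fixture(scope="session")
def small_truth():
    return generate_proteome(12, seed=11, pathway_size=4, pathway_log2fc=1.0,
                             n_null_pathways=2)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(gradient_length=150.0)


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free configuration for exact-recovery checks."""
    return SimConfig(replicate_cv=0.0, missing_rate=0.0,
                     noise_peaks_per_scan=0, rt_jitter_sd=0.0,
                     gradient_length=150.0)
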