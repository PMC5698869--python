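import numpy as np
import pytest

from mmrkit.erp.containers import PreprocessConfig
from mmrkit.panel import load_panel
from mmrkit.simulate.eeg import ERPTemplateModel


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture
def noiseless_model():
    """Template model with every stochastic component switched off."""
    return ERPTemplateModel(noise_sigma_uv=0.0, alpha_amp_uv=0.0,
                            artifact_rate=0.0, subject_sigma_uv=0.0)


@pytest.fixture
def identity_config():
    """Preprocessing with filters and resampling disabled: epoching, baseline
    correction and averaging only (for analytic round-trip checks)."""
    return PreprocessConfig(lowpass_hz=None, highpass_hz=None, resample_hz=None)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
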