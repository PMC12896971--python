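import numpy as np
import pytest

from quadrasense.synth import SynthConfig, generate_dataset, generate_patch


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions shared across tests: 64-px patches,
    compact nuclei and mitotic figures, matching ROI radius."""
    return SynthConfig(patch_size=64, n_patches=24, mitosis_prob=0.5, seed=11,
                       nucleus_radius=4.0, mitosis_radius=5.0, roi_radius=6)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def clean_mitotic_patch():
    """A noise-free mitotic patch with known stain vectors."""
    cfg = SynthConfig(patch_size=64, noise_sd=0.0, seed=5,
                      nucleus_radius=4.0, mitosis_radius=5.0, roi_radius=6)
    return cfg, generate_patch(cfg, label=1, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
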