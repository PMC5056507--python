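import numpy as np
import pytest

from spnradiomics import CohortSpec, generate_nodule, refine_roi
from spnradiomics.synthetic import DegradationParams, TextureParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_spec():
    """A small but otherwise default cohort specification."""
    return CohortSpec(n_benign=3, n_malignant=3, seed=7, image_size=48)


@pytest.fixture
def quiet_spec():
    """Deterministic degenerate spec: constant texture, no degradation."""
    tex = TextureParams(base_hu=25.0, sd_hu=0.0, corr_len=2.0, sd_spread=0.0, corr_spread=0.0)
    return CohortSpec(
        n_benign=2,
        n_malignant=2,
        seed=3,
        image_size=48,
        background_noise_sd=0.0,
        texture_params={"benign": tex, "malignant": tex},
        degradation_params=DegradationParams(
            contrast_offset_hu=0.0,
            confound_strength=0.0,
            pv_blur_px_per_ratio=0.0,
            sharpen_amount=0.0,
            kernel_noise_sd_hu=0.0,
        ),
    )


@pytest.fixture
def nodule(small_spec):
    image, mask = generate_nodule("malignant", 1, small_spec, subject_seed=0)
    return image, refine_roi(image, mask)
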