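import numpy as np
import pytest

from sglmri import SyntheticSpec, generate, preprocess_pipeline


@pytest.fixture(scope="session")
def small_dataset():
    """A small, clean synthetic dataset (no jitter/outliers) with its prep."""
    spec = SyntheticSpec(
        grid_shape=(8, 8, 4), n_areas=8, n_per_class=12, active_areas=(1, 2),
        effect_size=2.0, smooth_sigma=0.0, jitter_max=0, noise_sd=1.0,
        outlier_rate=0.0, seed=42,
    )
    ds = generate(spec)
    fm, groups, report = preprocess_pipeline(ds.features)
    return ds, fm, groups, report


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
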