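import numpy as np
import pytest

from fmrileak import CohortSpec, extract_slices, generate_subject_volume


@pytest.fixture(scope="session")
def tiny_spec():
    """Two-class desk cohort small enough for per-test generation."""
    return CohortSpec(
        n_per_class=3,
        class_labels=("CN", "AD"),
        volume_shape=(16, 16, 6, 4),
        fingerprint_sd=1.0,
        class_effect_sd=0.0,
        noise_sd=0.1,
        baseline=100.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_volume(tiny_spec):
    return generate_subject_volume(tiny_spec, "sub-CN-000", "CN")


@pytest.fixture(scope="session")
def tiny_stack(tiny_volume):
    return extract_slices(tiny_volume)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
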