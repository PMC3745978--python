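import numpy as np
import pytest
from hypothesis import settings

from abcfs import LabeledMatrix, SynthSpec, generate

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def separable_data() -> LabeledMatrix:
    """Two 2-D Gaussian classes 10 sigma apart: effectively noiseless."""
    data, _, _ = generate(
        SynthSpec(
            n_per_class=(40, 40),
            n_informative=2,
            n_noise=0,
            class_separation=10.0,
            seed=7,
        )
    )
    return data


@pytest.fixture
def noisy_fixture():
    """The default benchmark: 3 informative + 7 noise features."""
    data, informative, _ = generate(SynthSpec(seed=2))
    return data, informative


def shuffled_labels(data: LabeledMatrix, seed: int) -> LabeledMatrix:
    """Copy of ``data`` with labels permuted independently of features."""
    rng = np.random.default_rng(seed)
    return LabeledMatrix(
        features=data.features.copy(),
        labels=rng.permutation(data.labels),
        class_set=data.class_set,
        feature_names=data.feature_names,
    )
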