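import numpy as np
import pytest

from methdeg import msdcnn
from methdeg.io import BetaMatrix, LabelSet
from methdeg.synthdata import CohortConfig, generate_binary_cohort, generate_multiclass_cohort

#: small-but-trainable CNN configuration used throughout the suite
TINY_MSDCNN = dict(
    blocks_per_branch=1,
    filters_per_block=(8,),
    dense_units=16,
    epochs=12,
)


@pytest.fixture(scope="session")
def binary_cohort():
    """Separable binary cohort: 100/class, 200 probes, 20 planted, delta 0.4."""
    cfg = CohortConfig(
        n_samples_per_class=100,
        n_cpgs=200,
        n_informative_per_class=20,
        effect_delta=0.4,
        precision=50.0,
        background_mean_range=(0.3, 0.7),
        seed=11,
    )
    return generate_binary_cohort(cfg)


@pytest.fixture(scope="session")
def multiclass_cohort():
    """Separable 4-class cohort: 60/class, 120 probes, 12 planted per class."""
    cfg = CohortConfig(
        n_samples_per_class=60,
        n_cpgs=120,
        n_informative_per_class=12,
        effect_delta=0.4,
        precision=50.0,
        background_mean_range=(0.3, 0.7),
        seed=13,
    )
    return generate_multiclass_cohort(cfg)


@pytest.fixture
def small_beta():
    rng = np.random.default_rng(0)
    values = rng.uniform(0, 1, size=(5, 7))
    return BetaMatrix(values, [f"s{i}" for i in range(5)], [f"cg{j}" for j in range(7)])
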