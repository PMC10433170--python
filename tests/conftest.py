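import warnings

import numpy as np
import pytest

from ssvep_tcsc.pipeline import RunConfig, analyze_dataset
from ssvep_tcsc.reference_tcsc import default_psychophysical_curve
from ssvep_tcsc.synthetic_eeg import DatasetConfig, generate_dataset


@pytest.fixture(scope="session")
def ref_curve():
    return default_psychophysical_curve()


@pytest.fixture(scope="session")
def small_dataset():
    """Compact two-experiment cohort used by pipeline-level tests."""
    config = DatasetConfig(experiments=(2, 3), cohort_sizes={2: 3, 3: 4})
    return generate_dataset(config, master_seed=11)


@pytest.fixture(scope="session")
def analyzed(small_dataset):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_dataset(small_dataset,
                               RunConfig(experiments=(2, 3)))


@pytest.fixture(scope="session")
def recovery_run():
    """Threshold-bracketing cohort (relative MD grid) with ground truth,
    for parameter-recovery checks."""
    config = DatasetConfig(experiments=(3,), cohort_sizes={3: 12})
    dataset = generate_dataset(config, master_seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = analyze_dataset(dataset, RunConfig(experiments=(3,)))
    return dataset, result


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
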