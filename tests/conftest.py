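import numpy as np
import pytest
from hypothesis import settings

import cerecpm as cc

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def parcels5():
    """Five parcels, two cerebellar — the smallest interesting COI setup."""
    return cc.ParcelTable(
        labels=("cb0", "cb1", "ctx0", "ctx1", "sc0"),
        groups=("cerebellar", "cerebellar", "cortical", "cortical", "subcortical"),
    )


@pytest.fixture(scope="session")
def small_spec():
    """A reduced cohort for fast unit-level pipeline tests."""
    return cc.SyntheticSpec(
        n_subjects=100,
        parcel_counts=(5, 10, 2),
        T=120,
        n_pos_edges=6,
        n_neg_edges=6,
        n_families=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    data, truth, _ = cc.generate_dataset(small_spec)
    return data, truth


@pytest.fixture(scope="session")
def default_run():
    """Default-condition cohort with a completed CPM run (shared, read-only)."""
    data, truth, _ = cc.generate_dataset(cc.SyntheticSpec(seed=3))
    result = cc.run_cpm(data, k=8, seed=3)
    return data, truth, result
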