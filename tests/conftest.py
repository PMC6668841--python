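import numpy as np
import pytest

from vistl.catalogue import default_catalogue
from vistl.encode import fit_imputation_stats, fit_normalizer
from vistl.models import make_split
from vistl.pipeline import prepare_cohort
from vistl.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def demo_catalogue():
    return default_catalogue("demo")


@pytest.fixture(scope="session")
def full_catalogue():
    return default_catalogue("full")


@pytest.fixture(scope="session")
def small_cohort():
    """400 admissions with observations; shared read-only across tests."""
    return generate_cohort(CohortConfig(n_admissions=400, seed=42))


@pytest.fixture(scope="session")
def small_split(small_cohort):
    return make_split(list(small_cohort.ids), seed=7)


@pytest.fixture(scope="session")
def small_prep(small_cohort, small_split):
    """Fitted stats + imputed native grids for the small cohort."""
    return prepare_cohort(small_cohort, small_split,
                          normalizations=("min_max", "custom"),
                          orderings=("standard", "within_group", "across_group"))


@pytest.fixture(scope="session")
def imputation_stats(small_cohort, small_split):
    return fit_imputation_stats(small_cohort, small_split.train_ids)


@pytest.fixture(scope="session")
def minmax_normalizer(small_prep):
    return small_prep.normalizers["min_max"]


@pytest.fixture(scope="session")
def custom_normalizer(small_prep):
    return small_prep.normalizers["custom"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
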