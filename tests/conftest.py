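import warnings

import pytest

from protegrate import synthetic_cohort as sc

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-sample, 200-gene cohort under the default study conditions."""
    spec = sc.default_cohort_spec(n_samples=60, n_genes=200, seed=1)
    return sc.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_spec():
    return sc.default_cohort_spec(n_samples=60, n_genes=200, seed=1)
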