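import numpy as np
import pytest

from semlink.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic world: 3 domains x 3 facets, 60 persons."""
    cfg = SimConfig(
        n_persons=60,
        n_domains=3,
        facets_per_domain=3,
        vocab_per_facet=6,
        embed_dim=32,
        terms_per_person=12,
        seed=101,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The canonical 5x6-facet world at a desk-scale sample size."""
    cfg = SimConfig(n_persons=150, seed=202)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
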