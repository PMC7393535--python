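import numpy as np
import pytest
from hypothesis import settings

from msical.simulate import CohortSpec, generate_reference

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """60 planted sites at 100x mean coverage; shared read-only across tests."""
    spec = CohortSpec(n_sites=60, coverage=100.0, seed=5)
    return generate_reference(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study design: 500 sites, 20 samples per group, 50x."""
    return generate_reference(CohortSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def est_tables(cohort, role, n_samples, rng, purity=None, depth_scale=1.0):
    """Per-sample {site_id: SlippageEstimate} tables from the fast path."""
    from msical.model import estimate_slippage
    from msical.simulate import generate_sample

    n_by_site = {t.site.site_id: t.site.n for t in cohort.truth}
    tables = []
    for _ in range(n_samples):
        dists = generate_sample(cohort, role, purity=purity, depth_scale=depth_scale, rng=rng)
        tables.append(
            {sid: estimate_slippage(d, n_by_site[sid]) for sid, d in dists.items() if d.m > 0}
        )
    return tables
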