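import numpy as np
import pytest

from connectogcn.connectome import fisher_z, pearson_connectivity, stack_edges
from connectogcn.synth import SynthConfig, generate_cohort, inject_site_effects


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Mixed 2-site cohort with a clear planted effect, shared across tests."""
    cfg = SynthConfig(
        n_regions=30,
        n_sites=3,
        site_sizes=((0, 24), (16, 10), (16, 10)),
        n_timepoints=150,
        signal_nodes=(3, 7, 11, 15, 19, 23),
        effect_size=0.4,
        site_shift=0.2,
        site_scale=0.1,
        seed=42,
    )
    records, series = generate_cohort(cfg)
    return cfg, records, series


@pytest.fixture(scope="session")
def small_edges(small_cohort):
    """Fisher-z edge table with injected site effects for the small cohort."""
    cfg, records, series = small_cohort
    mats = [
        fisher_z(pearson_connectivity(ts.values, subject_id=ts.subject_id))
        for ts in series
    ]
    edges = stack_edges(mats)
    sites = [r.site_id for r in records]
    injected, params = inject_site_effects(edges.to_numpy(), sites, cfg)
    return cfg, records, injected, np.array(sites), params, edges.to_numpy()
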