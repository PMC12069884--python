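import pytest
from hypothesis import HealthCheck, settings

import ntmemory as nt

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic experiment (seed 1): truth, counts, meta, bulk."""
    cfg = nt.SimConfig(seed=1)
    truth = nt.generate_truth(cfg)
    matrix, meta = nt.simulate_sc(truth, cfg)
    bulk = nt.simulate_bulk(truth, cfg)
    return cfg, truth, matrix, meta, bulk


@pytest.fixture(scope="session")
def default_de(default_sim):
    """Global NT-vs-IVF DE plus bulk donor/IVF statistics on the default run."""
    _, _, matrix, meta, bulk = default_sim
    de_sc = nt.nb_wald_de(matrix, meta)
    bulk_stats = nt.bulk_de(*bulk)
    return de_sc, bulk_stats
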