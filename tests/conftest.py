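import pytest

from contact_triad.inference_report import McmcConfig
from contact_triad.synthetic_data import SyntheticConfig, generate_survey
from contact_triad.triangles import enumerate_potential_triangles, trim_by_underlying_count


@pytest.fixture(scope="session")
def small_survey():
    """A small synthetic survey shared across tests: 5 locations x 4
    households, two visits, default generating truth."""
    cfg = SyntheticConfig(n_locations=5, households_per_location=4,
                          visits=(2, 3), seed=42)
    tables, truth = generate_survey(cfg)
    return cfg, tables, truth


@pytest.fixture(scope="session")
def small_triangles(small_survey):
    _, tables, _ = small_survey
    tri = enumerate_potential_triangles(tables["contact"], tables["triangle"])
    retained, _ = trim_by_underlying_count(tri)
    return retained


@pytest.fixture()
def tiny_mcmc():
    """Very short chains for smoke-level fits."""
    return McmcConfig(chains=2, iterations=240, warmup=120, seed=5,
                      max_treedepth=8)
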