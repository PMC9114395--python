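import pytest

from cryptphylo import simdata


@pytest.fixture(scope="session")
def default_cohort():
    """The default desk-scale cohort (8 crypts, 30X, seed 1): count
    matrix, variant table, and ground truth, shared across tests."""
    cfg = simdata.SimConfig(seed=1)
    matrix, variants, truth = simdata.simulate_cohort(cfg)
    return cfg, matrix, variants, truth


@pytest.fixture(scope="session")
def sbs_catalogue():
    from cryptphylo.catalogues import synthetic_sbs_catalogue
    return synthetic_sbs_catalogue()


@pytest.fixture(scope="session")
def id_catalogue():
    from cryptphylo.catalogues import synthetic_id_catalogue
    return synthetic_id_catalogue()
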