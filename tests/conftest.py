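"""Shared fixtures: models, solved reproductive values, ergodic distributions.

Everything is generated programmatically; session scope keeps the exact
enumeration work (chains, stationary solves) to one pass per run.
"""

import pytest

import rvfitness as rf


@pytest.fixture(scope="session")
def hd_model():
    return rf.make_haplodiploid()


@pytest.fixture(scope="session")
def hd_phi(hd_model):
    phi, diag = rf.solve_rv(hd_model)
    assert diag["residual"] <= 1e-10
    return phi


@pytest.fixture(scope="session")
def hd_full_chain(hd_model):
    return rf.full_chain(hd_model)


@pytest.fixture(scope="session")
def hd_D(hd_full_chain):
    return rf.ergodic_distribution(hd_full_chain)


@pytest.fixture(scope="session")
def hd_selective(hd_model):
    return rf.haplodiploid_selective_map(hd_model)


@pytest.fixture(scope="session")
def hd_background(hd_model):
    return rf.PhenotypeMap.uniform(
        hd_model.background,
        hd_model.class_space.classes,
        hd_model.genotype_space.genotypes,
    )


@pytest.fixture(scope="session")
def clonal_model():
    return rf.make_clonal(3)


@pytest.fixture(scope="session")
def age_model():
    return rf.make_age_density()


@pytest.fixture(scope="session")
def bethedge_model():
    return rf.make_bethedge()


@pytest.fixture(scope="session")
def bethedge_phi(bethedge_model):
    phi, _ = rf.solve_rv(bethedge_model)
    return phi


@pytest.fixture(scope="session")
def bethedge_D(bethedge_model):
    return rf.ergodic_distribution(rf.full_chain(bethedge_model))
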