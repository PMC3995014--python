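"""Shared fixtures.

The expensive end-to-end study (template database, groupwise template,
10-subject fusion experiment) is built once per session and reused by the
module tests and the acceptance tests alike.
"""
import pytest

from hippofuse.experiments import atrophy_study, build_study, fusion_study
from hippofuse.synthetic_data import PhantomSpec, make_phantom, make_template_database

SEED = 1234


@pytest.fixture(scope="session")
def study():
    """(database, groupwise template, pipeline config) at study scale."""
    return build_study(SEED)


@pytest.fixture(scope="session")
def fusion_table(study):
    db, template, config = study
    return fusion_study(db, template, config, n_subjects=10, seed=SEED)


@pytest.fixture(scope="session")
def atrophy_result(study):
    db, template, config = study
    return atrophy_study(db, template, config, seed=SEED, n_pairs=3)


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def clean_phantom():
    return make_phantom(PhantomSpec(seed=11, noise_sd=0.0, bias_amplitude=0.0))


@pytest.fixture(scope="session")
def small_db():
    return make_template_database(6, seed=7)
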