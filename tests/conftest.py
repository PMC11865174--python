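"""Shared fixtures: study-scale and large calibrated synthetic cohorts."""

import logging
import warnings

import pytest

from pvecophys.config import load_paper_defaults
from pvecophys.pipeline import build_trait_table, run_pipeline
from pvecophys.pv_analysis import fit_pv_table
from pvecophys.synthetic_cohort import generate_cohort

logging.getLogger("pvecophys").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def paper_config():
    return load_paper_defaults()


@pytest.fixture(scope="session")
def study_cohort(paper_config):
    """The field design: 2 species x 2 treatments x 5 plants, 6 campaigns."""
    return generate_cohort(paper_config, 42)


@pytest.fixture(scope="session")
def study_trait_table(study_cohort):
    return build_trait_table(study_cohort)


@pytest.fixture(scope="session")
def study_pipeline(paper_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(paper_config, seed=42)


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort (500 plants per cell) for mean-recovery checks."""
    config = load_paper_defaults()
    config.n_plants_per_cell = 500
    return generate_cohort(config, 42)


@pytest.fixture(scope="session")
def big_pv_params(big_cohort):
    params = fit_pv_table(big_cohort.pv_curves)
    return params[params["error"] == ""]
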