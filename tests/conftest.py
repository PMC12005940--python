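"""Shared synthetic-study fixtures: generated once, reused across tests."""

import pytest

import aerxover as ax


@pytest.fixture(scope="session")
def study_inputs():
    """Static inputs: parcels with seasonal AER, two years of exposures."""
    return ax.make_study_inputs(n_parcels=2000, n_cells=4,
                                span=("2009-12-01", "2011-12-31"), seed=11)


@pytest.fixture(scope="session")
def design_rows(study_inputs):
    """Design rows for 2,000 deaths under the default planted truth."""
    return ax.simulate_and_design(study_inputs, n_deaths=2000, seed=21).rows


@pytest.fixture(scope="session")
def interaction_fit(design_rows):
    return ax.fit_interaction(design_rows)
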