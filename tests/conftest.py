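"""Shared fixtures: expensive simulations are session-scoped so the
acceptance tests reuse one calibrated base run and one virtual population."""

from __future__ import annotations

import numpy as np
import pytest

from pbpkeo.analysis import locked_calibration, standard_model
from pbpkeo.parameters import load_params
from pbpkeo.pbpk import DoseRegimen, simulate_regimen


@pytest.fixture(scope="session")
def params():
    return load_params()


@pytest.fixture(scope="session")
def calibration():
    return locked_calibration()


@pytest.fixture(scope="session")
def base_result_80mg(params, calibration):
    """Mean-subject 80 mg OD × 14 d under the frozen calibration."""
    model = standard_model(params, calibration=calibration)
    return simulate_regimen(model, DoseRegimen(80.0, 24.0, 14))


@pytest.fixture(scope="session")
def population_frame():
    """The n=100, seed=1 reference population at 80 mg OD (used by the
    validation and population-statistics checks)."""
    from pbpkeo.acceptance_helpers import population_80mg
    return population_80mg(n=100, seed=1)


@pytest.fixture(scope="session")
def validation_outputs(population_frame):
    from pbpkeo.acceptance_helpers import run_validation
    records, summary, pop = run_validation(population=population_frame)
    return records, summary, pop
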