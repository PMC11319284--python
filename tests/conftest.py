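"""Shared fixtures.

Expensive artifacts (500 s single-cell equilibrations, the atrial
threshold-charge curve, small tissue runs) are session-scoped so the suite
pays for each exactly once; the package's own steady-state cache keeps them
shared with any further use.
"""

from __future__ import annotations

import numpy as np
import pytest

from sanfib.cellmodels import (CellParams, Phenotype, steady_state,
                               threshold_charge_curve)


@pytest.fixture(scope="session")
def san_params():
    return CellParams(Phenotype.SAN)


@pytest.fixture(scope="session")
def san_steady(san_params):
    return steady_state(san_params)


@pytest.fixture(scope="session")
def atrial_params_native():
    return CellParams(Phenotype.ATRIAL)


@pytest.fixture(scope="session")
def atrial_params_tissue():
    """Tissue atrial phenotype: crista-terminalis gNa doubling."""
    return CellParams(Phenotype.ATRIAL, multipliers={"gNa": 2.0})


@pytest.fixture(scope="session")
def atrial_steady_native(atrial_params_native):
    return steady_state(atrial_params_native)


@pytest.fixture(scope="session")
def fibroblast_steady():
    return steady_state(CellParams(Phenotype.FIBROBLAST))


@pytest.fixture(scope="session")
def qthr_curve_native(atrial_params_native):
    return threshold_charge_curve(atrial_params_native)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240730)
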