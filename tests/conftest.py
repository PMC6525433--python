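"""Shared fixtures.

The expensive coupled simulations (base case to 600 s, the comparison
parameter set, and the acceptance sweep rows) are run once per session and
shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from aeroband.core_model import ModelParameters, SpatialGrid
from aeroband.experiments import (
    run_base_case,
    run_mazzag_comparison,
    run_sensitivity_sweep,
)


@pytest.fixture(scope="session")
def base_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def grid640(base_params) -> SpatialGrid:
    return SpatialGrid.from_cells_per_mm(base_params.S, 128)


@pytest.fixture(scope="session")
def base_case():
    """Base-case run to 600 s: (SimulationResult, report dict)."""
    return run_base_case(t_end=600.0)


@pytest.fixture(scope="session")
def mazzag_case():
    """Comparison-parameter run to 600 s: (SimulationResult, report dict)."""
    return run_mazzag_comparison(t_end=600.0)


@pytest.fixture(scope="session")
def acceptance_sweep_rows():
    """The one-at-a-time rows needed for directional validation, keyed by
    (parameter, value)."""
    spec = [
        ("B_o", [1e9, 3e8]),
        ("C_o", [30.0, 10.0]),
        ("K", [6e-9, 2e-9]),
        ("C_hat_min", [0.015, 0.005]),
    ]
    rows = run_sensitivity_sweep(spec, t_end=300.0)
    return {(r.parameter, None if np.isnan(r.value) else r.value): r for r in rows}
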