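"""Shared fixtures: baseline parameter sets and one reusable solver run."""

import numpy as np
import pytest

from coshlib.oxyhb import hill_curve, adair_curve
from coshlib.params import (
    CapillarySpec,
    ResistanceSet,
    Solubilities,
    TissueSpec,
    krogh_radius_from_spacing,
)


@pytest.fixture(scope="session")
def curve():
    return hill_curve()


@pytest.fixture(scope="session")
def adair():
    return adair_curve()


@pytest.fixture(scope="session")
def sol():
    return Solubilities()


@pytest.fixture(scope="session")
def resistances():
    return ResistanceSet()


@pytest.fixture(scope="session")
def single_cap():
    """Single-capillary cylinder geometry (converging-bifurcation setup)."""
    return CapillarySpec(r_c=1.5, r_p=2.0, r_w=2.6, L=300.0)


@pytest.fixture(scope="session")
def single_tissue():
    return TissueSpec(r_t=23.0, M0=1e-3)


@pytest.fixture(scope="session")
def array_cap():
    """Parallel-capillary array geometry."""
    return CapillarySpec(r_c=1.6, r_p=2.0, r_w=2.5, L=100.0)


@pytest.fixture(scope="session")
def array_tissue():
    return TissueSpec(r_t=krogh_radius_from_spacing(40.0), M0=1e-3)


@pytest.fixture(scope="session")
def baseline_discrete_run():
    """Converged discrete-solver run at the coarse baseline (shared; slow)."""
    from coshlib.discrete_solver import SolverConfig, run_to_steady_state

    cfg = SolverConfig(
        spec=CapillarySpec(r_c=1.5, r_p=2.0, r_w=2.6, L=100.0),
        tissue=TissueSpec(r_t=23.0, M0=1e-3),
        inlet=(0.8, 0.6),
    )
    return run_to_steady_state(cfg)
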