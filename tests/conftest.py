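"""Shared fixtures: small meshes and the long healing runs reused across tests.

The 140-day runs use a deliberately coarse stump--callus mesh so the whole
suite stays fast; the qualitative healing properties they exercise are
resolution-independent.
"""

from __future__ import annotations

import numpy as np
import pytest

from tendonheal import simulation as sim
from tendonheal.differentiation import EndoGateParams
from tendonheal.geometry import GeometryParams, build_mesh, fixture_bar, fixture_single_element
from tendonheal.mechanics import FEOperator


COARSE = GeometryParams(n_cross=4, n_axial_stump=2, n_axial_callus=4)


@pytest.fixture(scope="session")
def coarse_geometry() -> GeometryParams:
    return COARSE


@pytest.fixture(scope="session")
def coarse_mesh():
    return build_mesh(COARSE)


@pytest.fixture(scope="session")
def coarse_op(coarse_mesh):
    return FEOperator(coarse_mesh)


@pytest.fixture()
def single_element():
    return fixture_single_element()


@pytest.fixture()
def bar10():
    return fixture_bar(10)


def _run(rule_set: str, horizon: int = 140, **kwargs) -> sim.HealingHistory:
    cfg = sim.SimulationConfig(geometry=COARSE, horizon=horizon, rule_set=rule_set, **kwargs)
    return sim.run_healing(cfg)


@pytest.fixture(scope="session")
def pe_history():
    """140-day principal-strain (PE) healing run."""
    return _run("PE")


@pytest.fixture(scope="session")
def endo_histories():
    """PE-ENDO runs at both cartilage thresholds (20% and 25%)."""
    return {
        0.20: _run("PE-ENDO", endo=EndoGateParams(cartilage_threshold=0.20)),
        0.25: _run("PE-ENDO", endo=EndoGateParams(cartilage_threshold=0.25)),
    }


@pytest.fixture(scope="session")
def oxy_sweep():
    """PE-OXY baseline plus the four hypoxia-increasing perturbations."""
    base = sim.SimulationConfig(geometry=COARSE, horizon=140, rule_set="PE-OXY")
    return sim.parameter_sweep(
        base, {"A_OSS": [3.0], "O": [0.25], "A": [0.25], "C": [0.75]}
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
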