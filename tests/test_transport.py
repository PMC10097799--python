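"""Diffusive transport: cells, strain-gated angiogenesis, oxygen with consumption."""

import numpy as np
import pytest

from tendonheal.geometry import ConfigurationError, fixture_bar, fixture_single_element
from tendonheal.mechanics import FEOperator, StimulusField
from tendonheal import transport
from tendonheal.transport import (
    AngioGate,
    CalibrationError,
    TransportField,
    angiogenesis_step,
    calibrate_cell_infiltration,
    diffuse_step,
    mature_vessels,
    mean_callus_density,
    oxygen_step,
)


def make_stimuli(oss: np.ndarray) -> StimulusField:
    n = len(oss)
    z = np.zeros(n)
    return StimulusField(
        eps1=z, eps2=z, eps3=z, oss=np.asarray(oss, dtype=float),
        hydrostatic=z, pore_pressure=z, fluid_flow=z,
        direction=np.tile([0.0, 0.0, 1.0], (n, 1)),
    )


def reference_diffusion_step(op, rho, D, dt, source_ids):
    """Independent dense oracle: lumped-mass backward-Euler diffusion step."""
    n = op.mesh.n_nodes
    M = np.diag(op.lumped_mass)
    L = op.scalar_laplacian().toarray()
    A = M / dt + D * L
    b = M / dt @ rho
    out = rho.astype(float).copy()
    dirich = np.zeros(n, dtype=bool)
    dirich[source_ids] = True
    out[dirich] = 1.0
    f = ~dirich
    out[f] = np.linalg.solve(A[np.ix_(f, f)], b[f] - A[np.ix_(f, dirich)] @ out[dirich])
    return np.clip(out, 0, 1)


class TestDiffusion:
    def test_uniform_field_unchanged_without_sources(self, bar10):
        op = FEOperator(bar10)
        rho = np.full(bar10.n_nodes, 0.3)
        out = diffuse_step(op, rho, D=1.0, dt=1.0, sources=np.array([], dtype=int))
        assert np.allclose(out, 0.3, atol=1e-12)

    def test_mass_conservation_without_sources(self, bar10, rng):
        op = FEOperator(bar10)
        rho = rng.uniform(0.2, 0.8, bar10.n_nodes)
        mass0 = np.dot(op.lumped_mass, rho)
        out = diffuse_step(op, rho, D=0.7, dt=1.0, sources=np.array([], dtype=int))
        assert np.dot(op.lumped_mass, out) == pytest.approx(mass0, rel=1e-10)

    def test_matches_dense_oracle(self, bar10, rng):
        op = FEOperator(bar10)
        rho = rng.uniform(0, 0.5, bar10.n_nodes)
        src = bar10.fixed_nodes
        got = diffuse_step(op, rho, D=0.4, dt=1.0, sources=src)
        want = reference_diffusion_step(op, rho, 0.4, 1.0, src)
        assert np.allclose(got, want, atol=1e-11)

    def test_source_drives_monotone_saturation(self, single_element):
        op = FEOperator(single_element)
        rho = np.zeros(8)
        src = single_element.fixed_nodes
        prev = 0.0
        for _ in range(30):
            rho = diffuse_step(op, rho, D=1.0, dt=1.0, sources=src)
            free_val = rho[single_element.loaded_nodes].mean()
            assert free_val >= prev - 1e-13
            prev = free_val
        assert prev > 0.95

    def test_invalid_inputs(self, single_element):
        op = FEOperator(single_element)
        with pytest.raises(ConfigurationError):
            diffuse_step(op, np.zeros(8), D=0.0, dt=1.0, sources=np.array([], dtype=int))
        with pytest.raises(ConfigurationError):
            diffuse_step(op, np.zeros(8), D=1.0, dt=-1.0, sources=np.array([], dtype=int))


class TestOxygen:
    def test_closed_form_decay_on_isolated_uniform_field(self, single_element):
        """Without diffusion gradients the sink integrates to exp(-C t) exactly."""
        op = FEOperator(single_element)
        rho = np.ones(8)
        cells = np.ones(8)
        for _ in range(2):  # two daily steps -> t = 2 days
            rho = oxygen_step(op, rho, O=1.0, C=0.5, rho_cells=cells, dt=1.0,
                              sources=np.array([], dtype=int))
        assert rho[0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_zero_cells_reduces_to_diffusion(self, bar10, rng):
        op = FEOperator(bar10)
        rho = rng.uniform(0, 1, bar10.n_nodes)
        src = bar10.fixed_nodes
        a = oxygen_step(op, rho, 0.5, 0.5, np.zeros(bar10.n_nodes), 1.0, src)
        b = diffuse_step(op, rho, 0.5, 1.0, src)
        assert np.allclose(a, b, atol=1e-12)

    def test_consumption_bounds_oxygen_below_pure_diffusion(self, bar10):
        op = FEOperator(bar10)
        src = bar10.fixed_nodes
        with_c = np.zeros(bar10.n_nodes)
        without = np.zeros(bar10.n_nodes)
        cells = np.ones(bar10.n_nodes)
        for _ in range(5):
            with_c = oxygen_step(op, with_c, 0.5, 0.5, cells, 1.0, src)
            without = oxygen_step(op, without, 0.5, 0.0, cells, 1.0, src)
        free = np.setdiff1d(np.arange(bar10.n_nodes), src)
        assert np.all(with_c[free] <= without[free] + 1e-12)
        assert np.all(with_c[free] < 1.0)

    def test_negative_consumption_rejected(self, single_element):
        op = FEOperator(single_element)
        with pytest.raises(ConfigurationError):
            oxygen_step(op, np.ones(8), 1.0, -0.1, np.ones(8), 1.0, np.array([], dtype=int))


class TestAngiogenesis:
    def test_fully_gated_field_unchanged(self, bar10, rng):
        op = FEOperator(bar10)
        rho = rng.uniform(0, 0.5, bar10.n_nodes)
        stim = make_stimuli(np.full(10, 10.0))  # all above the 6% threshold
        out = angiogenesis_step(op, rho, 0.5, 1.0, stim, AngioGate(), bar10.fixed_nodes)
        assert np.array_equal(out, rho)

    def test_ungated_equals_plain_diffusion(self, bar10):
        op = FEOperator(bar10)
        rho = np.zeros(bar10.n_nodes)
        stim = make_stimuli(np.zeros(10))
        a = angiogenesis_step(op, rho, 0.5, 1.0, stim, AngioGate(), bar10.fixed_nodes)
        b = diffuse_step(op, rho, 0.5, 1.0, bar10.fixed_nodes)
        assert np.allclose(a, b, atol=1e-12)

    def test_gated_distal_half_stays_empty(self, bar10):
        """Vessels cannot advance past over-strained elements (graph reachability)."""
        op = FEOperator(bar10)
        oss = np.zeros(10)
        oss[5:] = 12.0  # distal half blocked
        stim = make_stimuli(oss)
        rho = np.zeros(bar10.n_nodes)
        for _ in range(50):
            rho = angiogenesis_step(op, rho, 2.0, 1.0, stim, AngioGate(), bar10.fixed_nodes)
        distal_nodes = np.arange(4 * 6, bar10.n_nodes)  # beyond the blocked interface
        assert np.all(rho[distal_nodes] == 0.0)
        proximal = np.arange(4, 4 * 6)
        assert np.all(rho[proximal] > 0.0)

    def test_monotone_non_decreasing(self, bar10, rng):
        op = FEOperator(bar10)
        rho = rng.uniform(0, 0.9, bar10.n_nodes)
        oss = rng.uniform(0, 12, 10)
        out = angiogenesis_step(op, rho, 0.5, 1.0, make_stimuli(oss), AngioGate(), bar10.fixed_nodes)
        assert np.all(out >= rho - 1e-13)

    def test_missing_stimuli_raises(self, bar10):
        op = FEOperator(bar10)
        with pytest.raises(transport.StateError):
            angiogenesis_step(op, np.zeros(bar10.n_nodes), 0.5, 1.0, None, AngioGate(),
                              bar10.fixed_nodes)


class TestVesselMaturation:
    def _field(self, angio_value):
        n = 8
        return TransportField(
            cells=np.zeros(n), angio=np.full(n, angio_value), oxygen=np.zeros(n),
            cell_sources=np.array([], dtype=int), angio_sources=np.array([], dtype=int),
            oxygen_sources=np.array([], dtype=int),
        )

    def test_above_threshold_becomes_source(self):
        fld = mature_vessels(self._field(0.95), AngioGate())
        assert fld.vessel_flags.all()
        assert len(fld.oxygen_sources) == 8

    def test_exactly_at_threshold_is_not_matured(self):
        fld = mature_vessels(self._field(0.90), AngioGate())
        assert not fld.vessel_flags.any()

    def test_flags_are_monotone(self):
        fld = mature_vessels(self._field(0.95), AngioGate())
        fld.angio[:] = 0.1  # later recomputation drops below threshold
        fld = mature_vessels(fld, AngioGate())
        assert fld.vessel_flags.all()


class TestCalibration:
    def test_replay_hits_target_band(self, coarse_mesh, coarse_op):
        D = calibrate_cell_infiltration(coarse_op)
        rho = np.zeros(coarse_mesh.n_nodes)
        for _ in range(14):
            rho = diffuse_step(coarse_op, rho, D, 1.0, coarse_mesh.callus_surface_nodes)
        mean = mean_callus_density(coarse_op, rho)
        assert 0.95 <= mean <= 0.97

    def test_doubled_diffusivity_overshoots(self, coarse_mesh, coarse_op):
        D = calibrate_cell_infiltration(coarse_op)

        def day14(Dv):
            rho = np.zeros(coarse_mesh.n_nodes)
            for _ in range(14):
                rho = diffuse_step(coarse_op, rho, Dv, 1.0, coarse_mesh.callus_surface_nodes)
            return mean_callus_density(coarse_op, rho)

        assert day14(2 * D) > day14(D)
        assert day14(1e-4) < 0.5  # vanishing D leaves only a boundary layer

    def test_unreachable_target_reports_bracket(self, coarse_op):
        with pytest.raises(CalibrationError):
            calibrate_cell_infiltration(coarse_op, bracket=(1e-6, 1e-5))
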