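"""Stimulus measures, mixture rule and the finite-element engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tendonheal import geometry as geo, mechanics as mech
from tendonheal.geometry import REGION_CALLUS, REGION_STUMP, fixture_bar, fixture_single_element
from tendonheal.mechanics import (
    FEOperator,
    LoadProtocol,
    MaterialParameters,
    assemble_material,
    effective_axial_modulus,
    element_elasticity,
    hydrostatic_stress,
    mixture_multiplier,
    octahedral_shear_strain,
    reaction_force,
    solve_ramp,
    stiffness_at_load,
)
from tendonheal.remodeling import ElementState


def axial_fibrils(n_elements: int) -> np.ndarray:
    fib = np.zeros((n_elements, 13, 3))
    fib[:, :, 2] = 1.0
    return fib


def make_state(rhoF=0.0, rhoT=0.0, rhoC=0.0, rhoB=0.0, region=REGION_CALLUS):
    one = lambda v: np.array([float(v)])
    return ElementState(
        rhoF=one(rhoF), rhoT=one(rhoT), rhoC=one(rhoC), rhoB=one(rhoB),
        cells=one(1.0), fibrils=axial_fibrils(1), region=np.array([region]),
    )


class TestOctahedralShearStrain:
    def test_hydrostatic_state_is_zero(self):
        assert octahedral_shear_strain(0.02, 0.02, 0.02) == pytest.approx(0.0)

    def test_uniaxial_value(self):
        # (1/3) sqrt(0.03^2 + 0.03^2 + 0) = 0.014142...
        assert octahedral_shear_strain(0.03, 0.0, 0.0) == pytest.approx(0.0141421356, abs=1e-9)

    @given(
        st.permutations([0.03, 0.01, -0.02]),
    )
    @settings(deadline=None, max_examples=20)
    def test_permutation_symmetry(self, perm):
        ref = octahedral_shear_strain(0.03, 0.01, -0.02)
        assert octahedral_shear_strain(*perm) == pytest.approx(ref, rel=1e-12)


class TestHydrostaticStress:
    def test_isotropic(self):
        assert hydrostatic_stress(np.diag([3.0, 3.0, 3.0])) == pytest.approx(3.0)

    def test_trace_third(self):
        assert hydrostatic_stress(np.diag([1.0, 2.0, 3.0])) == pytest.approx(2.0)

    def test_pure_shear(self):
        s = np.array([[0, 1.0, 0.5], [1.0, 0, 0.2], [0.5, 0.2, 0]])
        assert hydrostatic_stress(s) == pytest.approx(0.0)


class TestMixtureRule:
    @pytest.mark.parametrize(
        "densities,expected",
        [
            ((0, 1, 0, 0), 1.0),
            ((0, 0, 0, 1), 40.40),
            ((0, 0, 1, 0), 2.62),
            ((1, 0, 0, 0), 0.5),
            ((0.5, 0.5, 0, 0), 0.75),
        ],
    )
    def test_pure_and_mixed_multipliers(self, densities, expected):
        assert mixture_multiplier(*densities) == pytest.approx(expected, abs=1e-12)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            mixture_multiplier(-0.1, 0, 0, 0)

    def test_assemble_material_scales_all_moduli(self):
        state = make_state(rhoB=1.0)
        mult, scaled = assemble_material(state, MaterialParameters())
        assert mult[0] == pytest.approx(40.40)
        base = MaterialParameters()
        for name in ("E1", "E2", "K1", "K2", "Ep", "En", "Gpn"):
            assert getattr(scaled[0], name) == pytest.approx(40.40 * getattr(base, name))

    def test_stump_elements_stay_intact(self):
        state = make_state(rhoB=1.0, region=REGION_STUMP)
        mult, _ = assemble_material(state, MaterialParameters())
        assert mult[0] == pytest.approx(1.0)


class TestAnalyticBar:
    def test_uniaxial_strain_and_stiffness(self, single_element):
        params = MaterialParameters()
        C = element_elasticity(np.ones(1), axial_fibrils(1), params)
        E_eff = effective_axial_modulus(C[0])
        prot = LoadProtocol(peak_force=2.0)
        stim, _ = solve_ramp(single_element, C, prot, params, constraint="roller")
        expected_strain_pct = 100 * prot.peak_force / (1.0 * E_eff)
        assert stim.eps1[0] == pytest.approx(expected_strain_pct, rel=1e-10)
        k = stiffness_at_load(single_element, C, prot, params, constraint="roller")
        assert k == pytest.approx(E_eff, rel=1e-8)  # E*A/L with A = L = 1

    def test_linearity_in_moduli_and_load(self, single_element):
        params = MaterialParameters()
        C = element_elasticity(np.ones(1), axial_fibrils(1), params)
        prot = LoadProtocol(peak_force=2.0)
        _, d1 = solve_ramp(single_element, C, prot, params, constraint="roller")
        _, d2 = solve_ramp(single_element, 2 * C, prot, params, constraint="roller")
        assert d2 == pytest.approx(0.5 * d1, rel=1e-12)
        s1, _ = solve_ramp(single_element, C, prot, params, constraint="roller")
        s3, _ = solve_ramp(
            single_element, C, LoadProtocol(peak_force=1.0), params, constraint="roller"
        )
        assert s3.eps1[0] == pytest.approx(0.5 * s1.eps1[0], rel=1e-12)

    def test_force_balance(self, bar10):
        params = MaterialParameters()
        C = element_elasticity(np.ones(10), axial_fibrils(10), params)
        prot = LoadProtocol()
        r = reaction_force(bar10, C, prot)
        assert r == pytest.approx(-prot.peak_force, rel=1e-8)

    def test_series_softening_bound(self, bar10):
        """A soft mid-segment makes the bar softer than either homogeneous bar."""
        params = MaterialParameters()
        prot = LoadProtocol()
        mult_soft = np.ones(10)
        mult_soft[4:6] = 0.1
        fib = axial_fibrils(10)
        k_mixed = stiffness_at_load(bar10, element_elasticity(mult_soft, fib, params), prot, params)
        k_stiff = stiffness_at_load(bar10, element_elasticity(np.ones(10), fib, params), prot, params)
        k_soft = stiffness_at_load(bar10, element_elasticity(0.1 * np.ones(10), fib, params), prot, params)
        assert k_soft < k_mixed < k_stiff

    def test_zero_stiffness_element_raises(self, single_element):
        with pytest.raises(mech.SolverError):
            solve_ramp(single_element, np.zeros((1, 6, 6)), LoadProtocol(), MaterialParameters())


def test_strain_extraction_matches_imposed_linear_field(single_element):
    """The centroid strain operator recovers sym(grad u) for any linear field."""
    rng = np.random.default_rng(7)
    A = rng.normal(size=(3, 3)) * 0.01
    op = FEOperator(single_element)
    u = (single_element.nodes @ A.T).ravel()
    strain = np.einsum("eij,ej->ei", op.B0, u[op.edofs[0]][None, :])
    sym = 0.5 * (A + A.T)
    expected = np.array(
        [sym[0, 0], sym[1, 1], sym[2, 2], 2 * sym[1, 2], 2 * sym[0, 2], 2 * sym[0, 1]]
    )
    assert np.allclose(strain[0], expected, atol=1e-14)


def test_displacement_monotone_in_stiffening(bar10):
    """Raising any element's mixture multiplier never raises the end displacement."""
    params = MaterialParameters()
    prot = LoadProtocol()
    fib = axial_fibrils(10)
    mult = np.full(10, 0.5)
    _, d0 = solve_ramp(bar10, element_elasticity(mult, fib, params), prot, params)
    for i in (0, 5, 9):
        m2 = mult.copy()
        m2[i] = 2.0
        _, d = solve_ramp(bar10, element_elasticity(m2, fib, params), prot, params)
        assert d <= d0 + 1e-14


def test_random_fibrils_soften_axial_response(single_element):
    """Randomly oriented fibrils give a lower axial modulus than aligned ones."""
    rng = np.random.default_rng(0)
    v = rng.normal(size=(1, 13, 3))
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    params = MaterialParameters()
    C_rand = element_elasticity(np.ones(1), v, params)
    C_axial = element_elasticity(np.ones(1), axial_fibrils(1), params)
    assert effective_axial_modulus(C_rand[0]) < effective_axial_modulus(C_axial[0])
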