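"""Quasi-static mechanics of the healing construct and stimulus extraction.

The engine is a small-strain, fiber-reinforced linear-elastic finite-element
model: each element carries an isotropic ground substance (modulus ``Ep``,
Poisson ratio ``poisson``) plus 13 collagen fibril reinforcements
(modulus ``E1`` distributed equally over the fibril directions).  The whole
elastic tensor is scaled by the tissue-mixture multiplier

    m = 0.5 rhoF + rhoT + 2.62 rhoC + 40.40 rhoB

so densification stiffens the callus, lowering strains and switching the
differentiation rules.  The fluid phase is a one-step backward-difference
biphasic solve: the volumetric strain rate over the load ramp acts as a
source for a Darcy pressure problem drained at the lateral surface, giving
per-element pore pressure (MPa) and fluid-flow speed (um/s).

Stimuli are evaluated at peak load (end of the ramp).  Strains are reported
in percent, stresses in MPa, fluid flow in um/s, matching the thresholds of
the differentiation rule tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import splu

from .geometry import (
    GAUSS_POINTS,
    REGION_CALLUS,
    REGION_STUMP,
    ConfigurationError,
    HealingMesh,
    _GAUSS_GRADS,
    _GAUSS_N,
    _shape_gradients,
)

#: mixture scaling coefficients for fat-, tendon-, cartilage- and bone-like tissue
MIXTURE_COEFFS = {"fat": 0.5, "tendon": 1.0, "cartilage": 2.62, "bone": 40.40}


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class MaterialParameters:
    """Intact-tendon stiffness parameters (MPa) and biphasic constants.

    ``E1`` acts as the fibril (collagen) modulus and ``Ep`` as the ground
    substance modulus in the linear engine; the remaining moduli
    (E2, K1, K2, En, Gpn) are carried so that the mixture rule scales the
    full intact parameter set, and so that a higher-fidelity constitutive
    engine can be plugged in without changing the interface.  Values are
    artifact defaults chosen so the intact construct sits at about 1% axial
    strain under the 2 N load.
    """

    E1: float = 60.0  # fibril modulus, MPa
    E2: float = 30.0
    K1: float = 15.0
    K2: float = 15.0
    Ep: float = 5.0  # ground substance modulus, MPa
    En: float = 5.0
    Gpn: float = 2.0
    poisson: float = 0.3
    permeability: float = 0.01  # mm^4 / (N s) == mm^2 / (MPa s)
    storage: float = 0.1  # biphasic storage coefficient, 1/MPa

    def validate(self) -> None:
        moduli = (self.E1, self.E2, self.K1, self.K2, self.Ep, self.En, self.Gpn)
        if min(moduli) <= 0 or self.permeability <= 0 or self.storage <= 0:
            raise ConfigurationError("all moduli, permeability and storage must be positive")
        if not 0 <= self.poisson < 0.5:
            raise ConfigurationError("Poisson ratio must be in [0, 0.5)")

    def scaled(self, multiplier: float) -> "MaterialParameters":
        """All stiffness parameters scaled by the same mixture multiplier."""
        return replace(
            self,
            E1=self.E1 * multiplier,
            E2=self.E2 * multiplier,
            K1=self.K1 * multiplier,
            K2=self.K2 * multiplier,
            Ep=self.Ep * multiplier,
            En=self.En * multiplier,
            Gpn=self.Gpn * multiplier,
        )


@dataclass(frozen=True)
class LoadProtocol:
    """Tensile ramp load: 2.0 N peak at 1.1 N/s along z by default."""

    peak_force: float = 2.0  # N
    ramp_rate: float = 1.1  # N/s
    axis: int = 2

    def validate(self) -> None:
        if self.peak_force <= 0 or self.ramp_rate <= 0:
            raise ConfigurationError("peak force and ramp rate must be positive")

    @property
    def ramp_time(self) -> float:
        return self.peak_force / self.ramp_rate  # s


@dataclass
class StimulusField:
    """Per-element biophysical stimuli from one mechanics solve.

    Principal strains are in percent (eps1 >= eps2 >= eps3), octahedral shear
    strain in percent, hydrostatic stress in MPa (tension positive), pore
    pressure in MPa (compression positive), fluid flow in um/s.
    """

    eps1: np.ndarray
    eps2: np.ndarray
    eps3: np.ndarray
    oss: np.ndarray
    hydrostatic: np.ndarray
    pore_pressure: np.ndarray
    fluid_flow: np.ndarray
    direction: np.ndarray  # (E, 3) unit max-principal-strain directions
    pressure_nodal: np.ndarray | None = None  # (N,) MPa, for export


def octahedral_shear_strain(eps1, eps2, eps3):
    """(1/3) sqrt[(e1-e3)^2 + (e1-e2)^2 + (e2-e3)^2]; permutation symmetric."""
    eps1, eps2, eps3 = (np.asarray(e, dtype=float) for e in (eps1, eps2, eps3))
    return (1.0 / 3.0) * np.sqrt((eps1 - eps3) ** 2 + (eps1 - eps2) ** 2 + (eps2 - eps3) ** 2)


def hydrostatic_stress(sigma: np.ndarray) -> float:
    """Mean of the diagonal (trace/3) of a symmetric stress tensor."""
    sigma = np.asarray(sigma, dtype=float)
    return float(np.trace(sigma)) / 3.0


def mixture_multiplier(rhoF, rhoT, rhoC, rhoB):
    """Composite stiffness multiplier 0.5 rhoF + rhoT + 2.62 rhoC + 40.40 rhoB."""
    arrs = [np.asarray(r, dtype=float) for r in (rhoF, rhoT, rhoC, rhoB)]
    if any(np.any(a < 0) for a in arrs):
        raise ValueError("tissue densities must be non-negative")
    rhoF, rhoT, rhoC, rhoB = arrs
    return (
        MIXTURE_COEFFS["fat"] * rhoF
        + MIXTURE_COEFFS["tendon"] * rhoT
        + MIXTURE_COEFFS["cartilage"] * rhoC
        + MIXTURE_COEFFS["bone"] * rhoB
    )


def assemble_material(state, params: MaterialParameters):
    """Per-element effective moduli from tissue densities.

    Every stiffness parameter of a callus element is scaled by the same
    mixture multiplier; stump elements stay at intact values (multiplier 1).
    Returns ``(multipliers, scaled_params)`` where ``scaled_params`` is a
    list of :class:`MaterialParameters`, one per element.
    """
    mult = np.asarray(mixture_multiplier(state.rhoF, state.rhoT, state.rhoC, state.rhoB))
    mult = np.where(state.region == REGION_STUMP, 1.0, mult)
    scaled = [params.scaled(float(m)) for m in np.atleast_1d(mult)]
    return mult, scaled


def isotropic_elasticity(E: float, nu: float) -> np.ndarray:
    """6x6 Voigt elasticity matrix (engineering shear strains)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def fiber_voigt(direction: np.ndarray) -> np.ndarray:
    """Voigt vector b of the structure tensor m x m (stress/strain pairing)."""
    m = np.asarray(direction, dtype=float)
    B = np.einsum("...i,...j->...ij", m, m)
    return np.stack(
        [B[..., 0, 0], B[..., 1, 1], B[..., 2, 2], B[..., 1, 2], B[..., 0, 2], B[..., 0, 1]],
        axis=-1,
    )


def element_elasticity(multipliers: np.ndarray, fibrils: np.ndarray, params: MaterialParameters) -> np.ndarray:
    """Elastic tensors (E, 6, 6): multiplier * [iso ground + fibril reinforcement].

    ``fibrils`` is (E, 13, 3) unit directions; the fibril modulus E1 is
    distributed equally over the 13 directions.
    """
    C_iso = isotropic_elasticity(params.Ep, params.poisson)
    b = fiber_voigt(fibrils)  # (E, 13, 6)
    C_fib = params.E1 / fibrils.shape[1] * np.einsum("efi,efj->eij", b, b)
    return np.asarray(multipliers)[:, None, None] * (C_iso[None] + C_fib)


def effective_axial_modulus(C: np.ndarray, axis: int = 2) -> float:
    """Uniaxial-stress effective modulus 1 / S[axis, axis] from a 6x6 tensor."""
    S = np.linalg.inv(C)
    return 1.0 / S[axis, axis]


class FEOperator:
    """Precomputed element matrices for a fixed mesh (geometry never changes)."""

    def __init__(self, mesh: HealingMesh):
        self.mesh = mesh
        coords = mesh.nodes[mesh.elements]  # (E, 8, 3)
        E = mesh.n_elements

        jac = np.einsum("gaj,eak->egjk", _GAUSS_GRADS, coords)  # (E, 8, 3, 3)
        det = np.linalg.det(jac)
        inv = np.linalg.inv(jac)
        # physical shape gradients at gauss points: (E, 8gp, 8node, 3)
        grads = np.einsum("egjk,gaj->egak", inv, _GAUSS_GRADS)
        self.wdet = det  # unit gauss weights

        # strain-displacement matrices B (E, 8gp, 6, 24), Voigt order
        # [exx, eyy, ezz, gyz, gxz, gxy], dofs ordered (node0 x,y,z, node1 ...)
        B = np.zeros((E, 8, 6, 24))
        gx, gy, gz = grads[..., 0], grads[..., 1], grads[..., 2]
        for a in range(8):
            B[:, :, 0, 3 * a + 0] = gx[:, :, a]
            B[:, :, 1, 3 * a + 1] = gy[:, :, a]
            B[:, :, 2, 3 * a + 2] = gz[:, :, a]
            B[:, :, 3, 3 * a + 1] = gz[:, :, a]
            B[:, :, 3, 3 * a + 2] = gy[:, :, a]
            B[:, :, 4, 3 * a + 0] = gz[:, :, a]
            B[:, :, 4, 3 * a + 2] = gx[:, :, a]
            B[:, :, 5, 3 * a + 0] = gy[:, :, a]
            B[:, :, 5, 3 * a + 1] = gx[:, :, a]
        self.B = B

        # centroid quantities
        g0 = _shape_gradients(np.zeros(3))  # (8, 3)
        jac0 = np.einsum("aj,eak->ejk", g0, coords)
        inv0 = np.linalg.inv(jac0)
        grads0 = np.einsum("ejk,aj->eak", inv0, g0)  # (E, 8, 3)
        B0 = np.zeros((E, 6, 24))
        for a in range(8):
            B0[:, 0, 3 * a + 0] = grads0[:, a, 0]
            B0[:, 1, 3 * a + 1] = grads0[:, a, 1]
            B0[:, 2, 3 * a + 2] = grads0[:, a, 2]
            B0[:, 3, 3 * a + 1] = grads0[:, a, 2]
            B0[:, 3, 3 * a + 2] = grads0[:, a, 1]
            B0[:, 4, 3 * a + 0] = grads0[:, a, 2]
            B0[:, 4, 3 * a + 2] = grads0[:, a, 0]
            B0[:, 5, 3 * a + 0] = grads0[:, a, 1]
            B0[:, 5, 3 * a + 1] = grads0[:, a, 0]
        self.B0 = B0
        self.grads0 = grads0

        # global dof bookkeeping
        dofs = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(E, 24)
        self.edofs = dofs
        self.krows = np.repeat(dofs, 24, axis=1).ravel()
        self.kcols = np.tile(dofs, (1, 24)).ravel()
        self.ndof = 3 * mesh.n_nodes

        # scalar (transport / pressure) element Laplacian and lumped mass
        self.ke_scalar = np.einsum("eg,egak,egbk->eab", det, grads, grads)
        self.me_lumped = np.einsum("eg,ga->ea", det, _GAUSS_N)  # (E, 8) row-sum mass
        self.srows = np.repeat(mesh.elements, 8, axis=1).ravel()
        self.scols = np.tile(mesh.elements, (1, 8)).ravel()

        lumped = np.zeros(mesh.n_nodes)
        np.add.at(lumped, mesh.elements.ravel(), self.me_lumped.ravel())
        self.lumped_mass = lumped

        # lumped nodal mass restricted to callus elements (volume weights)
        callus_mass = np.zeros(mesh.n_nodes)
        cal = mesh.region == REGION_CALLUS
        np.add.at(callus_mass, mesh.elements[cal].ravel(), self.me_lumped[cal].ravel())
        self.callus_node_mass = callus_mass

        # consistent nodal weights for uniform traction on the loaded face
        self.load_weights = self._face_weights(mesh.loaded_nodes)
        self.loaded_area = self.load_weights.sum()

        self._scalar_laplacian = None

    def _face_weights(self, face_nodes: np.ndarray) -> np.ndarray:
        """Consistent load weights int N_i dA over element faces on a node set."""
        mesh = self.mesh
        face_set = set(int(n) for n in face_nodes)
        # local faces of the VTK hexahedron
        local_faces = [
            (0, 1, 2, 3),
            (4, 5, 6, 7),
            (0, 1, 5, 4),
            (1, 2, 6, 5),
            (2, 3, 7, 6),
            (3, 0, 4, 7),
        ]
        g1 = 1.0 / np.sqrt(3.0)
        quad = [(-g1, -g1), (g1, -g1), (g1, g1), (-g1, g1)]
        weights = np.zeros(mesh.n_nodes)
        for e, conn in enumerate(mesh.elements):
            for lf in local_faces:
                ids = conn[list(lf)]
                if not all(int(i) in face_set for i in ids):
                    continue
                X = mesh.nodes[ids]  # (4, 3)
                for s, t in quad:
                    N = 0.25 * np.array(
                        [(1 - s) * (1 - t), (1 + s) * (1 - t), (1 + s) * (1 + t), (1 - s) * (1 + t)]
                    )
                    dNds = 0.25 * np.array([-(1 - t), (1 - t), (1 + t), -(1 + t)])
                    dNdt = 0.25 * np.array([-(1 - s), -(1 + s), (1 + s), (1 - s)])
                    a1 = dNds @ X
                    a2 = dNdt @ X
                    dA = np.linalg.norm(np.cross(a1, a2))
                    weights[ids] += N * dA
        return weights

    def scalar_laplacian(self, element_mask: np.ndarray | None = None) -> csr_matrix:
        """Assembled FE Laplacian over (optionally a subset of) elements."""
        if element_mask is None:
            if self._scalar_laplacian is None:
                vals = self.ke_scalar.ravel()
                self._scalar_laplacian = coo_matrix(
                    (vals, (self.srows, self.scols)), shape=(self.mesh.n_nodes,) * 2
                ).tocsr()
            return self._scalar_laplacian
        mask = np.asarray(element_mask, dtype=bool)
        idx = np.repeat(mask, 64)
        vals = self.ke_scalar.ravel()[idx]
        return coo_matrix(
            (vals, (self.srows[idx], self.scols[idx])), shape=(self.mesh.n_nodes,) * 2
        ).tocsr()

    def assemble_stiffness(self, C: np.ndarray) -> csr_matrix:
        """Global stiffness from per-element 6x6 elastic tensors."""
        Ke = np.einsum("eg,egik,eij,egjl->ekl", self.wdet, self.B, C, self.B, optimize=True)
        return coo_matrix((Ke.ravel(), (self.krows, self.kcols)), shape=(self.ndof,) * 2).tocsr()


def _principal(strain_voigt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Principal strains (desc) and max-principal direction from Voigt strains."""
    E = strain_voigt.shape[0]
    T = np.empty((E, 3, 3))
    T[:, 0, 0] = strain_voigt[:, 0]
    T[:, 1, 1] = strain_voigt[:, 1]
    T[:, 2, 2] = strain_voigt[:, 2]
    T[:, 1, 2] = T[:, 2, 1] = 0.5 * strain_voigt[:, 3]
    T[:, 0, 2] = T[:, 2, 0] = 0.5 * strain_voigt[:, 4]
    T[:, 0, 1] = T[:, 1, 0] = 0.5 * strain_voigt[:, 5]
    w, v = np.linalg.eigh(T)  # ascending
    direction = v[:, :, 2]
    nrm = np.linalg.norm(direction, axis=1, keepdims=True)
    direction = direction / np.where(nrm == 0, 1.0, nrm)
    return w[:, 2], w[:, 1], w[:, 0], direction


def solve_ramp(
    mesh: HealingMesh,
    C: np.ndarray,
    protocol: LoadProtocol,
    params: MaterialParameters,
    op: FEOperator | None = None,
    constraint: str = "clamped",
) -> tuple[StimulusField, float]:
    """Solve the quasi-static ramp and extract stimuli at peak load.

    ``constraint="clamped"`` fixes all dofs of the fixed face (the healing
    construct gripped at the bone end); ``"roller"`` fixes only axial motion
    plus minimal rigid-body constraints, reproducing the analytic uniaxial
    bar exactly.  Returns ``(stimuli, end_displacement)`` where the end
    displacement is the consistent-load-weighted mean axial displacement of
    the loaded face (mm).
    """
    protocol.validate()
    op = op or FEOperator(mesh)

    zero_stiff = np.flatnonzero(np.einsum("eii->e", C[:, :3, :3]) <= 0)
    if len(zero_stiff):
        raise SolverError(f"zero-stiffness element(s): {zero_stiff[:5].tolist()}")

    K = op.assemble_stiffness(C)
    f = np.zeros(op.ndof)
    f[3 * mesh.loaded_nodes + protocol.axis] = (
        protocol.peak_force * op.load_weights[mesh.loaded_nodes] / op.loaded_area
    )

    fixed_dofs = _fixed_dofs(mesh, protocol.axis, constraint)
    free = np.ones(op.ndof, dtype=bool)
    free[fixed_dofs] = False
    u = np.zeros(op.ndof)
    Kff = K[free][:, free].tocsc()
    try:
        u[free] = splu(Kff).solve(f[free])
    except RuntimeError as exc:  # pragma: no cover - singular system
        raise SolverError(f"singular stiffness system: {exc}") from exc

    # element-centroid strains and stresses
    ue = u[op.edofs]  # (E, 24)
    strain = np.einsum("eij,ej->ei", op.B0, ue)  # Voigt
    stress = np.einsum("eij,ej->ei", C, strain)
    e1, e2, e3, direction = _principal(strain)
    sigma_h = stress[:, :3].sum(axis=1) / 3.0

    # biphasic pressure: S/t * M p + k * L p = -M (deps_v / t), drained laterally
    t_ramp = protocol.ramp_time
    eps_v = strain[:, :3].sum(axis=1)
    q = np.zeros(mesh.n_nodes)
    np.add.at(q, mesh.elements.ravel(), (op.me_lumped * (eps_v / t_ramp)[:, None]).ravel())
    A = params.storage / t_ramp * coo_matrix(
        (op.lumped_mass, (np.arange(mesh.n_nodes),) * 2)
    ).tocsr() + params.permeability * op.scalar_laplacian()
    p = np.zeros(mesh.n_nodes)
    drained = np.zeros(mesh.n_nodes, dtype=bool)
    drained[mesh.lateral_surface_nodes] = True
    freep = ~drained
    Aff = A[freep][:, freep].tocsc()
    p[freep] = splu(Aff).solve(-q[freep])

    grad_p = np.einsum("eak,ea->ek", op.grads0, p[mesh.elements])  # (E, 3) MPa/mm
    ff = params.permeability * np.linalg.norm(grad_p, axis=1) * 1e3  # um/s
    pp_elem = -p[mesh.elements].mean(axis=1)  # compression positive

    stimuli = StimulusField(
        eps1=100 * e1,
        eps2=100 * e2,
        eps3=100 * e3,
        oss=100 * octahedral_shear_strain(e1, e2, e3),
        hydrostatic=sigma_h,
        pore_pressure=pp_elem,
        fluid_flow=ff,
        direction=direction,
        pressure_nodal=p,
    )
    w = op.load_weights[mesh.loaded_nodes]
    end_disp = float(np.dot(w, u[3 * mesh.loaded_nodes + protocol.axis]) / w.sum())
    return stimuli, end_disp


def _fixed_dofs(mesh: HealingMesh, axis: int, constraint: str) -> np.ndarray:
    if constraint == "clamped":
        return (3 * mesh.fixed_nodes[:, None] + np.arange(3)).ravel()
    if constraint != "roller":
        raise ConfigurationError(f"unknown constraint mode {constraint!r}")
    lateral = [a for a in range(3) if a != axis]
    dofs = list(3 * mesh.fixed_nodes + axis)
    coords = mesh.nodes[mesh.fixed_nodes]
    a_idx = int(mesh.fixed_nodes[0])
    dofs += [3 * a_idx + lateral[0], 3 * a_idx + lateral[1]]
    # second node sharing lateral[1]-coordinate with A, to block in-plane rotation
    same = [
        int(n)
        for n, c in zip(mesh.fixed_nodes, coords)
        if n != a_idx
        and abs(c[lateral[1]] - mesh.nodes[a_idx, lateral[1]]) < 1e-12
        and abs(c[lateral[0]] - mesh.nodes[a_idx, lateral[0]]) > 1e-12
    ]
    if not same:  # pragma: no cover - fixture meshes always provide one
        same = [int(mesh.fixed_nodes[1])]
    dofs.append(3 * same[0] + lateral[1])
    return np.array(sorted(set(dofs)), dtype=np.int64)


def reaction_force(mesh: HealingMesh, C: np.ndarray, protocol: LoadProtocol, op: FEOperator | None = None,
                   constraint: str = "clamped") -> float:
    """Total axial reaction at the fixed face (force-balance check)."""
    op = op or FEOperator(mesh)
    K = op.assemble_stiffness(C)
    f = np.zeros(op.ndof)
    f[3 * mesh.loaded_nodes + protocol.axis] = (
        protocol.peak_force * op.load_weights[mesh.loaded_nodes] / op.loaded_area
    )
    fixed_dofs = _fixed_dofs(mesh, protocol.axis, constraint)
    free = np.ones(op.ndof, dtype=bool)
    free[fixed_dofs] = False
    u = np.zeros(op.ndof)
    u[free] = splu(K[free][:, free].tocsc()).solve(f[free])
    r = K @ u - f
    return float(r[3 * mesh.fixed_nodes + protocol.axis].sum())


def stiffness_at_load(
    mesh: HealingMesh,
    C: np.ndarray,
    protocol: LoadProtocol,
    params: MaterialParameters | None = None,
    op: FEOperator | None = None,
    constraint: str = "clamped",
) -> float:
    """Secant stiffness (N/mm): peak force over end displacement of the loaded face."""
    params = params or MaterialParameters()
    _, end_disp = solve_ramp(mesh, C, protocol, params, op, constraint)
    if end_disp == 0:
        raise SolverError("degenerate model: zero end displacement under load")
    return protocol.peak_force / end_disp
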