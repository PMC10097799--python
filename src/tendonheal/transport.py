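"""Cell infiltration, angiogenesis and oxygen transport on the nodal mesh graph.

All three species evolve by Fickian diffusion (d rho / dt = D lap rho) with
implicit (backward Euler) time stepping on the FE Laplacian with a lumped
mass matrix, Dirichlet value 1 at source nodes and zero flux elsewhere.
Fields are fractions in [0, 1].

Angiogenesis is strain-gated: the diffusion operator is assembled only over
elements whose octahedral shear strain is below the A-OSS threshold; fully
gated regions do not evolve.  A node whose angiogenesis exceeds the
maturation threshold (default 90%, strict) becomes a matured blood vessel:
it is flagged as blood supply (used by the oxygen-coupled rule set) and
added to the oxygen source set.  Flags are monotone, vessels never regress.

Oxygen additionally has a cellular sink C * rho_cells * rho_oxygen, which is
integrated exactly by operator splitting (implicit diffusion step followed
by an exponential decay factor), so an isolated fully cellularized node
decays as exp(-C t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import splu

from .geometry import REGION_CALLUS, ConfigurationError, HealingMesh
from .mechanics import FEOperator, StimulusField


class CalibrationError(RuntimeError):
    pass


class StateError(RuntimeError):
    pass


@dataclass(frozen=True)
class AngioGate:
    """Angiogenesis gating thresholds.

    ``a_oss``: octahedral-shear-strain threshold in percent (vessels only
    grow through elements straining below it); ``maturation``: angiogenesis
    fraction above which (strictly) a node counts as a matured vessel.
    """

    a_oss: float = 6.0
    maturation: float = 0.90

    def validate(self) -> None:
        if self.a_oss <= 0 or self.maturation <= 0:
            raise ConfigurationError("gate thresholds must be positive")


@dataclass
class TransportField:
    """Nodal transport state: cells, angiogenesis, oxygen (fractions in [0, 1])."""

    cells: np.ndarray
    angio: np.ndarray
    oxygen: np.ndarray
    cell_sources: np.ndarray  # node ids, Dirichlet 1
    angio_sources: np.ndarray
    oxygen_sources: np.ndarray
    vessel_flags: np.ndarray = field(default=None)  # bool per node, monotone

    def __post_init__(self) -> None:
        if self.vessel_flags is None:
            self.vessel_flags = np.zeros(len(self.cells), dtype=bool)


def _implicit_step(
    op: FEOperator,
    rho: np.ndarray,
    D: float,
    dt: float,
    sources: np.ndarray,
    element_mask: np.ndarray | None = None,
) -> np.ndarray:
    """One backward-Euler diffusion step; Dirichlet 1 at active source nodes."""
    n = op.mesh.n_nodes
    M = op.lumped_mass
    L = op.scalar_laplacian(element_mask)

    if element_mask is not None:
        active_elems = np.flatnonzero(np.asarray(element_mask, dtype=bool))
        active_nodes = np.zeros(n, dtype=bool)
        active_nodes[op.mesh.elements[active_elems].ravel()] = True
    else:
        active_nodes = np.ones(n, dtype=bool)

    dirich = np.zeros(n, dtype=bool)
    src = np.asarray(sources, dtype=np.int64)
    dirich[src[active_nodes[src]]] = True

    A = coo_matrix((M / dt, (np.arange(n),) * 2)).tocsr() + D * L
    b = M / dt * rho
    # impose Dirichlet rows
    freen = ~dirich
    out = rho.copy()
    out[dirich] = 1.0
    if freen.any():
        Aff = A[freen][:, freen].tocsc()
        bf = b[freen] - A[freen][:, dirich] @ out[dirich]
        out[freen] = splu(Aff).solve(bf)
    return np.clip(out, 0.0, 1.0)


def diffuse_step(
    op: FEOperator,
    rho: np.ndarray,
    D: float,
    dt: float,
    sources: np.ndarray,
) -> np.ndarray:
    """One implicit diffusion step (d rho/dt = D lap rho), clamped to [0, 1]."""
    if dt <= 0 or D <= 0:
        raise ConfigurationError("dt and diffusion constant must be positive")
    return _implicit_step(op, np.asarray(rho, dtype=float), D, dt, sources)


def oxygen_step(
    op: FEOperator,
    rho_oxy: np.ndarray,
    O: float,
    C: float,
    rho_cells: np.ndarray,
    dt: float,
    sources: np.ndarray,
) -> np.ndarray:
    """Diffusion from surface and matured vessels, minus the cellular sink.

    The sink -C * rho_cells * rho_oxy is integrated exactly over the step
    (exponential factor after the implicit diffusion step); source nodes are
    then re-imposed at 1.
    """
    if C < 0:
        raise ConfigurationError("oxygen consumption coefficient must be non-negative")
    out = diffuse_step(op, rho_oxy, O, dt, sources)
    out = out * np.exp(-C * np.asarray(rho_cells, dtype=float) * dt)
    src = np.asarray(sources, dtype=np.int64)
    if len(src):
        out[src] = np.clip(out[src], None, 1.0)
        out[src] = 1.0
    return np.clip(out, 0.0, 1.0)


def angiogenesis_step(
    op: FEOperator,
    rho_angio: np.ndarray,
    A: float,
    dt: float,
    stimuli: StimulusField | None,
    gate: AngioGate,
    sources: np.ndarray,
) -> np.ndarray:
    """Strain-gated vessel ingrowth.

    Diffusion proceeds only through elements with octahedral shear strain
    below the A-OSS threshold; nodes touched by no ungated element keep
    their value (sources included).  The field is monotone non-decreasing.
    """
    gate.validate()
    if stimuli is None:
        raise StateError("angiogenesis step requires the current-iteration stimulus field")
    mask = np.asarray(stimuli.oss) < gate.a_oss
    rho_angio = np.asarray(rho_angio, dtype=float)
    if not mask.any():
        return rho_angio.copy()
    out = _implicit_step(op, rho_angio, A, dt, sources, element_mask=mask)
    return np.clip(np.maximum(out, rho_angio), 0.0, 1.0)


def mature_vessels(field: TransportField, gate: AngioGate) -> TransportField:
    """Flag matured vessels (angio strictly above threshold) and extend oxygen sources.

    Flags are monotone: once a node provides blood supply it keeps doing so.
    """
    new_flags = field.vessel_flags | (field.angio > gate.maturation)
    field.vessel_flags = new_flags
    field.oxygen_sources = np.union1d(field.oxygen_sources, np.flatnonzero(new_flags))
    return field


def mean_callus_density(op: FEOperator, rho: np.ndarray) -> float:
    """Volume-weighted mean nodal density over the callus region."""
    w = op.callus_node_mass
    return float(np.dot(w, rho) / w.sum())


def calibrate_cell_infiltration(
    op: FEOperator,
    dt: float = 1.0,
    target_day: int = 14,
    target_mean: float = 0.95,
    bracket: tuple[float, float] = (1e-4, 100.0),
    tol: float = 1e-8,
) -> float:
    """Diffusivity D (mm^2/day) such that the mean callus cell density reaches
    the target at ``target_day`` when infiltrating from the external callus
    surface.  Monotone bisection; returns the upper end of the final bracket
    so the replayed mean is >= target.  Deterministic.
    """
    sources = op.mesh.callus_surface_nodes

    def day14_mean(D: float) -> float:
        rho = np.zeros(op.mesh.n_nodes)
        for _ in range(int(round(target_day / dt))):
            rho = diffuse_step(op, rho, D, dt, sources)
        return mean_callus_density(op, rho)

    lo, hi = bracket
    f_lo, f_hi = day14_mean(lo), day14_mean(hi)
    if not (f_lo < target_mean <= f_hi):
        raise CalibrationError(
            f"target mean {target_mean} not bracketed: f({lo})={f_lo:.4f}, f({hi})={f_hi:.4f}"
        )
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if day14_mean(mid) >= target_mean:
            hi = mid
        else:
            lo = mid
    return hi


def initial_transport_field(mesh: HealingMesh) -> TransportField:
    """Day-0 transport state: callus deprived of cells, vessels and oxygen.

    The external callus surface is the Dirichlet source for all three
    species (extrinsic healing compartment); nodes interior to the stumps
    are native vascularized tissue held at 1.
    """
    n = mesh.n_nodes
    callus_nodes = np.unique(mesh.elements[mesh.region == REGION_CALLUS].ravel())
    stump_only = np.setdiff1d(np.arange(n), callus_nodes)

    cells = np.zeros(n)
    angio = np.zeros(n)
    oxygen = np.zeros(n)
    cells[stump_only] = 1.0
    angio[stump_only] = 1.0
    oxygen[stump_only] = 1.0

    surf = mesh.callus_surface_nodes
    for a in (cells, angio, oxygen):
        a[surf] = 1.0

    # cells infiltrate from the extrinsic compartment only; the native stump
    # cellularity is an initial condition, not a clamped source
    fld = TransportField(
        cells=cells,
        angio=angio,
        oxygen=oxygen,
        cell_sources=surf,
        angio_sources=np.union1d(surf, stump_only),
        oxygen_sources=np.union1d(surf, stump_only),
    )
    return fld


def element_average(mesh: HealingMesh, nodal: np.ndarray) -> np.ndarray:
    """Nodal field averaged to element centroids."""
    return np.asarray(nodal)[mesh.elements].mean(axis=1)


def node_average(op: FEOperator, elem_values: np.ndarray) -> np.ndarray:
    """Element field volume-weighted to nodes."""
    mesh = op.mesh
    out = np.zeros(mesh.n_nodes)
    np.add.at(out, mesh.elements.ravel(), (op.me_lumped * np.asarray(elem_values)[:, None]).ravel())
    return out / op.lumped_mass
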