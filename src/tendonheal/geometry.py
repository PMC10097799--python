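"""Idealized stump--callus geometry for the healing tendon.

The healing Achilles tendon is modeled as two cylindrical tendon stumps
(radius ``stump_radius``) joined by a bulging callus whose radius follows a
smooth cosine (``sin^2``) profile up to ``callus_radius`` at mid-length.
The mesh is all-hexahedral: each cross-section is a structured quad grid on
the square ``[-1, 1]^2`` mapped onto a disk with the elliptical grid mapping

    x = u * sqrt(1 - v^2 / 2),   y = v * sqrt(1 - u^2 / 2)

and scaled by the local profile radius.  Coordinates are in mm and the
tendon long axis is z.  Element data live at centroids; transport fields
live at nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

REGION_STUMP = 0
REGION_CALLUS = 1

# 2x2x2 Gauss quadrature on [-1,1]^3
_G = 1.0 / np.sqrt(3.0)
GAUSS_POINTS = np.array(
    [(sx * _G, sy * _G, sz * _G) for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)]
)
# VTK hexahedron corner ordering in reference coordinates
HEX_CORNERS = np.array(
    [
        (-1, -1, -1),
        (1, -1, -1),
        (1, 1, -1),
        (-1, 1, -1),
        (-1, -1, 1),
        (1, -1, 1),
        (1, 1, 1),
        (-1, 1, 1),
    ],
    dtype=float,
)


class ConfigurationError(ValueError):
    """Invalid geometry or simulation configuration."""


class MeshError(ValueError):
    """Inconsistent or degenerate mesh."""


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the idealized axisymmetric stump--callus profile.

    All lengths in mm.  Defaults are order-of-magnitude plausible for a rat
    Achilles tendon: stump radius 1.0, callus max radius 2.5, callus length
    5.0, stump length 3.0 on each side.
    """

    stump_radius: float = 1.0
    stump_length: float = 3.0
    callus_radius: float = 2.5
    callus_length: float = 5.0
    n_cross: int = 8  # elements across the diameter
    n_axial_stump: int = 3  # axial elements per stump
    n_axial_callus: int = 8  # axial elements in the callus

    def validate(self) -> None:
        if min(self.stump_radius, self.stump_length, self.callus_radius, self.callus_length) <= 0:
            raise ConfigurationError("all geometry dimensions must be positive")
        if self.callus_radius < self.stump_radius:
            raise ConfigurationError("callus max radius must be >= stump radius")
        if min(self.n_cross, self.n_axial_stump, self.n_axial_callus) < 1:
            raise ConfigurationError("element counts must be >= 1")

    @property
    def total_length(self) -> float:
        return 2.0 * self.stump_length + self.callus_length


def profile_radius(z: np.ndarray | float, params: GeometryParams) -> np.ndarray | float:
    """Outer radius of the tendon profile at axial position ``z`` (mm)."""
    z = np.asarray(z, dtype=float)
    ls, lc = params.stump_length, params.callus_length
    bulge = params.callus_radius - params.stump_radius
    xi = np.clip((z - ls) / lc, 0.0, 1.0)
    in_callus = (z > ls) & (z < ls + lc)
    r = params.stump_radius + np.where(in_callus, bulge * np.sin(np.pi * xi) ** 2, 0.0)
    return r if r.ndim else float(r)


def profile_volume(params: GeometryParams) -> float:
    """Closed-form solid-of-revolution volume of the parameterized profile.

    V = 2 pi r_s^2 L_s + pi L_c (r_s^2 + r_s a + 3 a^2 / 8) with
    a = callus_radius - stump_radius, using int sin^2 = L/2, int sin^4 = 3L/8.
    """
    rs, a = params.stump_radius, params.callus_radius - params.stump_radius
    v_stumps = 2.0 * np.pi * rs**2 * params.stump_length
    v_callus = np.pi * params.callus_length * (rs**2 + rs * a + 0.375 * a**2)
    return v_stumps + v_callus


@dataclass
class HealingMesh:
    """All-hex mesh of the stump--callus construct with region and boundary sets."""

    nodes: np.ndarray  # (N, 3) mm
    elements: np.ndarray  # (E, 8) int, VTK hexahedron ordering
    region: np.ndarray  # (E,) REGION_STUMP | REGION_CALLUS
    fixed_nodes: np.ndarray  # node ids on the fixed end (z = 0)
    loaded_nodes: np.ndarray  # node ids on the loaded end (z = L)
    callus_surface_nodes: np.ndarray  # external (lateral) callus surface
    lateral_surface_nodes: np.ndarray  # full lateral surface (stumps + callus)
    params: GeometryParams | None = None
    volumes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.elements.min() < 0 or self.elements.max() >= len(self.nodes):
            raise MeshError("element references node index out of range")
        self.volumes = element_volumes(self)
        if len(self.callus_surface_nodes) == 0:
            raise MeshError("external callus surface set is empty")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def callus_elements(self) -> np.ndarray:
        return np.flatnonzero(self.region == REGION_CALLUS)

    @property
    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def is_connected(self) -> bool:
        e = np.repeat(np.arange(self.n_elements), 8)
        n = self.elements.ravel()
        adj = coo_matrix((np.ones(len(n)), (e, n)), shape=(self.n_elements, self.n_nodes))
        graph = adj @ adj.T
        return connected_components(graph, directed=False, return_labels=False) == 1


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """d N_a / d xi_j for the 8-node trilinear hex at reference point xi -> (8, 3)."""
    g = np.empty((8, 3))
    for a, (cx, cy, cz) in enumerate(HEX_CORNERS):
        g[a, 0] = 0.125 * cx * (1 + cy * xi[1]) * (1 + cz * xi[2])
        g[a, 1] = 0.125 * cy * (1 + cx * xi[0]) * (1 + cz * xi[2])
        g[a, 2] = 0.125 * cz * (1 + cx * xi[0]) * (1 + cy * xi[1])
    return g


def shape_functions(xi: np.ndarray) -> np.ndarray:
    n = np.empty(8)
    for a, (cx, cy, cz) in enumerate(HEX_CORNERS):
        n[a] = 0.125 * (1 + cx * xi[0]) * (1 + cy * xi[1]) * (1 + cz * xi[2])
    return n


# gradients precomputed at the 8 Gauss points
_GAUSS_GRADS = np.stack([_shape_gradients(xi) for xi in GAUSS_POINTS])  # (8, 8, 3)
_GAUSS_N = np.stack([shape_functions(xi) for xi in GAUSS_POINTS])  # (8, 8)


def element_volumes(mesh: HealingMesh | np.ndarray, elements: np.ndarray | None = None) -> np.ndarray:
    """Exact (Gauss 2x2x2) volumes of trilinear hexahedra; raises on inversion."""
    if isinstance(mesh, HealingMesh):
        coords = mesh.nodes[mesh.elements]  # (E, 8, 3)
    else:
        coords = np.asarray(mesh)[elements]
    # J_g = grads_g^T @ X  -> (E, 8gp, 3, 3)
    jac = np.einsum("gaj,eak->egjk", _GAUSS_GRADS, coords)
    det = np.linalg.det(jac)
    if np.any(det <= 0):
        bad = np.flatnonzero(np.any(det <= 0, axis=1))
        raise MeshError(f"inverted element(s) with non-positive Jacobian: {bad[:5].tolist()}")
    return det.sum(axis=1)


def _disk_map(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Elliptical mapping of the square [-1,1]^2 onto the unit disk."""
    return u * np.sqrt(1.0 - 0.5 * v**2), v * np.sqrt(1.0 - 0.5 * u**2)


def build_mesh(params: GeometryParams | None = None) -> HealingMesh:
    """Build the idealized stump--callus hex mesh.

    Two cylindrical stump regions joined by a barrel-shaped (bulging) callus;
    deterministic for fixed params.
    """
    params = params or GeometryParams()
    params.validate()

    nc = params.n_cross
    n_layers = 2 * params.n_axial_stump + params.n_axial_callus
    ls, lc = params.stump_length, params.callus_length
    z_levels = np.concatenate(
        [
            np.linspace(0.0, ls, params.n_axial_stump + 1),
            np.linspace(ls, ls + lc, params.n_axial_callus + 1)[1:],
            np.linspace(ls + lc, params.total_length, params.n_axial_stump + 1)[1:],
        ]
    )

    u = np.linspace(-1.0, 1.0, nc + 1)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    dx, dy = _disk_map(uu, vv)  # unit-disk template, (nc+1, nc+1)

    n_per_layer = (nc + 1) ** 2
    nodes = np.empty((len(z_levels) * n_per_layer, 3))
    for k, z in enumerate(z_levels):
        r = profile_radius(z, params)
        sl = slice(k * n_per_layer, (k + 1) * n_per_layer)
        nodes[sl, 0] = (r * dx).ravel()
        nodes[sl, 1] = (r * dy).ravel()
        nodes[sl, 2] = z

    def nid(i: int, j: int, k: int) -> int:
        return k * n_per_layer + i * (nc + 1) + j

    elements = []
    region = []
    for k in range(n_layers):
        zc = 0.5 * (z_levels[k] + z_levels[k + 1])
        reg = REGION_CALLUS if ls < zc < ls + lc else REGION_STUMP
        for i in range(nc):
            for j in range(nc):
                elements.append(
                    [
                        nid(i, j, k),
                        nid(i + 1, j, k),
                        nid(i + 1, j + 1, k),
                        nid(i, j + 1, k),
                        nid(i, j, k + 1),
                        nid(i + 1, j, k + 1),
                        nid(i + 1, j + 1, k + 1),
                        nid(i, j + 1, k + 1),
                    ]
                )
                region.append(reg)
    elements = np.array(elements, dtype=np.int64)
    region = np.array(region, dtype=np.int64)

    on_rim = (np.abs(np.abs(uu) - 1.0) < 1e-12) | (np.abs(np.abs(vv) - 1.0) < 1e-12)
    rim_local = np.flatnonzero(on_rim.ravel())
    lateral = np.concatenate([k * n_per_layer + rim_local for k in range(len(z_levels))])
    z_lat = nodes[lateral, 2]
    callus_surface = lateral[(z_lat >= ls - 1e-12) & (z_lat <= ls + lc + 1e-12)]

    mesh = HealingMesh(
        nodes=nodes,
        elements=elements,
        region=region,
        fixed_nodes=np.arange(n_per_layer),
        loaded_nodes=np.arange(n_layers * n_per_layer, (n_layers + 1) * n_per_layer),
        callus_surface_nodes=callus_surface,
        lateral_surface_nodes=lateral,
        params=params,
    )
    return mesh


def fixture_single_element() -> HealingMesh:
    """Unit-cube single-hex fixture (callus region, fixed z=0 / loaded z=1 faces)."""
    return fixture_bar(1)


def fixture_bar(n: int) -> HealingMesh:
    """Straight bar of ``n`` unit-cube hexes in series along z (callus region)."""
    if n < 1:
        raise ConfigurationError("bar must have at least one element")
    square = np.array([(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)])
    nodes = np.array([(x, y, float(k)) for k in range(n + 1) for x, y in square])
    elements = np.array(
        [[4 * k, 4 * k + 1, 4 * k + 2, 4 * k + 3, 4 * k + 4, 4 * k + 5, 4 * k + 6, 4 * k + 7] for k in range(n)],
        dtype=np.int64,
    )
    all_nodes = np.arange(len(nodes))
    return HealingMesh(
        nodes=nodes,
        elements=elements,
        region=np.full(n, REGION_CALLUS, dtype=np.int64),
        fixed_nodes=np.arange(4),
        loaded_nodes=np.arange(4 * n, 4 * n + 4),
        callus_surface_nodes=all_nodes,
        lateral_surface_nodes=all_nodes,
        params=None,
    )
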