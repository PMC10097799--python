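"""Per-element tissue bookkeeping: production, degradation, material state,
and collagen fibril reorientation.

The callus starts at 10% tendon density (relative to the stumps) with 13
randomly oriented fibrils per element.  Tissue is produced at its daily rate
scaled linearly by the local cell density; as one tissue type is produced
the other types degrade at the same rate, apportioned proportionally to
their current densities.  During the first five days an inflammatory
baseline produces tendon at 50% of the default rate independent of the
mechanical stimulus.  Fibrils rotate toward the maximum principal strain
direction, reaching longitudinal alignment in four weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import HealingMesh, REGION_CALLUS, REGION_STUMP
from .mechanics import mixture_multiplier

TISSUE_INDEX = {"fat": 0, "tendon": 1, "cartilage": 2, "bone": 3}
N_FIBRILS = 13

#: default daily production rates (fraction/day): tendon/cartilage/fat at the
#: default rate, bone-like tissue slower
DEFAULT_RATE = 0.02
BONE_RATE = 0.012
INFLAMMATORY_DAYS = 5
INFLAMMATORY_FACTOR = 0.5
STIFFNESS_FLOOR = 0.01
ALIGNMENT_DAYS = 28.0


class StateError(RuntimeError):
    pass


@dataclass
class ElementState:
    """Struct-of-arrays tissue state for all elements of one mesh."""

    rhoF: np.ndarray
    rhoT: np.ndarray
    rhoC: np.ndarray
    rhoB: np.ndarray
    cells: np.ndarray  # per-element cell density fraction
    fibrils: np.ndarray  # (E, 13, 3) unit vectors
    region: np.ndarray  # REGION_STUMP | REGION_CALLUS
    ref_angles: np.ndarray | None = None  # day-0 fibril-to-target angles (rad)

    @property
    def n_elements(self) -> int:
        return len(self.rhoT)

    @property
    def densities(self) -> np.ndarray:
        return np.stack([self.rhoF, self.rhoT, self.rhoC, self.rhoB])

    def total(self) -> np.ndarray:
        return self.rhoF + self.rhoT + self.rhoC + self.rhoB

    def copy(self) -> "ElementState":
        return ElementState(
            self.rhoF.copy(), self.rhoT.copy(), self.rhoC.copy(), self.rhoB.copy(),
            self.cells.copy(), self.fibrils.copy(), self.region.copy(),
            None if self.ref_angles is None else self.ref_angles.copy(),
        )


def random_unit_vectors(rng: np.random.Generator, shape) -> np.ndarray:
    v = rng.normal(size=(*shape, 3))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def initial_state(mesh: HealingMesh, rng: np.random.Generator | None = None,
                  initial_tendon: float = 0.10) -> ElementState:
    """Day-0 state: stumps at full aligned tendon, callus at 10% random tendon."""
    rng = rng or np.random.default_rng(0)
    E = mesh.n_elements
    callus = mesh.region == REGION_CALLUS
    rhoT = np.where(callus, initial_tendon, 1.0)
    fibrils = np.zeros((E, N_FIBRILS, 3))
    fibrils[:, :, 2] = 1.0  # stumps: aligned with the tendon axis
    fibrils[callus] = random_unit_vectors(rng, (int(callus.sum()), N_FIBRILS))
    return ElementState(
        rhoF=np.zeros(E),
        rhoT=rhoT,
        rhoC=np.zeros(E),
        rhoB=np.zeros(E),
        cells=np.where(callus, 0.0, 1.0),
        fibrils=fibrils,
        region=mesh.region.copy(),
    )


def produce_and_degrade(
    state: ElementState,
    target: np.ndarray,
    rate: np.ndarray,
    dt: float,
    day: int,
    default_rate: float = DEFAULT_RATE,
) -> ElementState:
    """One daily production/degradation update (in place; returns state).

    ``target`` is an object array of tissue labels (or None for no
    production) and ``rate`` the matching daily rates.  The realized
    increment is rate * cell density * dt; the other tissues jointly lose
    min(increment, their total), split proportionally to their densities.
    During the inflammatory phase (day <= 5) every cellularized callus
    element produces tendon at 50% of the default rate regardless of the
    mechanical stimulus.  Stump elements are immutable.
    """
    E = state.n_elements
    target = np.asarray(target, dtype=object)
    rate = np.asarray(rate, dtype=float).copy()
    if day <= INFLAMMATORY_DAYS:
        target = np.full(E, "tendon", dtype=object)
        rate[:] = INFLAMMATORY_FACTOR * default_rate

    unknown = [t for t in set(target.tolist()) if t is not None and t not in TISSUE_INDEX]
    if unknown:
        raise StateError(f"unknown tissue label(s): {unknown}")
    if np.any(rate < 0):
        raise StateError("production rates must be non-negative")

    dens = np.stack([state.rhoF, state.rhoT, state.rhoC, state.rhoB], axis=1)  # (E, 4)
    active = (state.region == REGION_CALLUS) & (target != None)  # noqa: E711
    delta = rate * state.cells * dt

    for tissue, ti in TISSUE_INDEX.items():
        m = active & (target == tissue)
        if not m.any():
            continue
        d = delta[m]
        others = np.delete(np.arange(4), ti)
        others_total = dens[m][:, others].sum(axis=1)
        loss = np.minimum(d, others_total)
        gain = np.minimum(d, 1.0 - dens[m, ti])
        total = dens[m].sum(axis=1)
        gain = np.minimum(gain, 1.0 - (total - loss))
        gain = np.maximum(gain, 0.0)
        scale = np.ones_like(others_total)
        nz = others_total > 0
        scale[nz] = 1.0 - loss[nz] / others_total[nz]
        block = dens[m]
        block[:, others] *= scale[:, None]
        block[:, ti] += gain
        dens[m] = block

    dens = np.clip(dens, 0.0, 1.0)
    state.rhoF, state.rhoT, state.rhoC, state.rhoB = (dens[:, i].copy() for i in range(4))
    return state


def update_material_state(state: ElementState, floor: float = STIFFNESS_FLOOR) -> np.ndarray:
    """Mixture multipliers per element, floored for numerical robustness.

    Stump elements are pinned at the intact value 1; acellular early-callus
    elements with near-zero total density are floored at ``floor`` to keep
    the FE system nonsingular.
    """
    mult = mixture_multiplier(state.rhoF, state.rhoT, state.rhoC, state.rhoB)
    mult = np.maximum(mult, floor)
    return np.where(state.region == REGION_STUMP, 1.0, mult)


def reorient_fibrils(
    state: ElementState,
    target: np.ndarray,
    dt: float = 1.0,
    total_alignment_days: float = ALIGNMENT_DAYS,
) -> ElementState:
    """Rotate fibrils toward the maximum-principal-strain direction.

    Each fibril rotates in the plane it spans with the target by a fixed
    daily angle equal to its day-0 reference angle divided by the alignment
    horizon (four weeks), capped at the remaining angle, so alignment
    completes in ``total_alignment_days`` regardless of the starting angle.
    Directions are sign-symmetric (v and -v equivalent).  Stump fibrils are
    immutable.
    """
    target = np.asarray(target, dtype=float)
    nrm = np.linalg.norm(target, axis=-1, keepdims=True)
    if np.any(nrm == 0):
        raise StateError("zero-length reorientation target")
    t = target / nrm  # (E, 3)

    v = state.fibrils  # (E, 13, 3)
    dots = np.einsum("efk,ek->ef", v, t)
    sign = np.where(dots < 0, -1.0, 1.0)
    teff = sign[:, :, None] * t[:, None, :]  # flip target into the fibril hemisphere
    cosang = np.clip(np.abs(dots), -1.0, 1.0)
    angle = np.arccos(cosang)  # (E, 13) in [0, pi/2]

    if state.ref_angles is None:
        state.ref_angles = angle.copy()
    step = state.ref_angles / total_alignment_days * dt
    step = np.minimum(step, angle)

    # rotation in the (v, t) plane: v' = v cos a + w sin a, w ⟂ v toward t
    w = teff - cosang[:, :, None] * v
    wn = np.linalg.norm(w, axis=-1, keepdims=True)
    w = np.divide(w, wn, out=np.zeros_like(w), where=wn > 1e-15)
    rotated = v * np.cos(step)[:, :, None] + w * np.sin(step)[:, :, None]
    rotated /= np.linalg.norm(rotated, axis=-1, keepdims=True)

    callus = state.region == REGION_CALLUS
    state.fibrils[callus] = rotated[callus]
    return state
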