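"""Summaries of a healing run: bone volume, temporal curves, field export,
cross-algorithm comparison tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import REGION_CALLUS, HealingMesh
from .remodeling import ElementState
from .simulation import HealingHistory
from .transport import TransportField
from .mechanics import StimulusField
from . import vtkio

#: a tissue is considered present once its mean callus density exceeds this
#: fraction (0.1%), which guards against float dust
FIRST_APPEARANCE_THRESHOLD = 1e-3


class AnalysisError(ValueError):
    pass


def bone_volume(rhoB: np.ndarray, volumes: np.ndarray, callus_mask: np.ndarray | None = None) -> float:
    """Integral of element bone density times element volume (mm^3) over the callus."""
    rhoB = np.asarray(rhoB, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if rhoB.shape != volumes.shape:
        raise AnalysisError("density and volume arrays must have matching lengths")
    if callus_mask is not None:
        rhoB, volumes = rhoB[callus_mask], volumes[callus_mask]
    return float(np.sum(rhoB * volumes))


def temporal_curves(history: HealingHistory) -> pd.DataFrame:
    """Tidy long-format table day x variable (densities in %, stiffness N/mm,
    bone volume mm^3)."""
    if len(history.table) == 0:
        raise AnalysisError("empty history")
    t = history.table
    rows = []
    for var in ("rhoF", "rhoT", "rhoC", "rhoB"):
        rows.append(pd.DataFrame({"day": t["day"], "variable": var, "value": 100.0 * t[var]}))
    for var in ("stiffness", "bone_volume"):
        rows.append(pd.DataFrame({"day": t["day"], "variable": var, "value": t[var]}))
    return pd.concat(rows, ignore_index=True)


def first_appearance_day(history: HealingHistory, tissue: str) -> float:
    """First day the mean callus density of a tissue exceeds 0.1% (NaN if never)."""
    col = {"fat": "rhoF", "tendon": "rhoT", "cartilage": "rhoC", "bone": "rhoB"}[tissue]
    t = history.table
    base = t[col].iloc[0]
    above = t[t[col] > base + FIRST_APPEARANCE_THRESHOLD]
    return float(above["day"].iloc[0]) if len(above) else float("nan")


def summary_report(histories, labels=None) -> pd.DataFrame:
    """Cross-algorithm table: first-bone day, final densities, stiffness, bone volume."""
    if isinstance(histories, HealingHistory):
        histories = [histories]
    histories = list(histories)
    if not histories:
        raise AnalysisError("need at least one history")
    labels = list(labels) if labels is not None else [h.config.rule_set for h in histories]
    rows = []
    for label, h in zip(labels, histories):
        t = h.table
        rows.append(
            {
                "label": label,
                "first_tendon_day": first_appearance_day(h, "tendon"),
                "first_cartilage_day": first_appearance_day(h, "cartilage"),
                "first_bone_day": first_appearance_day(h, "bone"),
                "final_rhoT_pct": 100.0 * t["rhoT"].iloc[-1],
                "final_rhoC_pct": 100.0 * t["rhoC"].iloc[-1],
                "final_rhoB_pct": 100.0 * t["rhoB"].iloc[-1],
                "final_stiffness": t["stiffness"].iloc[-1],
                "final_bone_volume": t["bone_volume"].iloc[-1],
            }
        )
    return pd.DataFrame(rows)


def export_fields(
    mesh: HealingMesh,
    state: ElementState | None,
    transport_field: TransportField | None,
    stimuli: StimulusField | None,
    path,
) -> None:
    """Write one VTK snapshot: densities/stimuli as cell data (densities in %),
    transport as point data, region labels as integer cell data."""
    cell_data = {"region": mesh.region.astype(np.int64)}
    if state is not None:
        for name, arr in (("rhoF", state.rhoF), ("rhoT", state.rhoT),
                          ("rhoC", state.rhoC), ("rhoB", state.rhoB)):
            if len(arr) != mesh.n_elements:
                raise AnalysisError("state size does not match mesh")
            cell_data[name + "_pct"] = 100.0 * arr
        cell_data["cells_pct"] = 100.0 * state.cells
    if stimuli is not None:
        cell_data.update(
            eps1_pct=stimuli.eps1,
            oss_pct=stimuli.oss,
            hydrostatic_MPa=stimuli.hydrostatic,
            pore_pressure_MPa=stimuli.pore_pressure,
            fluid_flow_ums=stimuli.fluid_flow,
        )
    point_data = {}
    if transport_field is not None:
        point_data = {
            "cells": transport_field.cells,
            "angio": transport_field.angio,
            "oxygen": transport_field.oxygen,
            "vessel": transport_field.vessel_flags.astype(np.int64),
        }
    vtkio.write_vtk(path, mesh.nodes, mesh.elements, cell_data, point_data)


def radial_position(mesh: HealingMesh, element: int) -> float:
    """Normalized radial coordinate (0 = axis, 1 = surface) of an element centroid."""
    from .geometry import profile_radius

    c = mesh.centroids[element]
    r = float(np.hypot(c[0], c[1]))
    if mesh.params is None:
        return r
    return r / float(profile_radius(c[2], mesh.params))


def peak_cartilage_element(history: HealingHistory) -> int:
    """Element whose cartilage density peaked highest over the whole run."""
    return int(np.argmax(history.rhoC_peak))
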