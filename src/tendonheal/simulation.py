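"""Daily iteration loop for 20 weeks of simulated healing.

Each day: (1) assemble materials from the tissue state and solve the 2 N
ramp for the stimulus fields; (2) advance the transport fields (cell
infiltration always; strain-gated angiogenesis, vessel maturation and
oxygen when the rule set needs them); (3) classify each callus element to a
produced tissue (with the endochondral gate for PE-ENDO); (4) produce and
degrade tissue densities; (5) reorient fibrils toward the maximum principal
strain; (6) record mean densities, stiffness at peak load, bone volume and
vascularization.  Deterministic for a fixed config and seed (the RNG is
consumed only by the fibril initialization).
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import differentiation as diff
from . import mechanics, remodeling, transport
from .geometry import REGION_CALLUS, ConfigurationError, GeometryParams, HealingMesh, build_mesh
from .mechanics import FEOperator, LoadProtocol, MaterialParameters
from .transport import AngioGate

RULE_SET_NAMES = ("PE", "PE-HS", "PE-PP", "OSS-FF", "PE-OXY", "PE-ENDO")


@dataclass(frozen=True)
class TransportParams:
    """Transport constants.

    ``D`` is the cell-infiltration diffusivity in mm^2/day; when None it is
    calibrated so the mean callus cell density reaches 95% at day 14.  ``A``
    and ``O`` are the relative angiogenesis and oxygen diffusion factors
    (the study grid 0.25-0.5-1.0); their absolute diffusivities are
    ``A * vascular_ratio * D`` and ``O * vascular_ratio * D``, where
    ``vascular_ratio`` expresses that capillary ingrowth and blood-borne
    oxygen delivery are much slower than cell migration (vessels take most
    of the 20-week horizon to cross the callus, versus two weeks for
    cells).  ``C`` is the cellular oxygen consumption rate (1/day);
    ``a_oss`` the angiogenesis shear-strain threshold (%); ``maturation``
    the vessel maturation threshold (fraction, strict).
    """

    D: float | None = None
    A: float = 0.5
    O: float = 0.5
    C: float = 0.5
    a_oss: float = 6.0
    maturation: float = 0.90
    vascular_ratio: float = 0.125

    def gate(self) -> AngioGate:
        return AngioGate(a_oss=self.a_oss, maturation=self.maturation)


@dataclass(frozen=True)
class SimulationConfig:
    geometry: GeometryParams = field(default_factory=GeometryParams)
    material: MaterialParameters = field(default_factory=MaterialParameters)
    load: LoadProtocol = field(default_factory=LoadProtocol)
    transport: TransportParams = field(default_factory=TransportParams)
    rule_set: str = "PE"
    default_rate: float = remodeling.DEFAULT_RATE  # fraction/day
    bone_rate: float = remodeling.BONE_RATE
    endo: diff.EndoGateParams = field(default_factory=diff.EndoGateParams)
    horizon: int = 140  # days (20 weeks)
    dt: float = 1.0  # days per iteration
    seed: int = 0
    snapshot_every: int = 0  # 0: keep only the final state

    def validate(self) -> None:
        errors = []
        if self.horizon < 0:
            errors.append("horizon must be >= 0")
        if self.dt <= 0:
            errors.append("dt must be positive")
        if self.default_rate < 0 or self.bone_rate < 0:
            errors.append("production rates must be >= 0")
        base = self.rule_set.split()[0]
        if not (base in RULE_SET_NAMES or base.startswith("PE-ENDO")):
            errors.append(f"unknown rule set {self.rule_set!r}")
        try:
            self.geometry.validate()
            self.material.validate()
            self.load.validate()
            self.transport.gate().validate()
            self.endo.validate()
        except ConfigurationError as exc:
            errors.append(str(exc))
        if errors:
            raise ConfigurationError("; ".join(errors))

    @property
    def uses_oxygen(self) -> bool:
        return self.rule_set == "PE-OXY"

    @property
    def endo_enabled(self) -> bool:
        return self.rule_set.startswith("PE-ENDO")


@dataclass
class HealingHistory:
    """Time-indexed record of one healing run."""

    config: SimulationConfig
    mesh: HealingMesh
    table: pd.DataFrame  # one row per day
    final_state: remodeling.ElementState
    final_transport: transport.TransportField
    rhoC_peak: np.ndarray  # elementwise running max of cartilage density
    snapshots: list = field(default_factory=list)
    calibrated_D: float | None = None

    @property
    def days(self) -> np.ndarray:
        return self.table["day"].to_numpy()


def _mean_callus(values: np.ndarray, volumes: np.ndarray, callus: np.ndarray) -> float:
    return float(np.average(values[callus], weights=volumes[callus]))


def _tissue_rates(
    labels: np.ndarray, eps1: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """Daily production rate per element for its selected tissue.

    Tendon uses the strain-magnitude production law in the strain-regulated
    schemes (PE, PE-ENDO, PE-OXY) and the constant default rate in the
    older schemes; cartilage and fat use the default rate; bone its own.
    """
    strain_regulated = config.rule_set.startswith(("PE-ENDO", "PE-OXY")) or config.rule_set == "PE"
    rates = np.zeros(len(labels))
    for i, lab in enumerate(labels):
        if lab is None:
            continue
        if lab == "bone":
            rates[i] = config.bone_rate
        elif lab == "tendon" and strain_regulated:
            rates[i] = diff.tendon_rate_law(max(eps1[i], 0.0), peak_rate=config.default_rate)
        else:
            rates[i] = config.default_rate
    return rates


def run_healing(config: SimulationConfig | None = None, mesh: HealingMesh | None = None,
                op: FEOperator | None = None) -> HealingHistory:
    """Run the iterative healing framework and return its history.

    ``mesh``/``op`` may be passed to reuse a prebuilt mesh and its FE
    operator (they are deterministic functions of the geometry params).
    """
    config = config or SimulationConfig()
    config.validate()
    rs = diff.validate_rule_set(diff.get_rule_set(config.rule_set))

    mesh = mesh or build_mesh(config.geometry)
    op = op or FEOperator(mesh)
    rng = np.random.default_rng(config.seed)
    state = remodeling.initial_state(mesh, rng)
    tf = transport.initial_transport_field(mesh)
    gate = config.transport.gate()

    D = config.transport.D
    if D is None:
        D = transport.calibrate_cell_infiltration(op, dt=config.dt)
    A = config.transport.A * config.transport.vascular_ratio * D
    O = config.transport.O * config.transport.vascular_ratio * D

    callus = mesh.region == REGION_CALLUS
    vols = mesh.volumes
    records = []
    snapshots = []
    rhoC_peak = np.zeros(mesh.n_elements)

    def record(day: int, stiffness: float, mean_oxy: float, vasc_frac: float) -> None:
        records.append(
            {
                "day": day,
                "rhoF": _mean_callus(state.rhoF, vols, callus),
                "rhoT": _mean_callus(state.rhoT, vols, callus),
                "rhoC": _mean_callus(state.rhoC, vols, callus),
                "rhoB": _mean_callus(state.rhoB, vols, callus),
                "stiffness": stiffness,
                "bone_volume": float(np.sum(state.rhoB[callus] * vols[callus])),
                "vascular_fraction": vasc_frac,
                "mean_oxygen": mean_oxy,
            }
        )

    def solve_current():
        mult = remodeling.update_material_state(state)
        C = mechanics.element_elasticity(mult, state.fibrils, config.material)
        stim, end_disp = mechanics.solve_ramp(mesh, C, config.load, config.material, op)
        return stim, config.load.peak_force / end_disp

    stim, stiffness = solve_current()
    record(0, stiffness, float("nan"), 0.0)

    for day in range(1, config.horizon + 1):
        # 1. mechanics with yesterday's end-of-day material state
        stim, stiffness = solve_current()

        # 2. transport
        tf.cells = transport.diffuse_step(op, tf.cells, D, config.dt, tf.cell_sources)
        mean_oxy, vasc_frac = float("nan"), 0.0
        if config.uses_oxygen:
            tf.angio = transport.angiogenesis_step(op, tf.angio, A, config.dt, stim, gate, tf.angio_sources)
            tf = transport.mature_vessels(tf, gate)
            tf.oxygen = transport.oxygen_step(op, tf.oxygen, O, config.transport.C, tf.cells,
                                              config.dt, tf.oxygen_sources)
            mean_oxy = transport.mean_callus_density(op, tf.oxygen)
            vasc_frac = float(tf.vessel_flags.mean())

        state.cells = transport.element_average(mesh, tf.cells)

        # 3. classify
        stim_dict = {
            "eps1": np.maximum(stim.eps1, 0.0),
            "oss": stim.oss,
            "hs": np.maximum(-stim.hydrostatic, 0.0),
            "pp": stim.pore_pressure,
            "pp_abs": np.abs(stim.pore_pressure),
            "ff": stim.fluid_flow,
            "stim": diff.stim_combined(stim.oss, stim.fluid_flow),
            "oxygen": 100.0 * transport.element_average(mesh, tf.oxygen),
            "vascular": _element_vascular(mesh, tf.vessel_flags),
        }
        labels = diff.classify_field(rs, stim_dict)
        if config.endo_enabled:
            labels = np.array(
                [
                    diff.endochondral_gate(lab, e1, rc, rb, config.endo)
                    for lab, e1, rc, rb in zip(labels, stim_dict["eps1"], state.rhoC, state.rhoB)
                ],
                dtype=object,
            )

        # 4. produce / degrade
        rates = _tissue_rates(labels, stim_dict["eps1"], config)
        remodeling.produce_and_degrade(state, labels, rates, config.dt, day, config.default_rate)
        rhoC_peak = np.maximum(rhoC_peak, state.rhoC)

        # 5. reorient fibrils
        remodeling.reorient_fibrils(state, stim.direction, config.dt)

        # 6. record
        record(day, stiffness, mean_oxy, vasc_frac)
        if config.snapshot_every and day % config.snapshot_every == 0:
            snapshots.append((day, state.copy(), copy.deepcopy(tf), stim))

    return HealingHistory(
        config=config,
        mesh=mesh,
        table=pd.DataFrame.from_records(records),
        final_state=state,
        final_transport=tf,
        rhoC_peak=rhoC_peak,
        snapshots=snapshots,
        calibrated_D=D,
    )


def _element_vascular(mesh: HealingMesh, flags: np.ndarray) -> np.ndarray:
    """An element has blood supply if any incident node is a matured vessel."""
    return flags[mesh.elements].any(axis=1).astype(float)


SWEEP_KEYS = {
    "A": ("transport", "A"),
    "O": ("transport", "O"),
    "C": ("transport", "C"),
    "A_OSS": ("transport", "a_oss"),
    "rule_set": ("rule_set",),
    "default_rate": ("default_rate",),
    "bone_rate": ("bone_rate",),
}


def _override(config: SimulationConfig, key: str, value) -> SimulationConfig:
    if key not in SWEEP_KEYS:
        raise ConfigurationError(f"unknown sweep key {key!r}; known: {sorted(SWEEP_KEYS)}")
    path = SWEEP_KEYS[key]
    if len(path) == 1:
        return replace(config, **{path[0]: value})
    sub = replace(getattr(config, path[0]), **{path[1]: value})
    return replace(config, **{path[0]: sub})


def parameter_sweep(
    config: SimulationConfig,
    grid: dict[str, list],
    include_baseline: bool = True,
) -> dict[str, HealingHistory]:
    """One-factor-at-a-time sweep from the base config, same seed throughout.

    Returns a mapping ``label -> history`` with labels like ``"C=0.75"`` plus
    ``"baseline"``.  Unknown keys raise before any run.
    """
    for key in grid:
        if key not in SWEEP_KEYS:
            raise ConfigurationError(f"unknown sweep key {key!r}; known: {sorted(SWEEP_KEYS)}")
    mesh = build_mesh(config.geometry)
    op = FEOperator(mesh)
    base = config
    if base.transport.D is None:
        D = transport.calibrate_cell_infiltration(op, dt=base.dt)
        base = replace(base, transport=replace(base.transport, D=D))

    out: dict[str, HealingHistory] = {}
    if include_baseline:
        out["baseline"] = run_healing(base, mesh=mesh, op=op)
    for key, values in grid.items():
        for v in values:
            out[f"{key}={v}"] = run_healing(_override(base, key, v), mesh=mesh, op=op)
    return out


# --- configuration files -------------------------------------------------

_SECTION_TYPES = {
    "geometry": GeometryParams,
    "material": MaterialParameters,
    "load": LoadProtocol,
    "transport": TransportParams,
    "endo": diff.EndoGateParams,
}


def load_config(path) -> SimulationConfig:
    """Load a YAML run configuration, filling defaults and validating.

    An empty file yields the all-defaults config (PE rule set, 2 N load,
    140 days).  Schema violations are reported all at once.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration root must be a mapping")

    errors = []
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            valid = {f.name for f in dataclasses.fields(cls)}
            bad = set(value) - valid
            if bad:
                errors.append(f"{key}: unknown field(s) {sorted(bad)}")
            else:
                kwargs[key] = cls(**value)
        elif key in {f.name for f in dataclasses.fields(SimulationConfig)}:
            kwargs[key] = value
        else:
            errors.append(f"unknown configuration key {key!r}")
    if errors:
        raise ConfigurationError("; ".join(errors))
    config = SimulationConfig(**kwargs)
    config.validate()
    return config


def resolved_config_yaml(config: SimulationConfig) -> str:
    """Fully resolved config echo for the run log."""
    return yaml.safe_dump(dataclasses.asdict(config), sort_keys=False)
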