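"""Tissue-differentiation rule sets and production-rate laws.

Each rule set maps the per-element biophysical stimuli to the tissue type
produced that day.  Rules are declarative data: a tissue label plus a
conjunction of interval predicates over the stimulus fields

    eps1     max principal strain, %
    oss      octahedral shear strain, %
    hs       compressive hydrostatic stress magnitude, MPa
    pp       pore pressure, MPa (compression positive)
    pp_abs   |pore pressure|, MPa
    ff       fluid flow speed, um/s
    stim     combined Prendergast stimulus oss/3.75 + ff/3
    oxygen   oxygen concentration, %
    vascular blood-supply flag (0/1)

Shipped rule sets: PE (principal strain), PE-HS (strain + hydrostatic
stress, Carter-type), PE-PP (strain + pore pressure, Claes--Heigele-type),
OSS-FF (shear strain + fluid flow, Prendergast-type) and PE-OXY (strain +
oxygen/angiogenesis).  Fibrous-tissue outcomes of the bone-regeneration
schemes play the tendon role here; tendon is the universal fallback except
for PE-OXY, where sites that are neither hypoxic nor vascularized produce
nothing.  Interval boundaries are closed on the cartilage side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .geometry import ConfigurationError

TISSUES = ("fat", "tendon", "cartilage", "bone")
NO_TISSUE = None

STIM_FIELDS = ("eps1", "oss", "hs", "pp", "pp_abs", "ff", "stim", "oxygen", "vascular")


def stim_combined(oss, ff):
    """Combined biophysical stimulus stim = OSS/3.75 + FF/3."""
    return np.asarray(oss, dtype=float) / 3.75 + np.asarray(ff, dtype=float) / 3.0


@dataclass(frozen=True)
class Interval:
    """Half-open/closed interval predicate over one stimulus field."""

    lo: float | None = None
    hi: float | None = None
    lo_closed: bool = True
    hi_closed: bool = True

    def contains(self, x):
        x = np.asarray(x, dtype=float)
        ok = np.ones_like(x, dtype=bool)
        if self.lo is not None:
            ok &= (x >= self.lo) if self.lo_closed else (x > self.lo)
        if self.hi is not None:
            ok &= (x <= self.hi) if self.hi_closed else (x < self.hi)
        return ok


@dataclass(frozen=True)
class Rule:
    tissue: str | None
    predicates: dict[str, Interval]


@dataclass(frozen=True)
class RuleSet:
    """Ordered, mutually exclusive differentiation rules with a fallback tissue."""

    name: str
    rules: tuple[Rule, ...]
    fallback: str | None = "tendon"
    uses_oxygen: bool = False
    _validated: bool = field(default=False, compare=False)

    def required_fields(self) -> set[str]:
        out = set()
        for r in self.rules:
            out |= set(r.predicates)
        return out


def _iv(lo=None, hi=None, lo_closed=True, hi_closed=True) -> Interval:
    return Interval(lo, hi, lo_closed, hi_closed)


def builtin_rule_sets() -> dict[str, RuleSet]:
    """The five shipped rule tables (PE-ENDO reuses PE plus the gate)."""
    pe = RuleSet(
        name="PE",
        rules=(
            Rule("bone", {"eps1": _iv(hi=2.0, hi_closed=False)}),
            Rule("cartilage", {"eps1": _iv(lo=2.0, hi=4.0)}),
        ),
        fallback="tendon",
    )
    pe_hs = RuleSet(
        name="PE-HS",
        rules=(
            Rule("cartilage", {"eps1": _iv(hi=5.0, hi_closed=False), "hs": _iv(lo=0.2)}),
            Rule("bone", {"eps1": _iv(hi=5.0, hi_closed=False), "hs": _iv(hi=0.2, hi_closed=False)}),
        ),
        fallback="tendon",
    )
    pe_pp = RuleSet(
        name="PE-PP",
        rules=(
            Rule(
                "bone",
                {"eps1": _iv(hi=5.0, hi_closed=False), "pp_abs": _iv(hi=0.15, hi_closed=False)},
            ),
            Rule("cartilage", {"eps1": _iv(hi=15.0, hi_closed=False), "pp": _iv(lo=0.15)}),
        ),
        fallback="tendon",
    )
    oss_ff = RuleSet(
        name="OSS-FF",
        rules=(
            Rule("bone", {"stim": _iv(hi=1.0, hi_closed=False)}),
            Rule("cartilage", {"stim": _iv(lo=1.0, hi=3.0)}),
        ),
        fallback="tendon",
    )
    # Hypoxia (cartilage) takes precedence; at normoxic vascularized sites the
    # strain thresholds select fat / bone / tendon; elsewhere nothing forms.
    pe_oxy = RuleSet(
        name="PE-OXY",
        rules=(
            Rule("cartilage", {"oxygen": _iv(hi=3.0, hi_closed=False)}),
            Rule(
                "fat",
                {"oxygen": _iv(lo=3.0), "vascular": _iv(lo=1.0), "eps1": _iv(lo=25.0, lo_closed=False)},
            ),
            Rule(
                "bone",
                {"oxygen": _iv(lo=3.0), "vascular": _iv(lo=1.0), "eps1": _iv(hi=2.0, hi_closed=False)},
            ),
            Rule(
                "tendon",
                {"oxygen": _iv(lo=3.0), "vascular": _iv(lo=1.0), "eps1": _iv(lo=2.0, hi=25.0)},
            ),
        ),
        fallback=None,
        uses_oxygen=True,
    )
    return {rs.name: rs for rs in (pe, pe_hs, pe_pp, oss_ff, pe_oxy)}


def get_rule_set(name: str) -> RuleSet:
    """Look up a shipped rule set; PE-ENDO variants map onto the PE table."""
    sets = builtin_rule_sets()
    if name.startswith("PE-ENDO"):
        return replace(sets["PE"], name=name)
    if name not in sets:
        raise ConfigurationError(f"unknown rule set {name!r}; choose from {sorted(sets)} or PE-ENDO")
    return sets[name]


def validate_rule_set(rs: RuleSet, n_samples: int = 4000, seed: int = 0) -> RuleSet:
    """Randomized exclusivity/exhaustiveness check.

    Draws random stimulus tuples over generous ranges and verifies that at
    most one explicit rule matches each (the fallback covers the rest).
    """
    rng = np.random.default_rng(seed)
    samples = {
        "eps1": rng.uniform(0, 60, n_samples),
        "oss": rng.uniform(0, 60, n_samples),
        "hs": rng.uniform(0, 2, n_samples),
        "pp": rng.uniform(-2, 2, n_samples),
        "ff": rng.uniform(0, 20, n_samples),
        "oxygen": rng.uniform(0, 100, n_samples),
        "vascular": rng.integers(0, 2, n_samples).astype(float),
    }
    samples["pp_abs"] = np.abs(samples["pp"])
    samples["stim"] = stim_combined(samples["oss"], samples["ff"])
    matches = np.zeros(n_samples, dtype=int)
    for rule in rs.rules:
        ok = np.ones(n_samples, dtype=bool)
        for f, iv in rule.predicates.items():
            ok &= iv.contains(samples[f])
        matches += ok
    if matches.max() > 1:
        raise ConfigurationError(f"rule set {rs.name!r} is not mutually exclusive")
    return replace(rs, _validated=True)


def classify(rs: RuleSet, stimuli: dict) -> str | None:
    """Tissue produced for one element's stimulus tuple (or None: no production)."""
    for rule in rs.rules:
        if all(bool(iv.contains(stimuli[f])) for f, iv in rule.predicates.items()):
            return rule.tissue
    return rs.fallback


def classify_field(rs: RuleSet, stimuli: dict[str, np.ndarray]) -> np.ndarray:
    """Vectorized classification; returns an object array of labels/None."""
    n = len(next(iter(stimuli.values())))
    out = np.full(n, rs.fallback, dtype=object)
    assigned = np.zeros(n, dtype=bool)
    for rule in rs.rules:
        ok = np.ones(n, dtype=bool)
        for f, iv in rule.predicates.items():
            ok &= iv.contains(np.asarray(stimuli[f], dtype=float))
        take = ok & ~assigned
        out[take] = rule.tissue
        assigned |= ok
    return out


@dataclass(frozen=True)
class EndoGateParams:
    """Endochondral ossification gate: bone may only form at low strain on a
    cartilage scaffold (rhoC above threshold) or on existing bone."""

    strain_threshold: float = 2.0  # %
    cartilage_threshold: float = 0.25  # rho_endo^C, fraction (20% or 25%)

    def validate(self) -> None:
        if self.strain_threshold <= 0 or self.cartilage_threshold <= 0:
            raise ConfigurationError("endochondral gate thresholds must be positive")


def endochondral_gate(proposed, eps1, rhoC, rhoB, params: EndoGateParams):
    """Block bone proposals that do not meet the endochondral requirements.

    Bone passes only if eps1 < strain threshold AND (rhoC > rho_endo^C OR
    rhoB > 0); a blocked proposal means no production this iteration.
    Non-bone proposals pass through unchanged.
    """
    if proposed != "bone":
        return proposed
    if eps1 < params.strain_threshold and (rhoC > params.cartilage_threshold or rhoB > 0.0):
        return "bone"
    return NO_TISSUE


def tendon_rate_law(
    eps1,
    peak_rate: float = 0.02,
    peak_strain: float = 15.0,
    cutoff_strain: float = 30.0,
):
    """Strain-magnitude-dependent tendon production rate (fraction/day).

    Production rises linearly from 0 at zero strain to the default rate at
    ``peak_strain`` (15%), then falls linearly to 0 at ``cutoff_strain``
    (30%) and stays 0 beyond: over-strained tissue produces nothing.
    """
    eps1 = np.asarray(eps1, dtype=float)
    if np.any(eps1 < 0):
        raise ValueError("principal strain must be non-negative")
    up = peak_rate * eps1 / peak_strain
    down = peak_rate * (cutoff_strain - eps1) / (cutoff_strain - peak_strain)
    rate = np.where(eps1 <= peak_strain, up, np.maximum(down, 0.0))
    return rate if rate.ndim else float(rate)


def recover_threshold(
    predicate: Callable[[float], bool], lo: float, hi: float, tol: float = 1e-6
) -> float:
    """Bisect a monotone label switch of ``predicate`` over [lo, hi]."""
    p_lo = predicate(lo)
    if predicate(hi) == p_lo:
        raise ValueError("predicate does not switch over the bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if predicate(mid) == p_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def phase_table(rs: RuleSet, x_field: str, y_field: str, x_values, y_values, fixed: dict | None = None) -> list[list[str]]:
    """2D phase diagram of a rule set over a stimulus pair (for `rules validate`)."""
    fixed = dict(fixed or {})
    rows = []
    for y in y_values:
        row = []
        for x in x_values:
            stim = {f: 0.0 for f in STIM_FIELDS}
            stim.update(fixed)
            stim[x_field] = x
            stim[y_field] = y
            if "stim" not in (x_field, y_field) and "stim" not in fixed:
                stim["stim"] = stim_combined(stim["oss"], stim["ff"])
            label = classify(rs, stim)
            row.append(label if label is not None else "-")
        rows.append(row)
    return rows
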