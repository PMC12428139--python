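"""Double-reciprocal geometry and kinetic-mechanism inference.

A dead-end inhibitor's pattern against each substrate (competitive, mixed,
noncompetitive, uncompetitive) together with the geometry of the
initial-velocity double-reciprocal family diagnoses the order of substrate
binding in a two-substrate mechanism.  This module derives the exact algebraic
(slope, intercept) lines each rate law implies in 1/v-vs-1/S space, classifies
fitted inhibition models into pattern regions, and turns a complete 2×2
pattern table into a mechanism call via a packaged, auditable rule table
(``data/mechanism_rules.json``) — the rules are data, not branching code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

from .errors import UsageError, ValidationError
from .fitting import FitResult
from .rate_laws import (CompetitiveModel, MixedModel, RandomBiBiModel,
                        UncompetitiveModel)

__all__ = [
    "InhibitionPattern", "MechanismCall", "reciprocal_lines",
    "intersection_point", "classify_pattern", "infer_mechanism",
    "CELLS", "load_rule_table",
]

#: The four cells of a complete dead-end inhibition study of an A+B reaction.
CELLS = ("analog_a_vs_a", "analog_a_vs_b", "analog_b_vs_a", "analog_b_vs_b")

GEOMETRIES = ("intersecting_on_1s_axis", "intersecting_left", "parallel")

REGIONS = ("on_1v_axis", "left_of_1v_above_1s", "left_of_1v_below_1s",
           "left_of_1v_on_1s_axis", "parallel")


@dataclass(frozen=True)
class InhibitionPattern:
    """Pattern label plus the common intersection of the reciprocal lines."""

    label: str                       # C | MT | NC | UC
    region: str
    intersection_x: float | None     # 1/mM
    intersection_y: float | None     # 1/velocity


@dataclass(frozen=True)
class MechanismCall:
    mechanism: str                   # rapid_equilibrium_random | ordered_* | ambiguous
    evidence: tuple = ()             # ((cell, label), ...)
    annotations: tuple = ()


def load_rule_table() -> dict:
    """Load the packaged dead-end-pattern rule table (JSON)."""
    with resources.files("enzkin.data").joinpath("mechanism_rules.json").open(
            "r", encoding="utf-8") as fh:
        return json.load(fh)


# --- reciprocal-line algebra ---------------------------------------------

def reciprocal_lines(model, levels: Sequence[float]) -> list[tuple[float, float]]:
    """Exact (slope, intercept) of 1/v vs 1/S at each fixed level.

    For inhibition models the levels are inhibitor concentrations; for the
    random bi-bi model they are fixed co-substrate (B) concentrations and the
    lines are 1/v vs 1/A.  Derived by inverting the rate laws algebraically:

    * competitive:   slope = Km(1+I/Ki)/Vmax,      intercept = 1/Vmax
    * mixed:         slope = Km(1+I/Ki)/Vmax,      intercept = (1+I/(αKi))/Vmax
    * uncompetitive: slope = Km/Vmax,              intercept = (1+I/Ki)/Vmax
    * bi-bi:         slope = (Ka/Vmax)(1+Kb/B),    intercept = (1/Vmax)(1+Kb/B)
    """
    if len(levels) < 2:
        raise ValidationError("reciprocal_lines needs >= 2 fixed levels")
    lines = []
    for lev in levels:
        if lev < 0:
            raise ValidationError("fixed levels must be >= 0")
        if isinstance(model, CompetitiveModel):
            lines.append((model.km * (1 + lev / model.ki) / model.vmax,
                          1.0 / model.vmax))
        elif isinstance(model, MixedModel):
            lines.append((model.km * (1 + lev / model.ki) / model.vmax,
                          (1 + lev / (model.alpha * model.ki)) / model.vmax))
        elif isinstance(model, UncompetitiveModel):
            lines.append((model.km / model.vmax,
                          (1 + lev / model.ki) / model.vmax))
        elif isinstance(model, RandomBiBiModel):
            if lev <= 0:
                raise ValidationError("bi-bi fixed co-substrate levels must be > 0")
            factor = 1 + model.kb / lev
            lines.append((model.ka * factor / model.vmax, factor / model.vmax))
        else:
            raise UsageError(f"unsupported model type {type(model).__name__}")
    return lines


def intersection_point(line1: tuple[float, float],
                       line2: tuple[float, float]) -> tuple[float, float] | None:
    """Intersection of two (slope, intercept) lines, or None if parallel."""
    (s1, b1), (s2, b2) = line1, line2
    if s1 == s2:
        return None
    x = (b2 - b1) / (s1 - s2)
    return x, s1 * x + b1


def _fit_to_model(fit: FitResult):
    p = fit.parameters
    if fit.model_id == "C":
        return CompetitiveModel(p["vmax"], p["km"], p["ki"])
    if fit.model_id == "MT":
        return MixedModel(p["vmax"], p["km"], p["ki"], p["alpha"])
    if fit.model_id == "NC":
        return MixedModel(p["vmax"], p["km"], p["ki"], 1.0)
    if fit.model_id == "UC":
        return UncompetitiveModel(p["vmax"], p["km"], p["ki"])
    raise UsageError(f"classify_pattern handles inhibition fits, not {fit.model_id!r}")


def classify_pattern(fit: FitResult, alpha_tol: float = 0.05) -> InhibitionPattern:
    """Map a converged inhibition fit to its double-reciprocal pattern.

    An MT fit whose α lies within ``alpha_tol`` of 1 is reported NC (lines
    meeting on the 1/S axis); an MT fit pinned at the upper α bound is
    reported UC (parallel lines).  Pattern regions depend only on Km, Ki and
    α — rescaling Vmax moves the intersection along 1/v but not across
    regions.
    """
    if not fit.converged:
        raise UsageError("cannot classify an unconverged fit")
    model = _fit_to_model(fit)
    vmax = fit.parameters["vmax"]
    if fit.model_id == "C":
        return InhibitionPattern("C", "on_1v_axis", 0.0, 1.0 / vmax)
    if fit.model_id == "UC":
        return InhibitionPattern("UC", "parallel", None, None)
    # mixed family: intersection at x = −1/(αKm), y = (1 − 1/α)/Vmax
    alpha = 1.0 if fit.model_id == "NC" else fit.parameters["alpha"]
    if fit.model_id == "MT" and alpha >= 0.999e3:  # pinned at upper bound
        return InhibitionPattern("UC", "parallel", None, None)
    x = -1.0 / (alpha * fit.parameters["km"])
    y = (1.0 - 1.0 / alpha) / vmax
    if abs(alpha - 1.0) < alpha_tol:
        return InhibitionPattern("NC", "left_of_1v_on_1s_axis",
                                 -1.0 / fit.parameters["km"], 0.0)
    region = "left_of_1v_below_1s" if alpha < 1.0 else "left_of_1v_above_1s"
    return InhibitionPattern("MT", region, x, y)


# --- mechanism inference -------------------------------------------------

def _normalize_patterns(patterns: Mapping) -> dict[str, str]:
    """Accept cell keys as strings or (analog, substrate) tuples, and values
    as labels or InhibitionPattern objects."""
    key_map = {
        ("analog_a", "A"): "analog_a_vs_a",
        ("analog_a", "B"): "analog_a_vs_b",
        ("analog_b", "A"): "analog_b_vs_a",
        ("analog_b", "B"): "analog_b_vs_b",
    }
    out = {}
    for key, value in patterns.items():
        cell = key_map.get(key, key)
        if cell not in CELLS:
            raise UsageError(f"unknown pattern cell {key!r}")
        label = value.label if isinstance(value, InhibitionPattern) else str(value)
        if label not in ("C", "MT", "NC", "UC"):
            raise UsageError(f"unknown pattern label {label!r} in cell {cell}")
        out[cell] = label
    missing = [c for c in CELLS if c not in out]
    if missing:
        raise UsageError(f"pattern table is missing cell(s): {missing}")
    return out


def _rule_matches(when: Mapping, table: Mapping[str, str], geometry: str) -> bool:
    for key, allowed in when.items():
        observed = geometry if key == "geometry" else table[key]
        if observed not in allowed:
            return False
    return True


def infer_mechanism(patterns: Mapping,
                    initial_velocity_geometry: str) -> MechanismCall:
    """Translate a complete dead-end pattern table into a mechanism call.

    ``patterns`` maps the four cells (A-analog vs A/B, B-analog vs A/B) to
    pattern labels; ``initial_velocity_geometry`` describes the uninhibited
    double-reciprocal family.  The call is produced purely by the packaged
    rule table, so identical inputs always yield identical calls.  Tables the
    rules cannot place are returned as ``ambiguous`` with the violating cells
    listed in the annotations.
    """
    if initial_velocity_geometry not in GEOMETRIES:
        raise UsageError(
            f"geometry must be one of {GEOMETRIES}, got {initial_velocity_geometry!r}")
    table = _normalize_patterns(patterns)
    rules = load_rule_table()
    evidence = tuple((cell, table[cell]) for cell in CELLS)
    annotations: list[str] = []

    call = None
    for rule in rules["rules"]:
        if _rule_matches(rule["when"], table, initial_velocity_geometry):
            call = rule["call"]
            if rule.get("annotation"):
                annotations.append(rule["annotation"])
            break
    if call is None:
        call = rules.get("default_call", "ambiguous")
        random_rule = next(r for r in rules["rules"]
                           if r["call"] == "rapid_equilibrium_random")
        violations = []
        for key, allowed in random_rule["when"].items():
            observed = (initial_velocity_geometry if key == "geometry"
                        else table[key])
            if observed not in allowed:
                violations.append(f"{key}={observed}")
        annotations.append("unplaced pattern table; violating cells: "
                           + ", ".join(violations))

    for extra in rules.get("extra_annotations", []):
        if _rule_matches(extra["when"], table, initial_velocity_geometry):
            annotations.append(extra["annotation"])
    if call == "rapid_equilibrium_random" and rules.get("standing_annotation"):
        annotations.append(rules["standing_annotation"])

    return MechanismCall(mechanism=call, evidence=evidence,
                         annotations=tuple(annotations))
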