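"""Seeded synthetic velocity datasets and DSC traces.

Wet-lab stand-in for the whole pipeline: velocity datasets are drawn on the
preset experiment designs (``data/designs.yaml`` — the concentration grids of
the saturation, bi-substrate, and dead-end inhibition assays) from a chosen
rate law plus a configurable noise model, and DSC traces come from the
two-state simulator plus additive instrument noise.  Every random draw flows
from the ``NoiseModel`` seed, so a fixed seed reproduces datasets
byte-for-byte.

Noise model: v = law(S)·(1 + cv·ε) + floor_sd·ε′ with ε, ε′ i.i.d. standard
normal.  The default 2 % proportional CV is typical of coupled
spectrophotometric PK assays averaged over short initial-rate windows; the
generator does not emulate the coupled LDH/NADH detection chemistry or
instrument drift.

The generating truth is recorded in dataset metadata under the namespaced key
``enzkin:truth`` so that recovery tests can find it but fitting code cannot
read it by accident.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import DesignError, UsageError, ValidationError
from .fitting import MODEL_PARAMS, TRUTH_KEY, VelocityDataset, predict
from .thermal import DSCTrace, simulate_endotherm

__all__ = ["NoiseModel", "DesignSpec", "paper_design", "design_keys",
           "generate_velocities", "generate_dsc"]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description; ``seed`` fixes all randomness."""

    kind: str = "proportional"     # proportional | additive | mixed
    cv: float = 0.02               # fractional SD of the proportional part
    floor_sd: float = 0.0          # additive SD in velocity units
    seed: int = 0
    clip_negative: bool = True

    def __post_init__(self):
        if self.kind not in ("proportional", "additive", "mixed"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0 or self.floor_sd < 0:
            raise ValidationError("cv and floor_sd must be >= 0")


@dataclass(frozen=True)
class DesignSpec:
    """Concentration grid of one experiment (mM) plus replicate count."""

    kind: str
    a_levels: tuple[float, ...]
    b_levels: tuple[float, ...] = ()
    i_levels: tuple[float, ...] = ()
    replicates: int = 3
    note: str = ""

    def __post_init__(self):
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if not self.a_levels:
            raise ValidationError("a_levels must be non-empty")
        if self.kind == "bisubstrate_grid" and not self.b_levels:
            raise ValidationError("bisubstrate_grid needs b_levels")
        if self.kind == "inhibition_grid" and not self.i_levels:
            raise ValidationError("inhibition_grid needs i_levels")


def _load_designs() -> dict:
    with resources.files("enzkin.data").joinpath("designs.yaml").open(
            "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def design_keys() -> list[str]:
    """All recognised preset design keys."""
    return sorted(_load_designs())


def paper_design(figure: str, replicates: int = 3) -> DesignSpec:
    """Look up a preset design by its figure key (see ``design_keys()``)."""
    designs = _load_designs()
    if figure not in designs:
        raise UsageError(
            f"unknown design key {figure!r}; known keys: {sorted(designs)}")
    raw = designs[figure]
    return DesignSpec(kind=raw["kind"],
                      a_levels=tuple(raw["a_levels"]),
                      b_levels=tuple(raw.get("b_levels", ())),
                      i_levels=tuple(raw.get("i_levels", ())),
                      replicates=replicates,
                      note=raw.get("note", ""))


_ARITY = {"mm": "single_substrate", "hill": "single_substrate",
          "bibi": "bisubstrate_grid",
          "C": "inhibition_grid", "MT": "inhibition_grid",
          "UC": "inhibition_grid", "NC": "inhibition_grid"}


def _design_points(design: DesignSpec) -> pd.DataFrame:
    if design.kind == "single_substrate":
        grid = pd.DataFrame({"a": design.a_levels})
        grid["b"] = np.nan
        grid["i"] = 0.0
    elif design.kind == "bisubstrate_grid":
        aa, bb = np.meshgrid(design.a_levels, design.b_levels, indexing="ij")
        grid = pd.DataFrame({"a": aa.ravel(), "b": bb.ravel(), "i": 0.0})
    elif design.kind == "inhibition_grid":
        aa, ii = np.meshgrid(design.a_levels, design.i_levels, indexing="ij")
        grid = pd.DataFrame({"a": aa.ravel(), "b": np.nan, "i": ii.ravel()})
    else:
        raise ValidationError(f"unknown design kind {design.kind!r}")
    return grid


def generate_velocities(design: DesignSpec, model_id: str,
                        parameters: dict[str, float],
                        noise: NoiseModel) -> VelocityDataset:
    """Draw one velocity dataset from a rate law on a design.

    Replicates are independent draws from the seeded generator; with
    ``cv = floor_sd = 0`` the velocities equal the rate law exactly.
    """
    if model_id not in MODEL_PARAMS:
        raise UsageError(f"unknown model_id {model_id!r}")
    if _ARITY[model_id] != design.kind:
        raise DesignError(
            f"model {model_id!r} needs a {_ARITY[model_id]} design, "
            f"got {design.kind}")
    missing = set(MODEL_PARAMS[model_id]) - set(parameters)
    if missing:
        raise ValidationError(f"missing parameters for {model_id}: {sorted(missing)}")

    grid = _design_points(design)
    v_true = predict(model_id, parameters, grid["a"].to_numpy(),
                     grid["b"].to_numpy(), grid["i"].to_numpy())
    rng = np.random.default_rng(noise.seed)
    frames = []
    for rep in range(1, design.replicates + 1):
        v = np.array(v_true, dtype=float, copy=True)
        if noise.kind in ("proportional", "mixed") and noise.cv > 0:
            v = v * (1.0 + noise.cv * rng.standard_normal(v.size))
        if noise.kind in ("additive", "mixed") and noise.floor_sd > 0:
            v = v + noise.floor_sd * rng.standard_normal(v.size)
        if noise.clip_negative:
            v = np.clip(v, 0.0, None)
        rep_frame = grid.copy()
        rep_frame["v"] = v
        rep_frame["replicate"] = f"r{rep}"
        frames.append(rep_frame)
    frame = pd.concat(frames, ignore_index=True)
    metadata = {
        TRUTH_KEY: {"model_id": model_id, "parameters": dict(parameters),
                    "noise": {"kind": noise.kind, "cv": noise.cv,
                              "floor_sd": noise.floor_sd, "seed": noise.seed}},
        "design_note": design.note,
    }
    return VelocityDataset(frame, design.kind, metadata)


def generate_dsc(tm: float, delta_h: float, vant_hoff_h: float,
                 noise: NoiseModel, grid: np.ndarray | None = None,
                 baseline_slope: float = 0.0,
                 label: str = "") -> DSCTrace:
    """Two-state endotherm plus seeded additive noise of SD ``floor_sd``."""
    trace = simulate_endotherm(tm, delta_h, vant_hoff_h,
                               baseline_slope=baseline_slope, grid=grid,
                               label=label)
    if noise.floor_sd == 0:
        return trace
    rng = np.random.default_rng(noise.seed)
    cp = (trace.excess_heat_capacity
          + noise.floor_sd * rng.standard_normal(trace.temperature.size))
    return DSCTrace(temperature=trace.temperature, excess_heat_capacity=cp,
                    scan_rate=trace.scan_rate, label=label)
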