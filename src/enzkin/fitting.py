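"""Nonlinear least-squares estimation of rate-law parameters.

All fits minimize the unweighted sum of squared residuals on untransformed
velocities (double-reciprocal plots are display-only, never the fitting
space).  Positivity is enforced by optimizing in log-parameter space with a
deterministic 8-point multistart lattice bracketing the data-implied scales,
so a fit is a pure function of the dataset.  Bi-substrate and inhibition data
are fitted globally: one parameter vector across every curve simultaneously.

Model selection uses AIC = n·ln(SSE/n) + 2k with a parsimony tie-break:
candidates within ΔAIC < 2 of the minimum are resolved toward the model with
fewer parameters.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConvergenceError, DesignError, UsageError, ValidationError

__all__ = [
    "VelocityPoint", "VelocityDataset", "FitResult", "SelectionResult",
    "predict", "fit_single_substrate", "fit_global_bisubstrate",
    "fit_inhibition", "select_model", "MODEL_PARAMS",
]

#: Metadata key under which the synthetic generator stores its ground truth.
#: Namespaced so fitting code cannot read it by accident; nothing in this
#: module touches dataset metadata at all.
TRUTH_KEY = "enzkin:truth"

DESIGN_KINDS = ("single_substrate", "bisubstrate_grid", "inhibition_grid")

MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "mm": ("vmax", "km"),
    "hill": ("vmax", "k05", "n"),
    "bibi": ("vmax", "ka", "kb"),
    "C": ("vmax", "km", "ki"),
    "MT": ("vmax", "km", "ki", "alpha"),
    "UC": ("vmax", "km", "ki"),
    "NC": ("vmax", "km", "ki"),
}


@dataclass(frozen=True)
class VelocityPoint:
    """One observation: substrate A (mM), optional co-substrate B, inhibitor I,
    and the measured velocity (µmol·min⁻¹·mg⁻¹)."""

    a: float
    v: float
    b: float = float("nan")
    i: float = 0.0
    replicate_id: str = "r1"


class VelocityDataset:
    """Tidy table of initial-velocity observations plus design metadata.

    The universal fitting input: ``frame`` has columns ``a, b, i, v,
    replicate`` (concentrations in mM).  ``design_kind`` is one of
    ``single_substrate | bisubstrate_grid | inhibition_grid``.
    """

    def __init__(self, frame: pd.DataFrame, design_kind: str,
                 metadata: dict | None = None):
        if design_kind not in DESIGN_KINDS:
            raise ValidationError(f"unknown design_kind {design_kind!r}")
        frame = frame.copy()
        if "b" not in frame.columns:
            frame["b"] = np.nan
        if "i" not in frame.columns:
            frame["i"] = 0.0
        if "replicate" not in frame.columns:
            frame["replicate"] = "r1"
        missing = {"a", "v"} - set(frame.columns)
        if missing:
            raise ValidationError(f"dataset frame missing columns {sorted(missing)}")
        if len(frame) == 0:
            raise DesignError("dataset must be non-empty")
        for col in ("a", "b", "i", "v"):
            frame[col] = frame[col].astype(float)
        if (frame[["a", "v"]] < 0).any().any():
            raise ValidationError("concentrations and velocities must be >= 0")
        if design_kind == "bisubstrate_grid" and frame["b"].isna().any():
            raise DesignError("bisubstrate_grid requires a b column without gaps")
        self.frame = frame[["a", "b", "i", "v", "replicate"]]
        self.design_kind = design_kind
        self.metadata = dict(metadata or {})

    @classmethod
    def from_points(cls, points: Sequence[VelocityPoint], design_kind: str,
                    metadata: dict | None = None) -> "VelocityDataset":
        frame = pd.DataFrame({
            "a": [p.a for p in points],
            "b": [p.b for p in points],
            "i": [p.i for p in points],
            "v": [p.v for p in points],
            "replicate": [p.replicate_id for p in points],
        })
        return cls(frame, design_kind, metadata)

    @property
    def points(self) -> Iterator[VelocityPoint]:
        for row in self.frame.itertuples(index=False):
            yield VelocityPoint(a=row.a, v=row.v, b=row.b, i=row.i,
                                replicate_id=str(row.replicate))

    def __len__(self) -> int:
        return len(self.frame)

    def data_hash(self) -> str:
        arr = np.ascontiguousarray(
            self.frame[["a", "b", "i", "v"]].to_numpy(dtype=float))
        return hashlib.sha1(arr.tobytes()).hexdigest()


@dataclass
class FitResult:
    model_id: str
    parameters: dict[str, float]
    stderr: dict[str, float]
    sse: float
    aic: float
    n_obs: int
    converged: bool
    n_starts_used: int
    data_hash: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.parameters)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "model_id": self.model_id,
            "parameters": self.parameters,
            "stderr": self.stderr,
            "sse": self.sse,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "data_hash": self.data_hash,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(model_id=d["model_id"],
                   parameters={k: float(v) for k, v in d["parameters"].items()},
                   stderr={k: float(v) for k, v in d.get("stderr", {}).items()},
                   sse=float(d["sse"]), aic=float(d["aic"]),
                   n_obs=int(d["n_obs"]), converged=bool(d["converged"]),
                   n_starts_used=int(d.get("n_starts_used", 0)),
                   data_hash=d.get("data_hash", ""),
                   metadata=d.get("metadata", {}))


@dataclass
class SelectionResult:
    best: FitResult
    table: pd.DataFrame


# --- model evaluation ----------------------------------------------------

def _eval_model(model_id: str, theta: np.ndarray, a: np.ndarray,
                b: np.ndarray, i: np.ndarray) -> np.ndarray:
    if model_id == "mm":
        vmax, km = theta
        return vmax * a / (km + a)
    if model_id == "hill":
        vmax, k05, n = theta
        an = np.power(a, n)
        return vmax * an / (k05 ** n + an)
    if model_id == "bibi":
        vmax, ka, kb = theta
        return vmax * a * b / (ka * kb + ka * b + kb * a + a * b)
    if model_id == "C":
        vmax, km, ki = theta
        return vmax * a / (km * (1.0 + i / ki) + a)
    if model_id == "MT":
        vmax, km, ki, alpha = theta
        return vmax * a / (km * (1.0 + i / ki) + a * (1.0 + i / (alpha * ki)))
    if model_id == "UC":
        vmax, km, ki = theta
        return vmax * a / (km + a * (1.0 + i / ki))
    if model_id == "NC":
        vmax, km, ki = theta
        return vmax * a / (km * (1.0 + i / ki) + a * (1.0 + i / ki))
    raise UsageError(f"unknown model_id {model_id!r}")


def predict(model_id: str, parameters: dict[str, float], a, b=None, i=None):
    """Evaluate a fitted (or hypothetical) model on concentration arrays."""
    names = MODEL_PARAMS.get(model_id)
    if names is None:
        raise UsageError(f"unknown model_id {model_id!r}")
    theta = np.array([parameters[name] for name in names], dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.zeros_like(a) if b is None else np.asarray(b, dtype=float)
    i = np.zeros_like(a) if i is None else np.asarray(i, dtype=float)
    return _eval_model(model_id, theta, a, b, i)


# --- multistart machinery ------------------------------------------------

_FTOL = 1e-10      # relative SSE change
_MAX_ITER = 500    # per start

def _log_bounds(model_id: str) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for name in MODEL_PARAMS[model_id]:
        if name == "n":
            lo.append(math.log(0.3)); hi.append(math.log(6.0))
        elif name == "alpha":
            lo.append(math.log(1e-3)); hi.append(math.log(1e3))
        else:
            lo.append(math.log(1e-10)); hi.append(math.log(1e10))
    return np.array(lo), np.array(hi)


def _starts(model_id: str, a: np.ndarray, b: np.ndarray,
            i: np.ndarray, v: np.ndarray) -> list[dict[str, float]]:
    """Eight deterministic starting points bracketing the data-implied scales:
    vmax near the top of the observed velocities, K near the median
    concentration, Ki near the median non-zero inhibitor level."""
    vtop = float(np.max(v)) or 1.0
    a_med = float(np.median(a[a > 0])) if np.any(a > 0) else 1.0
    starts = []
    if model_id == "mm":
        for fv in (1.0, 2.0):
            for fk in (0.3, 1.0, 3.0, 9.0):
                starts.append({"vmax": vtop * fv, "km": a_med * fk})
    elif model_id == "hill":
        for fv in (1.0, 2.0):
            for fk in (0.5, 2.0):
                for n0 in (1.0, 2.0):
                    starts.append({"vmax": vtop * fv, "k05": a_med * fk, "n": n0})
    elif model_id == "bibi":
        b_med = float(np.median(b[b > 0])) if np.any(b > 0) else 1.0
        for fv in (1.0, 2.0):
            for fk in (0.3, 1.0, 3.0, 9.0):
                starts.append({"vmax": vtop * fv, "ka": a_med * fk,
                               "kb": b_med * fk})
    else:  # inhibition family
        ipos = i[i > 0]
        i_med = float(np.median(ipos)) if ipos.size else 1.0
        for fv in (1.0, 2.0):
            for fk in (0.3, 1.0, 3.0, 9.0):
                s = {"vmax": vtop * fv, "km": a_med, "ki": i_med * fk}
                if model_id == "MT":
                    s["alpha"] = 1.0
                starts.append(s)
    return starts


def _fit(dataset: VelocityDataset, model_id: str) -> FitResult:
    frame = dataset.frame
    a = frame["a"].to_numpy()
    b = frame["b"].to_numpy()
    i = frame["i"].to_numpy()
    v = frame["v"].to_numpy()
    names = MODEL_PARAMS[model_id]
    lo, hi = _log_bounds(model_id)

    def residual(x: np.ndarray) -> np.ndarray:
        return v - _eval_model(model_id, np.exp(x), a, b, i)

    best = None
    n_used = 0
    for start in _starts(model_id, a, b, i, v):
        n_used += 1
        x0 = np.clip(np.log([start[name] for name in names]), lo, hi)
        res = least_squares(residual, x0, bounds=(lo, hi), method="trf",
                            ftol=_FTOL, xtol=1e-12, gtol=1e-12,
                            max_nfev=_MAX_ITER * (len(names) + 1))
        if best is None or res.cost < best.cost:
            best = res

    converged = bool(best is not None and best.status > 0
                     and np.all(np.isfinite(best.x)))
    theta = np.exp(best.x)
    sse = float(np.sum(residual(best.x) ** 2))
    n = len(v)
    k = len(names)
    aic = n * math.log(max(sse, 1e-300) / n) + 2 * k

    # Gauss–Newton standard errors in the original parameter space:
    # d r/d p = (d r/d log p) / p.
    stderr = {name: float("nan") for name in names}
    if converged and n > k:
        jac_p = best.jac / theta[np.newaxis, :]
        try:
            cov = (sse / (n - k)) * np.linalg.pinv(jac_p.T @ jac_p)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            stderr = {name: float(s) for name, s in zip(names, se)}
        except np.linalg.LinAlgError:
            pass

    result = FitResult(
        model_id=model_id,
        parameters={name: float(t) for name, t in zip(names, theta)},
        stderr=stderr, sse=sse, aic=aic, n_obs=n, converged=converged,
        n_starts_used=n_used, data_hash=dataset.data_hash())
    if not converged:
        raise ConvergenceError(
            f"{model_id} fit failed to converge on all {n_used} starts",
            best=result)
    return result


# --- public fitting operations ------------------------------------------

def fit_single_substrate(dataset: VelocityDataset, model_id: str) -> FitResult:
    """Fit the Michaelis–Menten (``mm``) or Hill (``hill``) law to a
    single-substrate saturation dataset."""
    if model_id not in ("mm", "hill"):
        raise UsageError(f"model_id must be 'mm' or 'hill', got {model_id!r}")
    if dataset.design_kind != "single_substrate":
        raise DesignError(
            f"expected single_substrate design, got {dataset.design_kind}")
    n_levels = dataset.frame["a"].nunique()
    need = 5 if model_id == "hill" else 4
    if n_levels < need:
        raise DesignError(
            f"{model_id} fit needs >= {need} distinct substrate levels, "
            f"got {n_levels}")
    return _fit(dataset, model_id)


def fit_global_bisubstrate(dataset: VelocityDataset) -> FitResult:
    """Globally fit the rapid-equilibrium random bi-bi law to a two-substrate
    grid: one (Vmax, Ka, Kb) across all fixed-co-substrate curves at once."""
    if dataset.design_kind != "bisubstrate_grid":
        raise DesignError(
            f"expected bisubstrate_grid design, got {dataset.design_kind}")
    na = dataset.frame["a"].nunique()
    nb = dataset.frame["b"].nunique()
    if na < 3 or nb < 3:
        raise DesignError(
            f"bi-substrate fit needs >= 3 levels of each substrate "
            f"(got {na} A levels, {nb} B levels); with a single fixed "
            f"co-substrate level Kb is unidentifiable")
    return _fit(dataset, "bibi")


def fit_inhibition(dataset: VelocityDataset, model_id: str) -> FitResult:
    """Globally fit one dead-end inhibition law over all (S, I) pairs.

    ``model_id``: ``C`` (linear competitive), ``MT`` (linear mixed with free
    α), ``UC`` (uncompetitive: slope unchanged), ``NC`` (noncompetitive, the
    α = 1 restriction of MT).
    """
    if model_id not in ("C", "MT", "UC", "NC"):
        raise UsageError(f"model_id must be one of C/MT/UC/NC, got {model_id!r}")
    if dataset.design_kind != "inhibition_grid":
        raise DesignError(
            f"expected inhibition_grid design, got {dataset.design_kind}")
    i_levels = dataset.frame["i"].unique()
    if len(i_levels) < 3 or not np.any(i_levels == 0.0):
        raise DesignError(
            "inhibition fit needs >= 3 inhibitor levels including I = 0")
    return _fit(dataset, model_id)


def select_model(fits: Sequence[FitResult]) -> SelectionResult:
    """Pick the AIC-minimizing fit; ΔAIC < 2 ties resolve to fewer parameters.

    All candidates must have been fitted to the identical dataset.
    """
    if not fits:
        raise UsageError("select_model needs at least one fit")
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise UsageError("select_model requires fits on the identical dataset")
    amin = min(f.aic for f in fits)
    candidates = [f for f in fits if f.aic - amin < 2.0]
    best = min(candidates, key=lambda f: (f.n_params, f.aic))
    table = pd.DataFrame({
        "model_id": [f.model_id for f in fits],
        "n_params": [f.n_params for f in fits],
        "sse": [f.sse for f in fits],
        "aic": [f.aic for f in fits],
        "delta_aic": [f.aic - amin for f in fits],
        "selected": [f is best for f in fits],
    }).sort_values("aic", ignore_index=True)
    return SelectionResult(best=best, table=table)
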