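"""File formats, run configuration, and report rendering.

CSV dialect is pinned package-wide: UTF-8, comma separator, decimal point, LF
line endings, concentrations always in mM.  Velocity files carry their design
kind and metadata in ``#``-prefixed header comments (JSON-encoded), so a
write→read round trip reproduces a dataset exactly; numeric cells are written
with 12 significant digits.

Reporting-layer rounding (2 dp for log efficiencies, nearest integer for kcat
and fold changes) happens here and only here — computations upstream are
never rounded.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, DesignError, ParseError
from .fitting import FitResult, VelocityDataset
from .rate_laws import (EnzymeMassModel, catalytic_efficiency,
                        kcat_from_specific_activity)
from .synthetic_data import NoiseModel

__all__ = ["read_velocity_csv", "write_velocity_csv", "RunConfig",
           "derived_constants_table", "write_report", "artifact_header"]

_VELOCITY_COLUMNS = ("a_mM", "b_mM", "i_mM", "v", "replicate")
_REQUIRED = ("a_mM", "v", "replicate")
_RENAME = {"a_mM": "a", "b_mM": "b", "i_mM": "i"}


def artifact_header(seed: int | None = None, config_hash: str | None = None,
                    **extra: str) -> list[str]:
    """Standard provenance comment lines for every output artifact."""
    lines = [f"# enzkin {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config_hash is not None:
        lines.append(f"# config_hash={config_hash}")
    for key, value in extra.items():
        lines.append(f"# {key}={value}")
    return lines


def write_velocity_csv(dataset: VelocityDataset, path: str | Path,
                       seed: int | None = None) -> None:
    path = Path(path)
    frame = dataset.frame.rename(columns={v: k for k, v in _RENAME.items()})
    frame = frame[list(_VELOCITY_COLUMNS)]
    lines = artifact_header(seed=seed)
    lines.append(f"# design_kind={dataset.design_kind}")
    if dataset.metadata:
        lines.append("# metadata=" + json.dumps(dataset.metadata, sort_keys=True))
    body = frame.to_csv(index=False, float_format="%.12g", lineterminator="\n")
    path.write_text("\n".join(lines) + "\n" + body, encoding="utf-8")


def read_velocity_csv(path: str | Path) -> VelocityDataset:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"velocity file not found: {path}")
    design_kind = "single_substrate"
    metadata: dict = {}
    header_rows = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_rows += 1
            content = line[1:].strip()
            if content.startswith("design_kind="):
                design_kind = content.split("=", 1)[1]
            elif content.startswith("metadata="):
                metadata = json.loads(content.split("=", 1)[1])
    try:
        frame = pd.read_csv(path, skiprows=header_rows)
    except pd.errors.EmptyDataError:
        raise DesignError(f"{path}: empty data section") from None
    missing = set(_REQUIRED) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    unknown = set(frame.columns) - set(_VELOCITY_COLUMNS)
    if unknown:
        raise ParseError(f"{path}: unknown column(s) {sorted(unknown)}")
    if len(frame) == 0:
        raise DesignError(f"{path}: empty data section")
    for col in ("a_mM", "b_mM", "i_mM", "v"):
        if col not in frame.columns:
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2 + header_rows  # 1-based incl. header
            raise ParseError(f"{path}: non-numeric value in column {col!r}, "
                             f"file row {row}")
        frame[col] = coerced
    return VelocityDataset(frame.rename(columns=_RENAME), design_kind, metadata)


@dataclass(frozen=True)
class RunConfig:
    """Top-level run configuration; all randomness flows from ``seed``."""

    binding_constants: Path | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    output_dir: Path = Path(".")
    verbosity: int = 0
    seed: int = 0

    _KNOWN = {"binding_constants", "noise", "output_dir", "verbosity", "seed"}

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        unknown = set(raw) - cls._KNOWN
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        seed = int(raw.get("seed", 0))
        noise_raw = dict(raw.get("noise", {}))
        noise_raw.setdefault("seed", seed)
        bc = raw.get("binding_constants")
        if bc is not None:
            bc = Path(bc)
            if not bc.exists():
                raise ConfigurationError(f"binding-constants file not found: {bc}")
        return cls(binding_constants=bc, noise=NoiseModel(**noise_raw),
                   output_dir=Path(raw.get("output_dir", ".")),
                   verbosity=int(raw.get("verbosity", 0)), seed=seed)

    def config_hash(self) -> str:
        blob = json.dumps({
            "binding_constants": str(self.binding_constants),
            "noise": [self.noise.kind, self.noise.cv, self.noise.floor_sd,
                      self.noise.seed, self.noise.clip_negative],
            "seed": self.seed,
        }, sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def derived_constants_table(rows: list[dict],
                            mass: EnzymeMassModel) -> pd.DataFrame:
    """Render fitted constants as a derived-constants table.

    Each input row needs ``substrate``, ``k`` (the apparent K in mM) and
    ``vmax``; ``n`` (Hill coefficient) is optional.  Output columns follow
    the conventional layout: K_app, n, V_max, k_cat, log k_cat/K, with the
    reporting rounding applied (kcat to the nearest integer, log efficiency
    to 2 dp).
    """
    out = []
    for row in rows:
        kcat = kcat_from_specific_activity(row["vmax"], mass)
        out.append({
            "substrate": row["substrate"],
            "K_app_mM": row["k"],
            "n": row.get("n", float("nan")),
            "Vmax_umol_min_mg": row["vmax"],
            "kcat_s": int(round(kcat)),
            "log_kcat_K": round(catalytic_efficiency(kcat, row["k"]), 2),
        })
    return pd.DataFrame(out, columns=["substrate", "K_app_mM", "n",
                                      "Vmax_umol_min_mg", "kcat_s",
                                      "log_kcat_K"])


def rows_from_fits(fits: list[tuple[str, FitResult]]) -> list[dict]:
    """Convert labelled fits into table rows (K picked per model family)."""
    rows = []
    for substrate, fit in fits:
        p = fit.parameters
        if fit.model_id == "mm":
            rows.append({"substrate": substrate, "k": p["km"], "vmax": p["vmax"]})
        elif fit.model_id == "hill":
            rows.append({"substrate": substrate, "k": p["k05"], "n": p["n"],
                         "vmax": p["vmax"]})
        elif fit.model_id == "bibi":
            rows.append({"substrate": substrate + " (A)", "k": p["ka"],
                         "vmax": p["vmax"]})
            rows.append({"substrate": substrate + " (B)", "k": p["kb"],
                         "vmax": p["vmax"]})
        else:
            rows.append({"substrate": substrate, "k": p["km"], "vmax": p["vmax"]})
    return rows


def write_report(table: pd.DataFrame, csv_path: str | Path,
                 json_path: str | Path, seed: int | None = None,
                 config_hash: str | None = None) -> None:
    """Write one table as CSV and JSON; the two renderings agree field by field."""
    csv_path, json_path = Path(csv_path), Path(json_path)
    header = artifact_header(seed=seed, config_hash=config_hash)
    body = table.to_csv(index=False, float_format="%.12g", lineterminator="\n")
    csv_path.write_text("\n".join(header) + "\n" + body, encoding="utf-8")
    doc = {
        "schema_version": 1,
        "generator": f"enzkin {__version__}",
        "seed": seed,
        "config_hash": config_hash,
        "rows": json.loads(table.to_json(orient="records")),
    }
    json_path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
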