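"""Readers, writers and run configuration shared by all modules.

Localization tables use the ThunderSTORM CSV dialect: a header row with
column names like ``x [nm]``; column order is free.  Reports are JSON
lines with deterministic key order so identical runs produce identical
bytes.  Run configuration is validated strictly (unknown keys rejected)
against a schema shipped with the package.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .layout import ROWS, COLS

__all__ = [
    "FormatError",
    "read_localization_csv",
    "write_localization_csv",
    "write_report",
    "read_report",
    "write_matrix_json",
    "read_matrix_json",
    "RunConfig",
    "load_config",
    "config_schema",
]

REQUIRED_COLUMNS = ("frame", "x [nm]", "y [nm]", "uncertainty [nm]")
OPTIONAL_COLUMNS = ("intensity [photon]",)


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# localization tables
# ---------------------------------------------------------------------------

def read_localization_csv(path) -> pd.DataFrame:
    """Read a ThunderSTORM-dialect localization table.

    Columns may appear in any order; missing mandatory columns raise a
    :class:`FormatError` naming the column.  Row order is preserved.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().strip('"') for c in df.columns]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    out = df[cols].copy()
    out["frame"] = out["frame"].astype(np.int64)
    for col in cols[1:]:
        out[col] = out[col].astype(float)
    if not np.isfinite(out[["x [nm]", "y [nm]"]].to_numpy()).all():
        raise FormatError("non-finite coordinates in localization table")
    if (out["uncertainty [nm]"] <= 0).any():
        raise FormatError("localization uncertainties must be positive")
    return out


def write_localization_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# reports (JSON lines)
# ---------------------------------------------------------------------------

_HEADER = "# dnam report v1"


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(results: Iterable[dict], path) -> None:
    """Write records as newline-terminated JSON lines with sorted keys;
    byte-identical output for identical input."""
    lines = [_HEADER]
    for rec in results:
        lines.append(json.dumps(_jsonable(rec), sort_keys=True))
    Path(path).write_text("\n".join(lines) + "\n")


def read_report(path) -> list[dict]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        out.append(json.loads(line))
    return out


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix_json(matrix: np.ndarray, path, provenance: str = "encoded") -> None:
    payload = {
        "rows": ROWS,
        "cols": COLS,
        "bits": np.asarray(matrix, dtype=int).tolist(),
        "provenance": provenance,
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def read_matrix_json(path) -> np.ndarray:
    d = json.loads(Path(path).read_text())
    m = np.array(d["bits"], dtype=np.uint8)
    if m.shape != (d["rows"], d["cols"]):
        raise FormatError("matrix shape does not match header")
    return m


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class CodecConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    segment_bits: int = Field(16, ge=1)
    n_droplets: int = Field(15, ge=1)
    max_flips: int = Field(9, ge=0)
    max_expansions: int = Field(10_000, ge=1)
    redundancy: float = Field(1.5, gt=0)


class ClusterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    radius_nm: float = Field(60.0, gt=0)
    min_count: int = Field(50, ge=1)
    band_frac: float = Field(0.15, ge=0, le=1)


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pitch_nm: float = Field(10.0, gt=0)
    gtol: float = Field(1e-6, gt=0)
    max_iter: int = Field(300, ge=1)


class SimulatorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    message_sizes: list[int] = Field(default_factory=lambda: [160])
    error_means: list[float] = Field(default_factory=lambda: [0.0, 7.4, 8.2, 9.0])
    copies_per_origami: int = Field(10, ge=1)
    repetitions: int = Field(40, ge=1)


class RunConfig(BaseModel):
    """Top-level configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    schema_version: int = 1
    layout_path: str | None = None
    seed: int = 0
    codec: CodecConfig = Field(default_factory=CodecConfig)
    cluster: ClusterConfig = Field(default_factory=ClusterConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    simulator: SimulatorConfig = Field(default_factory=SimulatorConfig)


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig.model_validate(data or {})


def config_schema() -> dict:
    return RunConfig.model_json_schema()
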