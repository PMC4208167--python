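"""Configuration and report I/O for the reading/optimization pipeline.

File formats
------------
* factor file (YAML or JSON): list of ``{id, name, level1, level2}`` entries
  mirroring the camera-parameter table.
* run CSV: ``run_index``, one level column per array column (``c1..cN``,
  values 1/2), then ``m1..mk`` reference and ``y1..yk`` measured grayscales.
* response-table / ANOVA / precision reports: plain CSV with a ``#``
  provenance header (tool version, seed, config hash).
* calibration model: JSON (see ``CalibrationResults``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import FactorAssignment, OrthogonalArray, assign_factors, get_array
from .exceptions import InputError

_CONFIG_KEYS = {
    "factor_file",
    "array",
    "polarity",
    "lane",
    "orientation",
    "min_depth",
    "calibration_levels",
    "seed",
    "output_dir",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Strictly-validated pipeline configuration (YAML or JSON file)."""

    factor_file: str | None = None
    array: str = "L12"
    polarity: str = "net"
    lane: tuple[int, int, int, int] | None = None
    orientation: str = "control-bottom"
    min_depth: float = 5.0
    calibration_levels: tuple[float, ...] = (6.25, 12.5, 25.0, 37.5, 50.0)
    seed: int = 0
    output_dir: str = "."

    def strip_config(self):
        from .densitometry import StripConfig

        return StripConfig(
            lane=self.lane,
            orientation=self.orientation,
            min_depth=self.min_depth,
            polarity=self.polarity,
        )


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a pipeline config; unknown keys are rejected and
    referenced paths must exist."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise InputError(f"config {path} must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    if "lane" in raw and raw["lane"] is not None:
        lane = raw["lane"]
        if not (isinstance(lane, (list, tuple)) and len(lane) == 4):
            raise InputError("config key 'lane' must be [row0, row1, col0, col1]")
        raw["lane"] = tuple(int(v) for v in lane)
    if "calibration_levels" in raw:
        raw["calibration_levels"] = tuple(float(v) for v in raw["calibration_levels"])
    cfg = PipelineConfig(**raw)
    if cfg.factor_file is not None:
        fpath = (path.parent / cfg.factor_file).resolve()
        if not fpath.exists():
            raise InputError(f"factor_file does not exist: {fpath}")
        object.__setattr__(cfg, "factor_file", str(fpath))
    cfg.strip_config()  # validates orientation/min_depth/polarity
    return cfg


def config_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# factor files


def load_factors(path: str | Path) -> list[dict]:
    """Read a factor definition file (YAML/JSON list of id/name/level1/level2)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        entries = json.loads(path.read_text())
    else:
        entries = yaml.safe_load(path.read_text())
    if not isinstance(entries, list) or not entries:
        raise InputError(f"factor file {path} must hold a non-empty list")
    for e in entries:
        if not isinstance(e, dict):
            raise InputError("each factor entry must be a mapping")
        missing = {"id", "level1", "level2"} - set(e)
        if missing:
            raise InputError(f"factor entry missing keys: {sorted(missing)}")
        extra = set(e) - {"id", "name", "level1", "level2"}
        if extra:
            raise InputError(f"unknown factor keys: {sorted(extra)}")
    return entries


# ---------------------------------------------------------------------------
# provenance header


def _provenance(seed=None, config=None) -> str:
    parts = [f"lfaquant {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config_sha256={config_hash(config)}")
    return "# " + " ".join(parts)


def _write_csv(df: pd.DataFrame, path: Path, seed=None, config=None, index=False):
    with open(path, "w") as fh:
        fh.write(_provenance(seed, config) + "\n")
        df.to_csv(fh, index=index)


def read_report_csv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# design / run sheets


def write_design_csv(
    array: OrthogonalArray,
    assignment: list[FactorAssignment],
    path: str | Path,
    seed=None,
) -> pd.DataFrame:
    """Write the run sheet: per run, the concrete setting of every factor."""
    rows = []
    for r in range(array.n_runs):
        row = {"run_index": r + 1}
        for f in assignment:
            level = int(array.cells[r, f.column])
            row[f"{f.factor_id}_level"] = level
            row[f.factor_id] = f.value(level)
        rows.append(row)
    df = pd.DataFrame(rows)
    _write_csv(df, Path(path), seed=seed)
    return df


def write_run_csv(
    array: OrthogonalArray,
    standard_signals: np.ndarray,
    measured_signals: np.ndarray,
    path: str | Path,
    seed=None,
) -> pd.DataFrame:
    """Write raw run data: levels per column plus (M, y) signal pairs."""
    M = np.asarray(standard_signals, dtype=float)
    y = np.asarray(measured_signals, dtype=float)
    if M.ndim == 1:
        M = np.broadcast_to(M, y.shape)
    df = pd.DataFrame({"run_index": np.arange(1, array.n_runs + 1)})
    for j in range(array.n_columns):
        df[f"c{j + 1}"] = array.cells[:, j]
    for i in range(M.shape[1]):
        df[f"m{i + 1}"] = M[:, i]
    for i in range(y.shape[1]):
        df[f"y{i + 1}"] = y[:, i]
    _write_csv(df, Path(path), seed=seed)
    return df


def read_run_csv(path: str | Path, array_name: str = "L12"):
    """Read a run CSV back into (array, standard matrix, measured matrix)."""
    df = read_report_csv(path)
    array = get_array(array_name)
    level_cols = [c for c in df.columns if c.startswith("c") and c[1:].isdigit()]
    m_cols = sorted(
        (c for c in df.columns if c.startswith("m") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    y_cols = sorted(
        (c for c in df.columns if c.startswith("y") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if len(df) != array.n_runs:
        raise InputError(
            f"run CSV has {len(df)} rows but {array_name} has {array.n_runs} runs"
        )
    if len(level_cols) != array.n_columns:
        raise InputError(
            f"run CSV has {len(level_cols)} level columns, expected {array.n_columns}"
        )
    if not m_cols or len(m_cols) != len(y_cols):
        raise InputError("run CSV must hold matching m1..mk and y1..yk columns")
    levels = df[[f"c{j + 1}" for j in range(array.n_columns)]].to_numpy()
    if not np.array_equal(levels, array.cells):
        raise InputError(f"run CSV level columns do not match the {array_name} array")
    return array, df[m_cols].to_numpy(float), df[y_cols].to_numpy(float)


# ---------------------------------------------------------------------------
# analysis reports


def write_response_table(results, path: str | Path, seed=None, config=None):
    df = results.response.table.reset_index()
    df.insert(1, "grand_mean", results.grand_mean)
    _write_csv(df, Path(path), seed=seed, config=config)


def read_response_table(path: str | Path):
    """Round-trip reader for a response-table report."""
    from .taguchi import ResponseTable

    df = read_report_csv(path)
    grand = float(df["grand_mean"].iloc[0])
    table = df.drop(columns=["grand_mean"]).set_index("factor")
    table["rank"] = table["rank"].astype(int)
    return ResponseTable(grand_mean=grand, table=table)


def write_anova_csv(results, path: str | Path, seed=None, config=None):
    df = results.anova.table.reset_index()
    _write_csv(df, Path(path), seed=seed, config=config)
    return df


def write_optimal_json(selection, path: str | Path, seed=None, config=None):
    payload = {
        "baseline_levels": selection.baseline_levels,
        "significant_factors": selection.significant_factors,
        "chosen_levels": selection.chosen_levels,
        "predicted_sn_db": selection.predicted_sn,
        "_provenance": _provenance(seed, config).lstrip("# "),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
    return payload


def write_signals_csv(records: list[dict], path: str | Path, seed=None, config=None):
    """One row per strip image: validity, band calls and reported grayscale."""
    _write_csv(pd.DataFrame(records), Path(path), seed=seed, config=config)
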