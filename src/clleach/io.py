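"""CSV/JSON/YAML formats of the pipeline.

All tables are plain UTF-8 CSV with a mandatory header (RFC-4180 dialect,
decimal point); reports are JSON.  The long-format observation table is
the interchange format between the generator, the accounting stage and
external field data:

    site_id,texture,treatment,das,cum_rain_mm,layer_top_cm,layer_bottom_cm,
    cl_mgkg,so4_mgkg,replicate

``so4_mgkg`` may be absent or empty; every other column is required.
Validation errors name the offending row and column.  Percentages are
serialized as percent, fractions are internal only.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError
from .synth import GeneratorConfig

OBSERVATION_COLUMNS = (
    "site_id",
    "texture",
    "treatment",
    "das",
    "cum_rain_mm",
    "layer_top_cm",
    "layer_bottom_cm",
    "cl_mgkg",
)
OPTIONAL_COLUMNS = ("so4_mgkg", "replicate")
_NUMERIC = ("das", "cum_rain_mm", "layer_top_cm", "layer_bottom_cm", "cl_mgkg", "so4_mgkg")


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format observation CSV.

    Raises :class:`~clleach.errors.DomainError` naming the row (1-based,
    excluding the header) and column for missing columns, non-numeric
    cells, negative concentrations or inverted layer bounds.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"{path.name}: missing required columns {missing}")
    if "replicate" not in df.columns:
        df["replicate"] = "1"
    for col in _NUMERIC:
        if col not in df.columns:
            continue
        raw = df[col].str.strip()
        optional = col in OPTIONAL_COLUMNS
        values = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = values.isna() & (raw != "")
        if not optional:
            bad |= raw == ""
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise DomainError(
                f"{path.name} row {row}, column {col!r}: "
                f"non-numeric or missing value {df.loc[row - 1, col]!r}"
            )
        df[col] = values
    df["replicate"] = pd.to_numeric(df["replicate"].replace("", "1")).astype(int)
    for col in ("cl_mgkg", "cum_rain_mm"):
        neg = df[col] < 0
        if neg.any():
            row = int(neg.idxmax()) + 1
            raise DomainError(
                f"{path.name} row {row}, column {col!r}: negative value "
                f"{df.loc[row - 1, col]}"
            )
    inverted = df["layer_bottom_cm"] <= df["layer_top_cm"]
    if inverted.any():
        row = int(inverted.idxmax()) + 1
        raise DomainError(f"{path.name} row {row}: layer_bottom_cm <= layer_top_cm")
    return df


def write_observations(df: pd.DataFrame, path: str | Path) -> Path:
    """Write an observation table as CSV (17 significant digits, lossless)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def write_json(obj: Any, path: str | Path) -> Path:
    """Serialize dataclasses / dicts / numpy scalars to pretty JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "value"):  # enums
            return o.value
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")
    return path


_CONFIG_KEYS = {f.name for f in dataclasses.fields(GeneratorConfig)}


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Load a :class:`~clleach.synth.GeneratorConfig` from YAML.

    Unknown keys are rejected so typos fail loudly.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise DomainError("config file must hold a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise DomainError(f"unknown config keys: {sorted(unknown)}")
    for key in ("cl_doses", "sampling_das", "sampling_rain", "background_cl"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return GeneratorConfig(**raw)


def config_hash(config: GeneratorConfig) -> str:
    """Short stable hash of the generator configuration, for run logs."""
    import hashlib

    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
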