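"""Delimited-text schemas and structured run configuration.

All on-disk data are UTF-8 CSV with dot decimal separators; speeds are
always m s^-1 in files (unit conversions happen only inside the
computation functions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SchemaError

__all__ = ["SCHEMAS", "read_table", "write_table", "RunConfig"]


@dataclass(frozen=True)
class TableSchema:
    name: str
    numeric: tuple[str, ...]
    text: tuple[str, ...] = ()
    key: tuple[str, ...] = ()

    @property
    def columns(self) -> tuple[str, ...]:
        return self.text + self.numeric


SCHEMAS: dict[str, TableSchema] = {
    "traces": TableSchema(
        "traces",
        numeric=("speed_m_s", "time_h", "o2_mg_L"),
        text=("eel_id", "condition"),
        key=("eel_id", "condition", "speed_m_s", "time_h"),
    ),
    "mo2": TableSchema(
        "mo2",
        numeric=("speed_m_s", "mo2", "r2", "p"),
        text=("eel_id", "condition"),
        key=("eel_id", "condition", "speed_m_s"),
    ),
    "ucrit_steps": TableSchema(
        "ucrit_steps",
        numeric=("step_speed_m_s", "completed_min"),
        text=("eel_id", "condition"),
        key=("eel_id", "condition", "step_speed_m_s"),
    ),
    "landmarks": TableSchema(
        "landmarks",
        numeric=("speed_m_s", "time_s", "lateral_m"),
        text=("eel_id", "condition", "site"),
        key=("eel_id", "condition", "speed_m_s", "site", "time_s"),
    ),
    "drag_calib": TableSchema(
        "drag_calib",
        numeric=("speed_m_s", "force_N", "replicate"),
        text=("dummy_label",),
        key=("dummy_label", "speed_m_s", "replicate"),
    ),
    "cohort": TableSchema(
        "cohort",
        numeric=("body_mass_kg", "body_length_m", "fish_area_mm2"),
        text=("eel_id",),
        key=("eel_id",),
    ),
    "effects": TableSchema(
        "effects",
        numeric=("drag_N", "red_pct_ucrit", "inc_pct_cotmin"),
        text=("eel_id",),
        key=("eel_id", "drag_N"),
    ),
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Raises :class:`SchemaError` naming the offending column or row for
    missing columns, non-numeric cells and duplicate key rows.  Row
    numbers refer to data rows (header excluded, 1-based).
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; know {sorted(SCHEMAS)}")
    sch = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in sch.columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    for col in sch.numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise SchemaError(
                f"{path.name}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at data row {row}"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax()) + 1
            raise SchemaError(
                f"{path.name}: empty cell in column {col!r} at data row {row}"
            )
        df[col] = converted
    if sch.key:
        dup = df.duplicated(subset=list(sch.key))
        if dup.any():
            row = int(dup.idxmax()) + 1
            raise SchemaError(
                f"{path.name}: duplicate key {tuple(sch.key)} at data row {row}"
            )
    return df[list(sch.columns)]


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Write a frame in schema column order (lossless round-trip)."""
    sch = SCHEMAS[schema]
    missing = [c for c in sch.columns if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write {schema}: missing column(s) {missing}")
    df[list(sch.columns)].to_csv(path, index=False)


@dataclass
class RunConfig:
    """Validated run configuration for the full pipeline.

    Defaults reproduce the experimental setup; any key not listed here
    is rejected on load so that typos cannot silently fall back to a
    default.
    """

    # fluid environment
    density: float = 1020.0
    drag_coefficient: float = 0.45
    reference_speed: float = 0.65
    # protocol
    speed_increment: float = 0.1
    interval_min: float = 20.0
    start_speed: float = 0.3
    # MO2 filters
    min_r2: float = 0.9
    alpha: float = 0.05
    # blocking correction
    blocking_enabled: bool = True
    tau: float = 0.8
    lam: float = 0.5
    # cross-section of a 150 mm diameter Blazka swim section; the fish
    # occupies <1% so the default correction is tiny
    tunnel_area_mm2: float = 17671.0
    blocking_exponent: float = 1.5
    # impairment / site model
    site_ucrit_increment: float = 15.0
    site_cotmin_increment: float = 63.0
    divergence_threshold: float = 10.0
    # kinematics analysis
    segment_length_s: float = 20.0
    n_blocks: int = 3
    # misc
    chamber_volume: float = 127.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_r2 < 1:
            raise ConfigError("min_r2 must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.speed_increment <= 0 or self.interval_min <= 0:
            raise ConfigError("protocol increments must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(
                f"{path}: unknown config key(s) {sorted(unknown)}; "
                f"known keys: {sorted(known)}"
            )
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
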