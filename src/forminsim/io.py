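"""Reading and writing the per-filament observation tables and configs.

The on-disk interchange format is plain CSV with one row per filament:

    condition_id, run_length_subunits (or run_length_um),
    elongation_rate_sub_s, run_time_s, censored,
    formin_intensity, control_intensity

Lengths may be given in micrometres only, in which case subunit counts
are derived via the 370 subunits/um conversion; run times are derived
from length and elongation rate when absent.  Round trips through
write/read are lossless for the canonical columns.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .survival import SUBUNITS_PER_UM, FilamentRecord

__all__ = [
    "CANONICAL_COLUMNS",
    "read_filament_table",
    "write_filament_table",
    "records_to_frame",
    "frame_to_records",
    "load_yaml",
    "dump_yaml",
]

CANONICAL_COLUMNS = [
    "condition_id",
    "run_length_subunits",
    "run_length_um",
    "elongation_rate_sub_s",
    "run_time_s",
    "censored",
    "formin_intensity",
    "control_intensity",
]


def read_filament_table(path: str | Path) -> pd.DataFrame:
    """Read a per-filament CSV, deriving any missing canonical columns."""
    df = pd.read_csv(path)
    if "run_length_subunits" not in df and "run_length_um" not in df:
        raise ValueError(
            f"{path}: need a run_length_subunits or run_length_um column"
        )
    if "elongation_rate_sub_s" not in df:
        raise ValueError(f"{path}: need an elongation_rate_sub_s column")
    if "run_length_subunits" not in df:
        df["run_length_subunits"] = df["run_length_um"] * SUBUNITS_PER_UM
    if "run_length_um" not in df:
        df["run_length_um"] = df["run_length_subunits"] / SUBUNITS_PER_UM
    if "run_time_s" not in df:
        df["run_time_s"] = df["run_length_subunits"] / df["elongation_rate_sub_s"]
    if "censored" not in df:
        df["censored"] = False
    df["censored"] = df["censored"].astype(bool)
    if "condition_id" not in df:
        df["condition_id"] = ""
    df["condition_id"] = df["condition_id"].fillna("").astype(str)
    if (df["run_length_subunits"] < 0).any():
        raise ValueError(f"{path}: negative run lengths")
    if (df["elongation_rate_sub_s"] <= 0).any():
        raise ValueError(f"{path}: non-positive elongation rates")
    ordered = [c for c in CANONICAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    return df[ordered + extra]


def write_filament_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a per-filament table as CSV (canonical column order first)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ordered = [c for c in CANONICAL_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in ordered]
    table[ordered + extra].to_csv(path, index=False)
    return path


def records_to_frame(records: Sequence[FilamentRecord]) -> pd.DataFrame:
    """Convert :class:`FilamentRecord` objects to the canonical table."""
    return pd.DataFrame(
        {
            "condition_id": [r.condition_id for r in records],
            "run_length_subunits": [r.run_length_subunits for r in records],
            "run_length_um": [r.run_length_um for r in records],
            "elongation_rate_sub_s": [r.elongation_rate for r in records],
            "run_time_s": [r.run_time for r in records],
            "censored": [r.censored for r in records],
            "formin_intensity": [r.formin_intensity for r in records],
            "control_intensity": [r.control_intensity for r in records],
        }
    )


def frame_to_records(table: pd.DataFrame) -> list[FilamentRecord]:
    """Convert a canonical table to :class:`FilamentRecord` objects."""

    def _opt(row: Any, name: str) -> Any:
        value = getattr(row, name, None)
        return None if value is None or (isinstance(value, float) and np.isnan(value)) else value

    return [
        FilamentRecord(
            run_length_subunits=row.run_length_subunits,
            elongation_rate=row.elongation_rate_sub_s,
            run_time=row.run_time_s,
            censored=bool(row.censored),
            condition_id=str(getattr(row, "condition_id", "")),
            formin_intensity=_opt(row, "formin_intensity"),
            control_intensity=_opt(row, "control_intensity"),
        )
        for row in table.itertuples()
    ]


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return data


def dump_yaml(data: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path
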