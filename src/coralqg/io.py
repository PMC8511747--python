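"""Trait-table reading, validation and config round-trips.

The single data currency of the package is the long-format trait table:
one row per fragment × trait with columns ``fragment_id, genotype_id,
treatment, tank_id, trait_name, value``.  Long format tolerates per-trait
missingness; a wide table (one column per trait) can be melted with
:func:`wide_to_long`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import TREATMENTS, DesignSpec, design_from_dict, design_to_dict

__all__ = [
    "REQUIRED_COLUMNS",
    "TraitTableError",
    "validate_table",
    "read_trait_table",
    "write_trait_table",
    "wide_to_long",
    "read_design",
    "write_design",
    "write_ground_truth",
]

REQUIRED_COLUMNS = ("fragment_id", "genotype_id", "treatment", "tank_id", "trait_name", "value")


class TraitTableError(ValueError):
    """Schema or consistency violation in a trait table."""


def validate_table(table: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Validate (and type) a long-format trait table.

    Checks: required columns present; no duplicate (fragment_id, trait_name)
    pairs; every tank maps to exactly one treatment; values finite (NaN is
    allowed — it marks a missing measurement — but ±inf is not).  Violations
    are reported with offending row numbers.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise TraitTableError(
            f"missing columns {missing}; expected schema {list(REQUIRED_COLUMNS)}"
        )
    df = table.loc[:, list(REQUIRED_COLUMNS)].copy()
    for col in ("fragment_id", "genotype_id", "treatment", "tank_id", "trait_name"):
        df[col] = df[col].astype(str)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")

    problems = []
    dup = df.duplicated(subset=["fragment_id", "trait_name"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        problems.append(f"duplicate (fragment_id, trait_name) pairs at rows {rows}")
    tank_map = df.groupby("tank_id", observed=True)["treatment"].nunique()
    bad_tanks = tank_map.index[tank_map > 1].tolist()
    if bad_tanks:
        problems.append(f"tanks assigned to more than one treatment: {bad_tanks}")
    unknown = sorted(set(df["treatment"]) - set(TREATMENTS))
    if unknown:
        problems.append(f"unknown treatment labels {unknown}; expected {list(TREATMENTS)}")
    inf = np.isinf(table["value"].to_numpy(dtype=float, na_value=np.nan))
    if inf.any():
        rows = table.index[inf].tolist()[:10]
        problems.append(f"non-finite values at rows {rows}")
    if problems:
        raise TraitTableError("; ".join(problems))
    return df


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a trait-table CSV."""
    return validate_table(Path(path))


def write_trait_table(table: pd.DataFrame, path: str | Path) -> None:
    table.loc[:, list(REQUIRED_COLUMNS)].to_csv(path, index=False)


def wide_to_long(wide: pd.DataFrame, trait_columns: list[str] | None = None) -> pd.DataFrame:
    """Melt a wide table (one column per trait) into the long schema."""
    id_cols = ["fragment_id", "genotype_id", "treatment", "tank_id"]
    missing = [c for c in id_cols if c not in wide.columns]
    if missing:
        raise TraitTableError(f"wide table missing id columns {missing}")
    traits = trait_columns or [c for c in wide.columns if c not in id_cols]
    long = wide.melt(id_vars=id_cols, value_vars=traits, var_name="trait_name", value_name="value")
    return validate_table(long)


def read_design(path: str | Path) -> DesignSpec:
    """Load a DesignSpec from YAML (or JSON)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return design_from_dict(data)


def write_design(design: DesignSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(design_to_dict(design), sort_keys=False))


def write_ground_truth(design: DesignSpec, path: str | Path) -> None:
    """Ground-truth sidecar JSON (per-trait generative parameters and H²)."""
    Path(path).write_text(json.dumps(design.ground_truth(), indent=2, sort_keys=True))
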