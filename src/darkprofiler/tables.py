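"""Feature-table schema and I/O helpers.

A *feature table* is a plain :class:`pandas.DataFrame` holding one row per
observation (a microscope site or an aggregated well) with a small set of
metadata columns followed by an arbitrary number of numeric image-feature
columns.  Feature names are treated as opaque strings throughout.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

#: Metadata columns recognised in feature tables.  ``site`` is present only in
#: site-level tables; everything that is not metadata is a feature column.
META_COLUMNS = (
    "plate_id",
    "well",
    "site",
    "compound_id",
    "concentration_um",
    "role",
    "dmso_percent",
)

CONTROL = "control"
TEST = "test"

_WELL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Names of all non-metadata (feature) columns, in table order."""
    return [c for c in df.columns if c not in META_COLUMNS]


def well_sort_key(well: str) -> tuple[int, int]:
    """Row-major plate order key: A01, A02, ... A24, B01, ... P24."""
    m = _WELL_RE.match(well)
    if m is None:
        raise ValueError(f"not a valid 384-well name: {well!r}")
    return (ord(m.group(1).upper()) - ord("A"), int(m.group(2)))


def order_wells(wells) -> list[str]:
    """Sort well names in the fixed row-major plate order."""
    return sorted(wells, key=well_sort_key)


def validate_feature_table(df: pd.DataFrame, site_level: bool | None = None) -> None:
    """Check the structural invariants of a feature table.

    Raises ``ValueError`` on: missing metadata columns, plates without control
    rows, non-positive test concentrations, or duplicated observation keys.
    ``site_level`` forces the expectation of a ``site`` column (True), its
    absence (False), or infers it (None).
    """
    required = {"plate_id", "well", "compound_id", "concentration_um", "role",
                "dmso_percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing metadata columns: {sorted(missing)}")
    if site_level is True and "site" not in df.columns:
        raise ValueError("site-level table expected but 'site' column is absent")
    if site_level is False and "site" in df.columns:
        raise ValueError("well-level table expected but 'site' column is present")
    if not feature_columns(df):
        raise ValueError("feature table has no feature columns")

    bad_roles = set(df["role"].unique()) - {CONTROL, TEST}
    if bad_roles:
        raise ValueError(f"unknown roles: {sorted(bad_roles)}")
    plates_without_controls = [
        p for p, grp in df.groupby("plate_id", sort=False)
        if not (grp["role"] == CONTROL).any()
    ]
    if plates_without_controls:
        raise ValueError(f"plates without control rows: {plates_without_controls}")

    tests = df[df["role"] == TEST]
    if (tests["concentration_um"] <= 0).any():
        bad = tests.loc[tests["concentration_um"] <= 0, "compound_id"].unique()
        raise ValueError(f"non-positive test concentrations for: {list(bad)[:5]}")

    key_cols = ["plate_id", "well"] + (["site"] if "site" in df.columns else [])
    if df.duplicated(key_cols).any():
        dupes = df.loc[df.duplicated(key_cols), key_cols].head()
        raise ValueError(f"duplicate observation keys:\n{dupes}")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table from CSV or Parquet (by file suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table to CSV or Parquet (by file suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)
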