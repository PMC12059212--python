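"""Domain tables, validation, and CSV input/output.

All pipeline stages exchange plain :class:`pandas.DataFrame` objects with the
column schemas declared in :data:`SCHEMAS`.  Five tables describe a colony:

``boxes``
    Nest-box registry with planar coordinates in meters.
``individuals``
    Tagged birds (sex, birth year, natal box where known).
``detections``
    Raw RFID reads: one row per (tag, box, timestamp).
``bouts``
    Recording-bout metadata: minutes of reader coverage per (box, date).
``breeding``
    One row per nesting attempt: lay/hatch dates, clutch wave, counts, owners.
``morphometrics``
    Per-capture measurements (mass, tarsus, beak, wing, three ornamental
    throat-feather lengths) plus capture time and date.

Validation is total: every input row is either accepted or reported with a
row-level reason, never silently dropped.  Coordinates given as lon/lat are
converted to planar meters through a local equirectangular projection about
the colony centroid; at colony scale (under ~1.5 km) the distortion is far
below measurement error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMAS",
    "SEASON_START",
    "Dataset",
    "ValidationReport",
    "read_tables",
    "write_tables",
    "validate_table",
    "project_lonlat",
    "season_day",
]

#: Required columns per table role.  Extra columns are carried through.
SCHEMAS: dict[str, list[str]] = {
    "boxes": ["box_id", "x", "y"],
    "individuals": ["tag_id", "sex", "birth_year", "natal_box"],
    "detections": ["tag_id", "box_id", "timestamp"],
    "bouts": ["box_id", "date", "minutes_recorded"],
    "breeding": [
        "box_id", "year", "wave", "lay_date", "hatch_date", "clutch_size",
        "fledged", "male_owner", "female_owner", "manipulated",
    ],
    "morphometrics": [
        "tag_id", "year", "mass", "tarsus", "beak", "wing",
        "throat1", "throat2", "throat3", "capture_time", "capture_date",
    ],
}

#: Season start used for within-season day numbers (breeding spans March-July).
SEASON_START = (3, 1)  # (month, day)

_DATE_COLS = {"detections": ["timestamp"], "bouts": ["date"],
              "breeding": ["lay_date", "hatch_date"],
              "morphometrics": ["capture_date"]}

_EARTH_RADIUS_M = 6_371_000.0


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class IntegrityError(ValueError):
    """A table-level invariant (unique keys, colony size) is violated."""


@dataclass
class ValidationReport:
    """Row-level diagnostics from :func:`validate_table`."""

    table: str
    n_input: int
    n_accepted: int
    rejected: pd.DataFrame  # original rows plus a ``reason`` column

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class Dataset:
    """Validated bundle of colony tables."""

    boxes: pd.DataFrame
    individuals: pd.DataFrame | None = None
    detections: pd.DataFrame | None = None
    bouts: pd.DataFrame | None = None
    breeding: pd.DataFrame | None = None
    morphometrics: pd.DataFrame | None = None
    reports: dict[str, ValidationReport] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        """Accepted row count per present table."""
        out = {}
        for role in SCHEMAS:
            tab = getattr(self, role)
            if tab is not None:
                out[role] = len(tab)
        return out


def _check_schema(df: pd.DataFrame, role: str) -> None:
    missing = [c for c in SCHEMAS[role] if c not in df.columns]
    if missing:
        raise SchemaError(f"table {role!r} is missing required columns {missing}")


def _row_checks(df: pd.DataFrame, role: str) -> pd.Series:
    """Return a reason string per row ('' = accepted)."""
    reason = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, msg: str) -> None:
        mask = mask.fillna(False) if mask.dtype == object else mask
        sel = mask & (reason == "")
        reason[sel] = msg

    if role == "boxes":
        xy = df[["x", "y"]].apply(pd.to_numeric, errors="coerce")
        flag(~np.isfinite(xy["x"]) | ~np.isfinite(xy["y"]), "non-finite coordinate")
        flag(df["box_id"].isna() | (df["box_id"].astype(str) == ""), "empty box_id")
    elif role == "individuals":
        flag(df["tag_id"].isna() | (df["tag_id"].astype(str) == ""), "empty tag_id")
        flag(~df["sex"].isin(["M", "F", "unknown"]) & df["sex"].notna(),
             "sex not in {M, F, unknown}")
    elif role == "detections":
        ts = pd.to_datetime(df["timestamp"], errors="coerce")
        flag(ts.isna(), "unparseable timestamp")
    elif role == "bouts":
        mins = pd.to_numeric(df["minutes_recorded"], errors="coerce")
        flag(mins.isna() | (mins < 0), "negative or missing minutes_recorded")
        flag(mins > 1440, "minutes_recorded exceeds one day")
    elif role == "breeding":
        clutch = pd.to_numeric(df["clutch_size"], errors="coerce")
        fledged = pd.to_numeric(df["fledged"], errors="coerce")
        flag(fledged < 0, "negative fledged count")
        flag(fledged > clutch, "fledged exceeds clutch_size")
        flag(~df["wave"].isin(["first", "second"]), "wave not in {first, second}")
        lay = pd.to_datetime(df["lay_date"], errors="coerce")
        hatch = pd.to_datetime(df["hatch_date"], errors="coerce")
        flag(lay.notna() & hatch.notna() & (hatch < lay), "hatch_date before lay_date")
    elif role == "morphometrics":
        for col in ["mass", "tarsus", "beak", "wing", "throat1", "throat2", "throat3"]:
            vals = pd.to_numeric(df[col], errors="coerce")
            flag(vals.notna() & (vals <= 0), f"non-positive {col}")
    return reason


def validate_table(df: pd.DataFrame, role: str) -> tuple[pd.DataFrame, ValidationReport]:
    """Validate one table; return (accepted rows, report).

    Raises :class:`SchemaError` for missing columns and
    :class:`IntegrityError` for duplicated primary keys.
    """
    if role not in SCHEMAS:
        raise ValueError(f"unknown table role {role!r}")
    _check_schema(df, role)
    if role == "boxes" and df["box_id"].duplicated().any():
        dups = df.loc[df["box_id"].duplicated(), "box_id"].tolist()
        raise IntegrityError(f"duplicate box_id values: {dups}")
    if role == "individuals" and df["tag_id"].duplicated().any():
        dups = df.loc[df["tag_id"].duplicated(), "tag_id"].tolist()
        raise IntegrityError(f"duplicate tag_id values: {dups}")

    reason = _row_checks(df, role)
    accepted = df[reason == ""].copy()
    rejected = df[reason != ""].copy()
    rejected["reason"] = reason[reason != ""]

    if role == "boxes" and len(accepted) < 2:
        raise IntegrityError("colony must contain at least 2 valid nest boxes")

    # Normalize dtypes on accepted rows.
    for col in _DATE_COLS.get(role, []):
        accepted[col] = pd.to_datetime(accepted[col], errors="coerce")
    if role == "boxes":
        accepted[["x", "y"]] = accepted[["x", "y"]].astype(float)
    if role == "breeding":
        accepted["clutch_size"] = pd.to_numeric(accepted["clutch_size"]).astype(int)
        accepted["fledged"] = pd.to_numeric(accepted["fledged"]).astype(int)
        accepted["year"] = pd.to_numeric(accepted["year"]).astype(int)
        accepted["manipulated"] = accepted["manipulated"].astype(bool)
    if role == "bouts":
        accepted["minutes_recorded"] = pd.to_numeric(accepted["minutes_recorded"]).astype(float)

    report = ValidationReport(role, len(df), len(accepted), rejected)
    return accepted.reset_index(drop=True), report


def read_tables(paths: Mapping[str, str | Path], lonlat: bool = False) -> Dataset:
    """Read and validate a bundle of CSV tables.

    Parameters
    ----------
    paths
        Mapping of table role (``boxes``, ``detections``, ...) to CSV path.
        ``boxes`` is required; the rest are optional.
    lonlat
        If True, box coordinates are longitude/latitude degrees and are
        projected to planar meters about the colony centroid.
    """
    if "boxes" not in paths:
        raise SchemaError("a 'boxes' table is required")
    tables: dict[str, pd.DataFrame] = {}
    reports: dict[str, ValidationReport] = {}
    for role, path in paths.items():
        raw = pd.read_csv(path)
        tables[role], reports[role] = validate_table(raw, role)
    if lonlat:
        x, y = project_lonlat(tables["boxes"]["x"].to_numpy(),
                              tables["boxes"]["y"].to_numpy())
        tables["boxes"]["x"], tables["boxes"]["y"] = x, y
    return Dataset(**tables, reports=reports)


def write_tables(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write every present table as CSV; returns role -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for role in SCHEMAS:
        tab = getattr(dataset, role)
        if tab is None:
            continue
        path = out_dir / f"{role}.csv"
        tab.to_csv(path, index=False)
        written[role] = path
    return written


def project_lonlat(lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local equirectangular projection (degrees -> meters about the centroid)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon0, lat0 = lon.mean(), lat.mean()
    x = np.radians(lon - lon0) * _EARTH_RADIUS_M * math.cos(math.radians(lat0))
    y = np.radians(lat - lat0) * _EARTH_RADIUS_M
    return x, y


def season_day(dates: pd.Series, year: int | None = None) -> pd.Series:
    """Day number within the breeding season (day 0 = 1 March)."""
    dates = pd.to_datetime(dates)
    years = dates.dt.year if year is None else year
    start = pd.to_datetime({"year": years, "month": SEASON_START[0],
                            "day": SEASON_START[1]}) if year is None else \
        pd.Timestamp(year=year, month=SEASON_START[0], day=SEASON_START[1])
    return (dates - start).dt.days
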