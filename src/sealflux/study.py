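"""Study tables: per-trip records of at-sea FMR, foraging success and behaviour.

The central data structure is :class:`StudyTable`, a thin validated wrapper
around a pandas DataFrame with one row per seal foraging trip.  A packaged
fixture (``"table1"``) holds the 48 usable doubly-labelled-water measurements
from 33 lactating northern fur seals that the downstream regression modules
operate on.  Seals measured in both summer and fall contribute two rows.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ParseError",
    "ColumnSummary",
    "StudyTable",
    "load_study_table",
    "summarize_column",
]

#: Canonical column schema for a study table.  ``at_sea_fmr`` may be missing
#: on individual rows (the row is retained but flagged unusable).
REQUIRED_COLUMNS = (
    "seal_id",
    "season",
    "at_sea_fmr",
    "mass_change_adj",
    "water_influx",
    "trip_duration",
    "pct_dive",
    "mean_max_depth",
    "fa_cluster",
    "tag_fsa",
)

NUMERIC_COLUMNS = (
    "at_sea_fmr",
    "mass_change_adj",
    "water_influx",
    "trip_duration",
    "pct_dive",
    "mean_max_depth",
    "tag_fsa",
)

VALID_SEASONS = frozenset({"summer", "fall"})


class SchemaError(ValueError):
    """A required column is absent or a categorical value is invalid."""


class ParseError(ValueError):
    """A numeric field failed to parse; the message names the offending row."""


@dataclass(frozen=True)
class ColumnSummary:
    """Five-number summary of a numeric study column (sd uses n-1)."""

    mean: float
    sd: float
    min: float
    max: float
    n: int


class StudyTable:
    """Validated table of per-trip measurements.

    Parameters
    ----------
    records
        DataFrame with the columns in :data:`REQUIRED_COLUMNS`.
    """

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = records.copy().reset_index(drop=True)
        df["seal_id"] = df["seal_id"].astype(str)
        df["season"] = df["season"].astype(str).str.lower()
        bad_season = sorted(set(df["season"]) - VALID_SEASONS) if len(df) else []
        if bad_season:
            raise SchemaError(f"invalid season value(s): {bad_season}")
        for col in NUMERIC_COLUMNS:
            converted = pd.to_numeric(df[col], errors="coerce")
            newly_bad = converted.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
            if newly_bad.any():
                row = int(np.flatnonzero(newly_bad)[0])
                raise ParseError(
                    f"non-numeric value {df[col].iloc[row]!r} in column {col!r} at row {row}"
                )
            df[col] = converted
        df["fa_cluster"] = pd.to_numeric(df["fa_cluster"], errors="coerce").astype("Int64")
        self.records = df

    # -- basic facts -------------------------------------------------------
    @property
    def n_measurements(self) -> int:
        return len(self.records)

    @property
    def n_seals(self) -> int:
        return self.records["seal_id"].nunique()

    @property
    def usable(self) -> pd.Series:
        """Rows with an at-sea FMR value (unusable rows are kept but flagged)."""
        return self.records["at_sea_fmr"].notna()

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.records)

    def __repr__(self) -> str:  # pragma: no cover - repr cosmetics
        return f"StudyTable(n_measurements={self.n_measurements}, n_seals={self.n_seals})"

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def _fixture_path(name: str) -> Path:
    res = importlib.resources.files("sealflux") / "data" / f"{name}.csv"
    return Path(str(res))


def load_study_table(source: str | Path) -> StudyTable:
    """Load a study table from a CSV path or a builtin fixture name.

    ``load_study_table("table1")`` returns the packaged study dataset
    (48 measurements, 33 seals).
    """
    path = Path(source)
    if not path.exists():
        candidate = _fixture_path(str(source))
        if candidate.exists():
            path = candidate
        else:
            raise FileNotFoundError(f"no such file or builtin fixture: {source}")
    df = pd.read_csv(path, dtype={"seal_id": str})
    return StudyTable(df)


def summarize_column(table: StudyTable, column: str) -> ColumnSummary:
    """Mean, sd (n-1), min, max and n of a numeric column, over non-missing rows.

    A single observation yields ``sd = nan`` (undefined).
    """
    if column not in table.records.columns:
        raise SchemaError(f"unknown column: {column!r}")
    if column not in NUMERIC_COLUMNS:
        raise SchemaError(f"column {column!r} is not numeric")
    vals = table.records[column].dropna().astype(float)
    if len(vals) == 0:
        raise ValueError(f"column {column!r} has no non-missing values")
    return ColumnSummary(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
        min=float(vals.min()),
        max=float(vals.max()),
        n=int(len(vals)),
    )
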