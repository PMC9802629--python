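"""Tabular input/output and run configuration.

The pipeline exchanges two delimited-text tables:

* a long-format vitals table with columns
  ``encounter_id, vital, offset_minutes, value`` — one row per raw
  measurement, offsets in integer minutes from admission; and
* a per-encounter table carrying demographics, comorbidity flags,
  admission dates, acuity inputs and outcome/censoring times.

All files are UTF-8 CSV with "." decimal so that any stage can be run
standalone on intermediate artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: The closed set of vital-sign names used throughout the pipeline.
VITALS: tuple[str, ...] = ("SBP", "DBP", "HR", "RR", "SpO2", "Temp")

#: Physiologic plausibility bounds used for outlier filtering.  Values
#: outside these ranges are treated as artifact (transcription or device
#: error) and dropped before hourly resampling.  Config-overridable.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "SBP": (30.0, 300.0),
    "DBP": (10.0, 200.0),
    "HR": (20.0, 300.0),
    "RR": (4.0, 80.0),
    "SpO2": (50.0, 100.0),
    "Temp": (30.0, 43.0),
}

VITALS_COLUMNS = ["encounter_id", "vital", "offset_minutes", "value"]


class SchemaError(ValueError):
    """A malformed row or missing column in an input table."""


@dataclasses.dataclass
class VitalSeries:
    """Irregular raw measurements of one vital for one encounter.

    ``samples`` is a list of ``(offset_minutes, value)`` pairs kept
    sorted by offset; offsets are minutes from admission (time zero).
    """

    encounter_id: str
    vital: str
    samples: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if self.vital not in VITALS:
            raise SchemaError(f"unknown vital {self.vital!r}; expected one of {VITALS}")
        self.samples = sorted(self.samples, key=lambda s: s[0])


@dataclasses.dataclass
class RunConfig:
    """Configuration for one pipeline run.

    ``window_hours`` is the early observation window (6 by default, 12
    in sensitivity mode).  Sensitivity analyses that drop vitals are
    expressed through ``included_vitals``.
    """

    window_hours: int = 6
    included_vitals: tuple[str, ...] = VITALS
    plausibility_bounds: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    n_resamples: int = 100
    subsample_fraction: float = 0.8
    delta_area_threshold: float = 0.10
    seed: int = 0
    split_fractions: tuple[float, float] = (0.55, 0.78)

    def __post_init__(self) -> None:
        if self.window_hours not in (6, 12):
            raise ValueError(f"window_hours must be 6 or 12, got {self.window_hours}")
        if not self.included_vitals:
            raise ValueError("included_vitals must be non-empty")
        unknown = set(self.included_vitals) - set(VITALS)
        if unknown:
            raise ValueError(f"unknown vitals in included_vitals: {sorted(unknown)}")
        for vital, (low, high) in self.plausibility_bounds.items():
            if not low < high:
                raise ValueError(f"bounds for {vital} must satisfy low < high")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "included_vitals" in raw:
            raw["included_vitals"] = tuple(raw["included_vitals"])
        if "plausibility_bounds" in raw:
            raw["plausibility_bounds"] = {
                v: tuple(b) for v, b in raw["plausibility_bounds"].items()
            }
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        if "split_fractions" in raw:
            raw["split_fractions"] = tuple(raw["split_fractions"])
        return cls(**raw)


def read_vitals(path: str | Path) -> list[VitalSeries]:
    """Read a long-format vitals CSV into per-(encounter, vital) series.

    Rows are validated (known vital name, numeric non-negative offset,
    numeric value) and grouped; errors name the offending 1-based data
    row.
    """
    df = pd.read_csv(path, dtype={"encounter_id": str})
    missing = [c for c in VITALS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing} in {path}")

    bad_vital = ~df["vital"].isin(VITALS)
    if bad_vital.any():
        row = int(df.index[bad_vital][0]) + 1
        raise SchemaError(
            f"row {row}: unknown vital {df.loc[df.index[bad_vital][0], 'vital']!r}"
        )
    for col in ("offset_minutes", "value"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(df.index[bad][0]) + 1
            raise SchemaError(f"row {row}: non-numeric {col}")
        df[col] = numeric
    neg = df["offset_minutes"] < 0
    if neg.any():
        row = int(df.index[neg][0]) + 1
        raise SchemaError(f"row {row}: negative offset_minutes")

    out: list[VitalSeries] = []
    for (enc, vital), grp in df.groupby(["encounter_id", "vital"], sort=True):
        samples = list(
            zip(grp["offset_minutes"].astype(float), grp["value"].astype(float))
        )
        out.append(VitalSeries(encounter_id=str(enc), vital=str(vital), samples=samples))
    return out


def write_vitals(series: Sequence[VitalSeries], path: str | Path) -> None:
    """Write series back to the long CSV format (inverse of read_vitals)."""
    rows = [
        {
            "encounter_id": s.encounter_id,
            "vital": s.vital,
            "offset_minutes": off,
            "value": val,
        }
        for s in series
        for off, val in s.samples
    ]
    pd.DataFrame(rows, columns=VITALS_COLUMNS).to_csv(path, index=False)


def read_encounters(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"encounter_id": str})
    if "encounter_id" not in df.columns:
        raise SchemaError(f"missing column 'encounter_id' in {path}")
    return df


def write_encounters(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def split_cohort(
    encounters: pd.DataFrame,
    boundaries: tuple,
    date_column: str = "admission_date",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Chronologically split encounters into train / validation / test.

    Development-on-early, validation-on-later splitting mitigates dataset
    drift (the TRIPOD type 2b design).  ``boundaries`` is either two
    fractions in (0, 1) (cumulative proportions of the date-sorted
    cohort) or two admission-date cutoffs.  Ties on admission date are
    broken by ascending ``encounter_id`` so the partition is stable.
    """
    if len(boundaries) != 2:
        raise ValueError("boundaries must have exactly two elements")
    b0, b1 = boundaries
    df = encounters.sort_values(
        [date_column, "encounter_id"], kind="mergesort"
    ).reset_index(drop=True)
    n = len(df)

    if all(isinstance(b, (int, float)) for b in boundaries):
        if not 0 < b0 < b1 < 1:
            raise ValueError("fraction boundaries must satisfy 0 < b0 < b1 < 1")
        i0 = int(b0 * n)
        i1 = int(b1 * n)
    else:
        if not b0 <= b1:
            raise ValueError("date boundaries must be ordered")
        dates = pd.to_datetime(df[date_column])
        i0 = int((dates < pd.to_datetime(b0)).sum())
        i1 = int((dates < pd.to_datetime(b1)).sum())

    train, val, test = df.iloc[:i0], df.iloc[i0:i1], df.iloc[i1:]
    if len(val) == 0:
        warnings.warn("validation partition is empty", stacklevel=2)
        logger.warning("split_cohort produced an empty validation partition")
    return train, val, test
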