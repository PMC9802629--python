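"""From raw irregular vital-sign series to the clustering feature matrix.

The early-window representation of an admission is a small grid: one
value per vital per hour of the observation window (6 vitals x 6 hours
by default, 36 features).  The steps, applied in order:

1. drop physiologically implausible measurements (range filter);
2. exclude encounters completely missing at least two of the six vitals
   within the window;
3. resample each remaining series to hourly bins, averaging multiple
   in-bin measurements;
4. impute empty bins by forward fill then backward fill along the hour
   axis, falling back to training-cohort per-(vital, hour) medians for
   vitals with no in-window measurement at all;
5. z-score every (vital, hour) feature with training-cohort statistics.

Clustering operates on the standardized features: unscaled Euclidean
distance would be dominated by the mmHg-scale pressures at the expense
of temperature and oxygen saturation.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import VITALS, VitalSeries

logger = logging.getLogger(__name__)

#: Imputation provenance tags, one per grid cell.
TAG_OBSERVED = "observed"
TAG_FORWARD = "forward"
TAG_BACKWARD = "backward"
TAG_MEDIAN = "median"


@dataclasses.dataclass
class VitalGrid:
    """Per-encounter vitals-by-hour matrix with missingness bookkeeping.

    ``values`` has shape ``(len(vitals), H)``; ``observed_mask`` is True
    where at least one raw measurement fell in that hour;
    ``imputation_source`` records, per cell, how its value arose.
    """

    encounter_id: str
    vitals: tuple[str, ...]
    values: np.ndarray
    observed_mask: np.ndarray
    imputation_source: np.ndarray  # dtype=object, tags above

    @property
    def window_hours(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class FeatureMatrix:
    """N x F standardized feature table plus the standardization used.

    Features are ordered vital-major, hour-minor: ``(SBP, h0) ...
    (SBP, h5), (DBP, h0) ...``.  ``standardization`` maps each feature
    name to the training-cohort ``(mean, sd)`` applied in z-scoring, so
    new cohorts can be projected into the same space without refitting.
    """

    encounter_ids: list[str]
    X: np.ndarray
    feature_names: list[tuple[str, int]]
    standardization: dict[tuple[str, int], tuple[float, float]]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def destandardize(self) -> np.ndarray:
        """Recover raw-scale features (inverse of the stored z-scoring)."""
        means = np.array([self.standardization[f][0] for f in self.feature_names])
        sds = np.array([self.standardization[f][1] for f in self.feature_names])
        return self.X * sds + means


def filter_outliers(
    series: VitalSeries, bounds: Mapping[str, tuple[float, float]]
) -> VitalSeries:
    """Drop samples outside the vital's plausibility range."""
    low, high = bounds[series.vital]
    if not (np.isfinite(low) and np.isfinite(high) and low < high):
        raise ValueError(f"invalid bounds for {series.vital}: ({low}, {high})")
    kept = [(off, val) for off, val in series.samples if low <= val <= high]
    dropped = len(series.samples) - len(kept)
    if dropped:
        logger.info(
            "encounter %s %s: dropped %d out-of-range sample(s)",
            series.encounter_id,
            series.vital,
            dropped,
        )
    return VitalSeries(series.encounter_id, series.vital, kept)


def resample_hourly(
    series: VitalSeries, window_hours: int
) -> tuple[np.ndarray, np.ndarray]:
    """Average raw samples into half-open hourly bins [60h, 60(h+1)).

    Returns ``(values, mask)`` of length ``window_hours``; empty bins
    are NaN with ``mask`` False.
    """
    values = np.full(window_hours, np.nan)
    mask = np.zeros(window_hours, dtype=bool)
    if series.samples:
        offs = np.array([s[0] for s in series.samples])
        vals = np.array([s[1] for s in series.samples])
        hours = (offs // 60).astype(int)
        in_window = (hours >= 0) & (hours < window_hours)
        for h in np.unique(hours[in_window]):
            values[h] = vals[in_window][hours[in_window] == h].mean()
            mask[h] = True
    return values, mask


def make_grids(
    series: Iterable[VitalSeries],
    window_hours: int,
    vitals: Sequence[str] = VITALS,
) -> list[VitalGrid]:
    """Assemble unimputed per-encounter grids from raw series."""
    by_encounter: dict[str, dict[str, VitalSeries]] = {}
    for s in series:
        by_encounter.setdefault(s.encounter_id, {})[s.vital] = s

    grids = []
    for enc in sorted(by_encounter):
        values = np.full((len(vitals), window_hours), np.nan)
        mask = np.zeros((len(vitals), window_hours), dtype=bool)
        tags = np.full((len(vitals), window_hours), TAG_MEDIAN, dtype=object)
        for i, vital in enumerate(vitals):
            if vital in by_encounter[enc]:
                values[i], mask[i] = resample_hourly(
                    by_encounter[enc][vital], window_hours
                )
        tags[mask] = TAG_OBSERVED
        grids.append(VitalGrid(enc, tuple(vitals), values, mask, tags))
    return grids


def exclude_encounters(
    grids: Sequence[VitalGrid], min_missing_vitals: int = 2
) -> tuple[list[str], list[str]]:
    """Apply the cohort exclusion rule.

    An encounter is excluded iff it has no in-window measurement for at
    least ``min_missing_vitals`` (default two) of the six vitals.  A
    single completely-missing vital (most often temperature) is kept
    and handled by imputation.
    """
    kept, excluded = [], []
    for g in grids:
        n_absent = int((~g.observed_mask.any(axis=1)).sum())
        (excluded if n_absent >= min_missing_vitals else kept).append(g.encounter_id)
    return kept, excluded


def training_medians(grids: Sequence[VitalGrid]) -> dict[tuple[str, int], float]:
    """Per-(vital, hour) medians over observed cells of the training cohort.

    The per-hour (rather than per-vital) median preserves trajectory
    shape when substituted for a fully missing vital.  Hours with no
    observation anywhere fall back to the vital's overall median.
    """
    medians: dict[tuple[str, int], float] = {}
    for i, vital in enumerate(grids[0].vitals):
        all_vals = np.concatenate(
            [g.values[i][g.observed_mask[i]] for g in grids]
        )
        overall = float(np.median(all_vals)) if all_vals.size else np.nan
        for h in range(grids[0].window_hours):
            vals = np.array(
                [g.values[i, h] for g in grids if g.observed_mask[i, h]]
            )
            medians[(vital, h)] = float(np.median(vals)) if vals.size else overall
    return medians


def impute_grid(
    grid: VitalGrid, medians: Mapping[tuple[str, int], float]
) -> VitalGrid:
    """Fill empty hourly bins: forward fill, then backward fill, then medians.

    Vitals with at least one observation are completed by propagating
    temporally adjacent values (forward first, so a leading gap is the
    only backward-filled region); vitals with no in-window observation
    take the training-cohort median trajectory.  ``observed_mask`` is
    left untouched and every cell is tagged with its provenance.
    """
    H = grid.window_hours
    values = grid.values.copy()
    tags = np.full(values.shape, TAG_OBSERVED, dtype=object)
    for i, vital in enumerate(grid.vitals):
        row = values[i]
        mask = grid.observed_mask[i]
        if not mask.any():
            for h in range(H):
                key = (vital, h)
                if key not in medians:
                    raise KeyError(f"training median missing for {key}")
                row[h] = medians[key]
                tags[i, h] = TAG_MEDIAN
            continue
        # forward fill
        last = None
        for h in range(H):
            if mask[h]:
                last = row[h]
            elif last is not None:
                row[h] = last
                tags[i, h] = TAG_FORWARD
        # backward fill (leading gap only, after forward fill)
        nxt = None
        for h in range(H - 1, -1, -1):
            if mask[h]:
                nxt = row[h]
            elif np.isnan(row[h]) and nxt is not None:
                row[h] = nxt
                tags[i, h] = TAG_BACKWARD
    return VitalGrid(grid.encounter_id, grid.vitals, values, grid.observed_mask, tags)


def build_features(
    grids: Sequence[VitalGrid],
    included_vitals: Sequence[str] = VITALS,
    fit_standardization: bool = True,
    standardization: Mapping[tuple[str, int], tuple[float, float]] | None = None,
) -> FeatureMatrix:
    """Flatten imputed grids into the standardized N x F feature matrix.

    F = |included_vitals| x window_hours (36 by default).  In fitting
    mode, per-feature means and SDs are estimated from these grids and
    stored; otherwise the supplied training standardization is applied
    unchanged so validation/test cohorts live in the training feature
    space.
    """
    if not grids:
        raise ValueError("no grids supplied")
    H = grids[0].window_hours
    feature_names = [(v, h) for v in included_vitals for h in range(H)]
    index = {v: i for i, v in enumerate(grids[0].vitals)}
    raw = np.empty((len(grids), len(feature_names)))
    for r, g in enumerate(grids):
        if np.isnan(g.values).any():
            raise ValueError(f"grid {g.encounter_id} contains NaN; impute first")
        for c, (v, h) in enumerate(feature_names):
            raw[r, c] = g.values[index[v], h]

    if fit_standardization:
        means = raw.mean(axis=0)
        sds = raw.std(axis=0, ddof=0)
        if np.any(sds == 0):
            bad = [feature_names[i] for i in np.flatnonzero(sds == 0)]
            raise ValueError(f"zero-variance feature(s) in fitting mode: {bad}")
        standardization = {
            f: (float(m), float(s)) for f, m, s in zip(feature_names, means, sds)
        }
    else:
        if standardization is None:
            raise ValueError("standardization required when fit_standardization=False")
        means = np.array([standardization[f][0] for f in feature_names])
        sds = np.array([standardization[f][1] for f in feature_names])

    X = (raw - means) / sds
    return FeatureMatrix(
        encounter_ids=[g.encounter_id for g in grids],
        X=X,
        feature_names=feature_names,
        standardization=dict(standardization),
    )


def feature_matrix_to_frame(fm: FeatureMatrix) -> pd.DataFrame:
    cols = [f"{v}_h{h}" for v, h in fm.feature_names]
    df = pd.DataFrame(fm.X, columns=cols)
    df.insert(0, "encounter_id", fm.encounter_ids)
    return df


def frame_to_feature_matrix(
    df: pd.DataFrame, standardization: Mapping[tuple[str, int], tuple[float, float]]
) -> FeatureMatrix:
    names = []
    for col in df.columns:
        if col == "encounter_id":
            continue
        vital, h = col.rsplit("_h", 1)
        names.append((vital, int(h)))
    X = df.drop(columns="encounter_id").to_numpy(dtype=float)
    return FeatureMatrix(
        encounter_ids=df["encounter_id"].astype(str).tolist(),
        X=X,
        feature_names=names,
        standardization=dict(standardization),
    )
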