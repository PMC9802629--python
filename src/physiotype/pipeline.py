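"""End-to-end orchestration of the physiotype pipeline.

Thin convenience layer over the stage modules: raw series -> filtered,
excluded, gridded, imputed, standardized features -> consensus
clustering -> labeled centroid model.  The CLI and the analysis
scripts are built on these entry points; each stage remains usable on
its own.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from . import preprocess
from .cluster import ConsensusKMeans, ConsensusKMeansResults, ResampleScheme
from .io import RunConfig, VitalSeries
from .model import PhysiotypeModel, derive_model, label_map, predict


@dataclasses.dataclass
class PreprocessResult:
    features: preprocess.FeatureMatrix
    kept: list[str]
    excluded: list[str]
    medians: dict[tuple[str, int], float]


def preprocess_cohort(
    series: Sequence[VitalSeries],
    config: RunConfig,
    medians: Mapping[tuple[str, int], float] | None = None,
    standardization: Mapping[tuple[str, int], tuple[float, float]] | None = None,
) -> PreprocessResult:
    """Filter, exclude, resample, impute and standardize one cohort.

    In training mode (``medians``/``standardization`` omitted) the
    per-(vital, hour) medians and z-scoring statistics are fitted on
    this cohort and returned for reuse; validation/test cohorts pass
    the training values so they are projected into the same space.
    """
    filtered = [
        preprocess.filter_outliers(s, config.plausibility_bounds) for s in series
    ]
    grids = preprocess.make_grids(filtered, config.window_hours)
    kept, excluded = preprocess.exclude_encounters(grids)
    kept_set = set(kept)
    grids = [g for g in grids if g.encounter_id in kept_set]
    if not grids:
        raise ValueError("all encounters excluded")
    fitted_medians = (
        dict(medians) if medians is not None else preprocess.training_medians(grids)
    )
    imputed = [preprocess.impute_grid(g, fitted_medians) for g in grids]
    features = preprocess.build_features(
        imputed,
        included_vitals=config.included_vitals,
        fit_standardization=standardization is None,
        standardization=standardization,
    )
    return PreprocessResult(features, kept, excluded, fitted_medians)


@dataclasses.dataclass
class DerivationResult:
    consensus: ConsensusKMeansResults
    model: PhysiotypeModel
    letters: np.ndarray  # physiotype letter per encounter


def derive_physiotypes(
    features: preprocess.FeatureMatrix, config: RunConfig
) -> DerivationResult:
    """Consensus clustering plus centroid model on a training cohort."""
    cons = ConsensusKMeans(
        features.X,
        k_range=config.k_range,
        scheme=ResampleScheme(
            n_resamples=config.n_resamples,
            subsample_fraction=config.subsample_fraction,
            base_seed=config.seed,
        ),
        threshold=config.delta_area_threshold,
    ).fit()
    model = derive_model(features, cons.labels)
    mapping = label_map(model, features, cons.labels)
    letters = np.array([mapping[int(c)] for c in cons.labels])
    return DerivationResult(consensus=cons, model=model, letters=letters)


def predict_physiotypes(
    model: PhysiotypeModel,
    series: Sequence[VitalSeries],
    config: RunConfig,
    medians: Mapping[tuple[str, int], float],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Assign physiotypes to a new cohort with a trained model.

    Returns ``(encounter_ids, letters, distances)``.  Standardization
    and imputation medians come from the model / training cohort and
    are never refit.
    """
    res = preprocess_cohort(
        series, config, medians=medians, standardization=model.standardization
    )
    letters, distances = predict(model, res.features)
    return res.features.encounter_ids, letters, distances
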