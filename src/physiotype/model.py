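"""Portable physiotype model: labeled centroids plus standardization.

Once the training cohort is partitioned, each cluster is summarized by
its centroid in standardized feature space and the clusters are named
A, B, C, D by ascending mean systolic blood pressure on the raw (mmHg)
scale.  New encounters — standardized with the *training* statistics,
never refit — are assigned to the nearest centroid by Euclidean
distance.  The model serializes to a flat JSON artifact so validation
and test stages never need the training data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import FeatureMatrix

PHYSIOTYPE_LABELS = ("A", "B", "C", "D")


@dataclasses.dataclass
class PhysiotypeModel:
    """Labeled centroids in the training-standardized feature space."""

    centroids: np.ndarray  # (k, F), standardized scale, rows in label order
    labels: tuple[str, ...]  # ("A", "B", "C", "D") for k=4
    feature_names: list[tuple[str, int]]
    standardization: dict[tuple[str, int], tuple[float, float]]

    def raw_centroids(self) -> np.ndarray:
        """Centroids de-standardized back to physical units."""
        means = np.array([self.standardization[f][0] for f in self.feature_names])
        sds = np.array([self.standardization[f][1] for f in self.feature_names])
        return self.centroids * sds + means

    def centroid_table(self) -> pd.DataFrame:
        cols = [f"{v}_h{h}" for v, h in self.feature_names]
        df = pd.DataFrame(self.raw_centroids(), columns=cols)
        df.insert(0, "physiotype", list(self.labels))
        return df

    def save(self, path: str | Path) -> None:
        payload = {
            "labels": list(self.labels),
            "feature_names": [[v, h] for v, h in self.feature_names],
            "centroids": self.centroids.tolist(),
            "standardization": {
                f"{v}_h{h}": list(self.standardization[(v, h)])
                for v, h in self.feature_names
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PhysiotypeModel":
        payload = json.loads(Path(path).read_text())
        names = [(v, int(h)) for v, h in payload["feature_names"]]
        return cls(
            centroids=np.array(payload["centroids"]),
            labels=tuple(payload["labels"]),
            feature_names=names,
            standardization={
                (v, h): tuple(payload["standardization"][f"{v}_h{h}"])
                for v, h in names
            },
        )


def derive_model(features: FeatureMatrix, labels: np.ndarray) -> PhysiotypeModel:
    """Summarize a partition as a labeled centroid model.

    Centroids are cluster means of the standardized features; clusters
    are ordered by the mean of their de-standardized SBP features
    across hours, ascending, and named A, B, C, D (for k=4; other k
    get A, B, ... prefixes of the alphabet).
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    k = len(clusters)
    if k > 26:
        raise ValueError("too many clusters to letter-label")
    cents = []
    for c in clusters:
        members = features.X[labels == c]
        if members.shape[0] == 0:
            raise ValueError(f"cluster {c} is empty")
        cents.append(members.mean(axis=0))
    cents = np.vstack(cents)

    sbp_idx = [i for i, (v, _) in enumerate(features.feature_names) if v == "SBP"]
    if not sbp_idx:
        raise ValueError("feature matrix carries no SBP features for label ordering")
    means = np.array([features.standardization[f][0] for f in features.feature_names])
    sds = np.array([features.standardization[f][1] for f in features.feature_names])
    raw = cents * sds + means
    order = np.argsort(raw[:, sbp_idx].mean(axis=1), kind="stable")

    letters = tuple(chr(ord("A") + i) for i in range(k))
    return PhysiotypeModel(
        centroids=cents[order],
        labels=letters,
        feature_names=list(features.feature_names),
        standardization=dict(features.standardization),
    )


def label_map(model: PhysiotypeModel, features: FeatureMatrix,
              cluster_labels: np.ndarray) -> dict[int, str]:
    """Map each original cluster index to its physiotype letter."""
    cluster_labels = np.asarray(cluster_labels)
    clusters = np.unique(cluster_labels)
    cents = np.vstack(
        [features.X[cluster_labels == c].mean(axis=0) for c in clusters]
    )
    out = {}
    for i, c in enumerate(clusters):
        d = np.linalg.norm(model.centroids - cents[i], axis=1)
        out[int(c)] = model.labels[int(np.argmin(d))]
    return out


def predict(
    model: PhysiotypeModel, features: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each encounter to the nearest centroid.

    ``features`` must already be standardized with the model's stored
    statistics.  Returns ``(labels, distances)`` where ``distances``
    has one Euclidean distance per centroid; ties break toward the
    earlier letter (argmin returns the first minimum).
    """
    if list(features.feature_names) != list(model.feature_names):
        raise ValueError("feature names do not match the model")
    diffs = features.X[:, None, :] - model.centroids[None, :, :]
    distances = np.sqrt((diffs**2).sum(axis=2))
    idx = distances.argmin(axis=1)
    labels = np.array([model.labels[i] for i in idx])
    return labels, distances
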