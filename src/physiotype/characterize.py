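"""Descriptive views of derived physiotypes.

Three read-only characterizations of a labeled feature matrix:

* pairwise standardized mean differences — for a pair of phenotypes,
  each (vital, hour) feature is re-standardized on the *pooled pair*
  (mean 0, SD 1), and the two group means on that scale quantify how
  much the feature separates the pair;
* self-organizing-map mosaics — a small Kohonen grid is trained on the
  features and each phenotype is summarized by the occupancy-weighted
  codebook of its members, yielding an "average mosaic" per phenotype;
* a 2-D embedding (t-SNE) for visualization.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .preprocess import FeatureMatrix


def smd_pairwise(
    features: FeatureMatrix, labels: Sequence, pair: tuple
) -> pd.DataFrame:
    """Standardized group means per feature for one phenotype pair.

    Rows are ordered by descending absolute between-group difference;
    columns give each group's mean on the pooled-pair z-scale.  A value
    of 1 means that group's mean sits one pooled SD above the pair as
    a whole.
    """
    labels = np.asarray(labels)
    a, b = pair
    in_pair = (labels == a) | (labels == b)
    if (labels == a).sum() < 2 or (labels == b).sum() < 2:
        raise ValueError("both groups need at least 2 members")
    X = features.X[in_pair]
    sub_labels = labels[in_pair]
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    mean_a = Z[sub_labels == a].mean(axis=0)
    mean_b = Z[sub_labels == b].mean(axis=0)
    df = pd.DataFrame(
        {
            "feature": [f"{v}_h{h}" for v, h in features.feature_names],
            f"mean_{a}": mean_a,
            f"mean_{b}": mean_b,
            "difference": mean_a - mean_b,
        }
    )
    df["abs_difference"] = df["difference"].abs()
    return df.sort_values("abs_difference", ascending=False, ignore_index=True)


@dataclasses.dataclass
class SomMosaic:
    """Trained Kohonen map plus per-item best-matching units."""

    codebook: np.ndarray  # (G, G, F)
    bmu: np.ndarray  # (N, 2) grid coordinates of each item's best node
    quantization_errors: np.ndarray  # per epoch

    @property
    def grid_size(self) -> int:
        return self.codebook.shape[0]


def train_som(
    features: FeatureMatrix,
    grid_size: int = 8,
    epochs: int = 20,
    seed: int = 0,
    lr_start: float = 0.5,
    lr_end: float = 0.01,
) -> SomMosaic:
    """Online Kohonen training with decaying rate and Gaussian neighborhood.

    The learning rate decays linearly from ``lr_start`` to ``lr_end``
    and the neighborhood radius from ``grid_size / 2`` to 0.5 over the
    epochs.  Mean quantization error (distance of each item to its
    best-matching unit) is recorded per epoch.  Deterministic under
    ``seed``.
    """
    X = features.X
    if X.shape[0] == 0:
        raise ValueError("empty features")
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    rng = np.random.default_rng(seed)
    n, F = X.shape
    G = grid_size
    codebook = X[rng.choice(n, size=G * G, replace=n < G * G)].reshape(G, G, F).copy()
    coords = np.stack(np.meshgrid(np.arange(G), np.arange(G), indexing="ij"), axis=-1)

    qerrors = []
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        lr = lr_start + (lr_end - lr_start) * frac
        sigma = G / 2 + (0.5 - G / 2) * frac
        order = rng.permutation(n)
        errs = np.empty(n)
        for j, i in enumerate(order):
            x = X[i]
            d2 = ((codebook - x) ** 2).sum(axis=2)
            win = np.unravel_index(np.argmin(d2), d2.shape)
            errs[j] = np.sqrt(d2[win])
            grid_d2 = ((coords - np.array(win)) ** 2).sum(axis=2)
            h = np.exp(-grid_d2 / (2 * sigma**2))
            codebook += (lr * h)[:, :, None] * (x - codebook)
        qerrors.append(errs.mean())

    d2 = ((X[:, None, None, :] - codebook[None]) ** 2).sum(axis=3)
    flat = d2.reshape(n, -1).argmin(axis=1)
    bmu = np.column_stack(np.unravel_index(flat, (G, G)))
    return SomMosaic(codebook=codebook, bmu=bmu, quantization_errors=np.array(qerrors))


def mosaic_for_phenotype(
    som: SomMosaic, labels: Sequence, phenotype
) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy map and occupancy-weighted average mosaic for one phenotype.

    The mosaic is the average of the codebook vectors of the nodes the
    phenotype's members map to, weighted by how many members each node
    captures; the occupancy grid sums to the phenotype's size.
    """
    labels = np.asarray(labels)
    members = np.flatnonzero(labels == phenotype)
    if members.size == 0:
        raise ValueError(f"phenotype {phenotype!r} absent from labels")
    G = som.grid_size
    occupancy = np.zeros((G, G))
    for i in members:
        occupancy[tuple(som.bmu[i])] += 1
    weights = occupancy / occupancy.sum()
    mosaic = som.codebook * weights[:, :, None]
    return mosaic, occupancy


def modal_node(som: SomMosaic, labels: Sequence, phenotype) -> tuple[int, int]:
    """Grid coordinates of the node capturing most of a phenotype."""
    _, occ = mosaic_for_phenotype(som, labels, phenotype)
    return tuple(int(v) for v in np.unravel_index(np.argmax(occ), occ.shape))


def embed_2d(
    features: FeatureMatrix, seed: int = 0, perplexity: float = 30.0
) -> np.ndarray:
    """t-SNE embedding of the feature matrix into 2-D for plotting.

    Pure visualization: the contract is an (N, 2) array in which
    separable groups remain separated.  Perplexity is capped below the
    sample count as t-SNE requires.
    """
    X = features.X
    if X.shape[0] < 5:
        raise ValueError("need at least 5 points to embed")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate (constant) features")
    perplexity = min(perplexity, (X.shape[0] - 1) / 3)
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return tsne.fit_transform(X)
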