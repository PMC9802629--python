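"""Consensus k-means clustering with resampling-based model selection.

For each candidate number of clusters *k*, the data are repeatedly
subsampled without replacement and partitioned with k-means; the
consensus matrix entry ``M_k(i, j)`` is the fraction of resamples in
which items *i* and *j* were assigned to the same cluster, among the
resamples in which both were drawn.  A stable clustering structure
drives the entries toward {0, 1}, which is summarized by the area under
the empirical CDF of the upper-triangular entries.  The number of
clusters is chosen from the relative change ("delta area") of that
area as *k* grows: the largest *k* that still produces a substantial
relative gain.

The surface follows the model/results idiom: build a
:class:`ConsensusKMeans` from a feature matrix, call :meth:`fit`, and
read the selected k, final labels and diagnostics off the returned
:class:`ConsensusKMeansResults`.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


@dataclasses.dataclass
class ResampleScheme:
    """Subsampling plan for consensus estimation.

    Resample ``r`` uses seed ``base_seed + r`` (a seed ladder), so a
    full run is reproducible and any single resample can be replayed.
    """

    n_resamples: int = 100
    subsample_fraction: float = 0.8
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 2:
            raise ValueError("n_resamples must be >= 2")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")


def kmeans_partition(
    X: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10
) -> np.ndarray:
    """Best-of-``n_restarts`` Lloyd k-means with k-means++ seeding."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of items {X.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    return km.fit_predict(X)


def consensus_matrix(
    X: np.ndarray,
    k: int,
    scheme: ResampleScheme,
    n_restarts: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the N x N consensus matrix for ``k`` clusters.

    Returns ``(M, counts)`` where ``counts[i, j]`` is the number of
    resamples in which both *i* and *j* were drawn.  Pairs never
    co-sampled get consensus 0 with a warning (vanishingly rare at the
    default 100 resamples of 80%).  The diagonal is set to 1.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    m = int(np.ceil(scheme.subsample_fraction * n))
    together = np.zeros((n, n))
    counts = np.zeros((n, n))
    for r in range(scheme.n_resamples):
        rng = np.random.default_rng(scheme.base_seed + r)
        idx = rng.choice(n, size=m, replace=False)
        labels = kmeans_partition(X[idx], k, seed=scheme.base_seed + r,
                                  n_restarts=n_restarts)
        same = labels[:, None] == labels[None, :]
        counts[np.ix_(idx, idx)] += 1.0
        together[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(counts > 0, together / np.maximum(counts, 1), 0.0)
    never = (counts == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        warnings.warn(
            f"{int(never.sum()) // 2} pair(s) never co-sampled; consensus set to 0",
            stacklevel=2,
        )
    np.fill_diagonal(M, 1.0)
    return M, counts


def cdf_area(M: np.ndarray) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Empirical CDF of upper-triangular consensus entries and its area.

    The CDF is a step function over [0, 1]; the area is the exact sum
    of step-height x step-width terms.  Returns ``((x, F(x)), area)``
    with the CDF evaluated at the sorted unique entries.
    """
    n = M.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")
    entries = M[np.triu_indices(n, k=1)]
    xs, counts = np.unique(entries, return_counts=True)
    F = np.cumsum(counts) / entries.size
    # Area under the right-continuous step CDF over [0, 1]: each level
    # F(x_i) extends from x_i to the next jump (or to 1).
    widths = np.diff(np.append(xs, 1.0))
    area = float(np.sum(F * widths))
    return (xs, F), area


def delta_areas(areas: Mapping[int, float]) -> dict[int, float]:
    """Relative change in CDF area as k increases.

    By convention the first k in the range keeps its absolute area
    (there is no smaller model to compare against).
    """
    ks = sorted(areas)
    if not ks:
        raise ValueError("empty areas")
    out = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        out[k] = (areas[k] - areas[prev]) / areas[prev]
    return out


def select_k(areas: Mapping[int, float], threshold: float = 0.10) -> int:
    """Pick the number of clusters by the delta-area rule.

    The selected k is the largest k whose relative area gain strictly
    exceeds ``threshold``; if none qualifies the minimum of the range
    is returned (parsimony).  Strict ">" means a boundary tie keeps
    the smaller k.
    """
    deltas = delta_areas(areas)
    ks = sorted(deltas)
    qualifying = [k for k in ks if deltas[k] > threshold]
    return max(qualifying) if qualifying else ks[0]


def cluster_consensus(M: np.ndarray, labels: np.ndarray) -> dict[int, float]:
    """Mean within-cluster pairwise consensus, per cluster.

    A singleton cluster has no pairs; by convention it reports 1 with
    a warning.
    """
    out: dict[int, float] = {}
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            warnings.warn(f"cluster {c} is a singleton; consensus set to 1",
                          stacklevel=2)
            out[int(c)] = 1.0
            continue
        sub = M[np.ix_(idx, idx)]
        pairs = sub[np.triu_indices(len(idx), k=1)]
        out[int(c)] = float(pairs.mean())
    return out


class ConsensusKMeans:
    """Consensus k-means model over a standardized feature matrix.

    Parameters
    ----------
    X : (N, F) array
        Standardized clustering features.
    k_range : sequence of int
        Candidate cluster counts, contiguous from the smallest (default
        2..8).
    scheme : ResampleScheme
        Subsampling plan shared across k.
    threshold : float
        Delta-area threshold for :func:`select_k`.
    """

    def __init__(
        self,
        X: np.ndarray,
        k_range: Sequence[int] = (2, 3, 4, 5, 6, 7, 8),
        scheme: ResampleScheme | None = None,
        threshold: float = 0.10,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.k_range = tuple(k_range)
        self.scheme = scheme or ResampleScheme()
        self.threshold = threshold

    def fit(self, final_restarts: int = 10) -> "ConsensusKMeansResults":
        matrices: dict[int, np.ndarray] = {}
        areas: dict[int, float] = {}
        cdfs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for k in self.k_range:
            M, _ = consensus_matrix(self.X, k, self.scheme)
            matrices[k] = M
            cdfs[k], areas[k] = cdf_area(M)
        k_star = select_k(areas, self.threshold)
        labels = kmeans_partition(
            self.X, k_star, seed=self.scheme.base_seed, n_restarts=final_restarts
        )
        cc = cluster_consensus(matrices[k_star], labels)
        return ConsensusKMeansResults(
            model=self,
            consensus_matrices=matrices,
            cdfs=cdfs,
            areas=areas,
            deltas=delta_areas(areas),
            selected_k=k_star,
            labels=labels,
            cluster_consensus_=cc,
        )


@dataclasses.dataclass
class ConsensusKMeansResults:
    """Fitted consensus clustering: matrices, model-selection curve, labels."""

    model: ConsensusKMeans
    consensus_matrices: dict[int, np.ndarray]
    cdfs: dict[int, tuple[np.ndarray, np.ndarray]]
    areas: dict[int, float]
    deltas: dict[int, float]
    selected_k: int
    labels: np.ndarray
    cluster_consensus_: dict[int, float]

    def summary(self) -> pd.DataFrame:
        """Per-k model-selection table (CDF area, delta area, selected flag)."""
        rows = [
            {
                "k": k,
                "cdf_area": self.areas[k],
                "delta_area": self.deltas[k],
                "selected": k == self.selected_k,
            }
            for k in sorted(self.areas)
        ]
        return pd.DataFrame(rows)

    def consensus_summary(self) -> pd.DataFrame:
        """Cluster sizes and within-cluster consensus at the selected k."""
        rows = [
            {
                "cluster": c,
                "size": int((self.labels == c).sum()),
                "cluster_consensus": v,
            }
            for c, v in sorted(self.cluster_consensus_.items())
        ]
        return pd.DataFrame(rows)
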