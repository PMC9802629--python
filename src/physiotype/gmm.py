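"""Gaussian-mixture reproducibility check for the consensus partition.

A k-component diagonal-covariance Gaussian mixture is fitted to the
same standardized feature matrix by expectation-maximization; the
resulting soft partition is compared with the consensus k-means
partition (adjusted Rand index), and the posterior membership
probabilities quantify how crisply the mixture separates encounters.
Diagonal covariances are the default: with 36 features and modest
cohort sizes, full 36x36 covariance estimation per component is
unstable and unnecessary for a reproducibility check.

The EM loop is implemented here (rather than delegated) so each fit
can record and assert the per-iteration log-likelihood trace; the
standard library implementation serves as an independent cross-check
in the test suite.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.metrics import adjusted_rand_score


@dataclasses.dataclass
class GmmFit:
    """A fitted k-component diagonal Gaussian mixture."""

    n_components: int
    weights: np.ndarray  # (k,)
    means: np.ndarray  # (k, F)
    variances: np.ndarray  # (k, F) diagonal covariances
    responsibilities: np.ndarray  # (N, k), rows sum to 1
    log_likelihood: float
    log_likelihood_trace: np.ndarray
    bic: float
    n_parameters: int
    converged: bool
    degenerate: bool = False

    @property
    def labels(self) -> np.ndarray:
        return self.responsibilities.argmax(axis=1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(self.n_components),
                "weight": self.weights,
                "size": np.bincount(self.labels, minlength=self.n_components),
            }
        )


def _log_gaussian_diag(
    X: np.ndarray, means: np.ndarray, variances: np.ndarray
) -> np.ndarray:
    """(N, k) log density of each point under each diagonal Gaussian."""
    n, F = X.shape
    out = np.empty((n, means.shape[0]))
    for c in range(means.shape[0]):
        diff2 = (X - means[c]) ** 2 / variances[c]
        out[:, c] = -0.5 * (
            F * np.log(2 * np.pi) + np.log(variances[c]).sum() + diff2.sum(axis=1)
        )
    return out


def _em_once(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    var_floor: np.ndarray,
) -> GmmFit:
    n, F = X.shape
    # init: means from k distinct data points, shared variance, equal weights
    means = X[rng.choice(n, size=k, replace=False)].copy()
    variances = np.tile(X.var(axis=0) + var_floor, (k, 1))
    weights = np.full(k, 1.0 / k)

    trace = []
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        log_pdf = _log_gaussian_diag(X, means, variances)
        weighted = log_pdf + np.log(weights)
        norm = logsumexp(weighted, axis=1)
        resp = np.exp(weighted - norm[:, None])
        ll = float(norm.sum())
        trace.append(ll)
        if ll - prev_ll < tol * abs(ll) and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
        # M step
        nk = resp.sum(axis=0) + 1e-300
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        for c in range(k):
            diff2 = (X - means[c]) ** 2
            var = (resp[:, c] @ diff2) / nk[c]
            low = var < var_floor
            if low.any():
                var = np.maximum(var, var_floor)
            variances[c] = var

    # parameter count: (k-1) weights + k*F means + k*F variances
    p = (k - 1) + 2 * k * F
    bic = -2.0 * trace[-1] + p * np.log(n)
    # a component resting on the variance floor or holding fewer than
    # ~2 effective members is a likelihood spike, not a mixture fit
    nk = resp.sum(axis=0)
    degenerate = bool(
        np.any(nk < 2.0) or np.any(variances <= var_floor * (1 + 1e-9))
    )
    return GmmFit(
        n_components=k,
        weights=weights,
        means=means,
        variances=variances,
        responsibilities=resp,
        log_likelihood=trace[-1],
        log_likelihood_trace=np.array(trace),
        bic=bic,
        n_parameters=p,
        converged=converged,
        degenerate=degenerate,
    )


def fit_gmm(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-7,
    max_iter: int = 300,
    var_floor_frac: float = 1e-6,
) -> GmmFit:
    """EM fit of a diagonal-covariance Gaussian mixture, best of ``n_init``.

    Component variances are floored at ``var_floor_frac`` of each
    feature's overall variance to prevent degenerate collapse (a
    warning is issued when the floor binds).  The log-likelihood trace
    of the winning run is retained; EM guarantees it is non-decreasing.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n <= k:
        raise ValueError(f"need more points than components (N={n}, k={k})")
    var_floor = var_floor_frac * X.var(axis=0)
    if np.any(var_floor == 0):
        var_floor = np.maximum(var_floor, 1e-12)
    rng = np.random.default_rng(seed)
    best: GmmFit | None = None
    for _ in range(n_init):
        fit = _em_once(X, k, rng, tol, max_iter, var_floor)
        if best is None:
            best = fit
        elif (not fit.degenerate, fit.log_likelihood) > (
            not best.degenerate,
            best.log_likelihood,
        ):
            best = fit
    assert best is not None
    if best.degenerate:
        warnings.warn("best GMM fit is degenerate (collapsed component)",
                      stacklevel=2)
    return best


def membership_quality(fit: GmmFit) -> dict[str, float | np.ndarray]:
    """Summaries of how confidently members belong to their component.

    Returns each item's maximum posterior, the overall median, the
    per-component median, and the fraction of items whose maximum
    posterior lies in the marginal band [0.45, 0.55] (low-confidence
    assignments).
    """
    max_post = fit.responsibilities.max(axis=1)
    labels = fit.labels
    per_cluster = {
        int(c): float(np.median(max_post[labels == c])) for c in np.unique(labels)
    }
    marginal = float(((max_post >= 0.45) & (max_post <= 0.55)).mean())
    return {
        "max_posterior": max_post,
        "median_posterior": float(np.median(max_post)),
        "per_cluster_median": per_cluster,
        "marginal_fraction": marginal,
    }


def compare_partitions(
    labels_a: np.ndarray, labels_b: np.ndarray
) -> tuple[float, pd.DataFrame]:
    """Adjusted Rand index and contingency table between two labelings."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must have equal length")
    ari = float(adjusted_rand_score(labels_a, labels_b))
    table = pd.crosstab(pd.Series(labels_a, name="a"), pd.Series(labels_b, name="b"))
    return ari, table


def bic_scan(
    X: np.ndarray, k_range=(2, 3, 4, 5, 6, 7, 8), seed: int = 0, n_init: int = 5
) -> pd.DataFrame:
    """Fit mixtures across ``k_range`` and tabulate BIC per k."""
    rows = []
    for k in k_range:
        fit = fit_gmm(X, k, seed=seed, n_init=n_init)
        rows.append({"k": k, "bic": fit.bic, "log_likelihood": fit.log_likelihood})
    return pd.DataFrame(rows)
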