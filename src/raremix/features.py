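"""Cluster-level features (separation, coverage) and the logistic rare prior.

Each candidate cluster k carries a frozen two-component feature vector
f_k = (separation, coverage):

* separation f1 — minimum Euclidean distance from the cluster's mean to the
  mean of any abundant cluster, in embedding units;
* coverage f2 — fraction of subjects in which the cluster has at least one
  cell.

Both components are min–max standardized to [0, 1] across the candidate
clusters, and the prior probability that cluster k is a genuine rare
population is the logistic

    P(gamma_k = 1) = 1 / (1 + exp{-(b0 + b1 . f_k)}),

with fixed coefficients b0 = -1, b1 = (1, 1), calibrated so that
f = (0.5, 0.5) gives prior probability exactly 0.5 and the two features
contribute equally.

Features are computed once from the initial candidate-cluster means and the
abundant-cluster means, then held fixed for the whole MCMC run so the prior
on gamma is a fixed distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import expit

__all__ = [
    "LogisticPriorConfig",
    "ClusterFeatureSet",
    "compute_separation",
    "compute_coverage",
    "standardize_unit_interval",
    "logistic_prior",
    "cluster_features",
]


@dataclass(frozen=True)
class LogisticPriorConfig:
    """Coefficients of the logistic prior on the rare indicator."""

    b0: float = -1.0
    b1: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if not np.isfinite([self.b0, *self.b1]).all():
            raise ValueError("logistic prior coefficients must be finite")


def compute_separation(
    candidate_means: np.ndarray, abundant_means: np.ndarray
) -> np.ndarray:
    """Min Euclidean distance from each candidate mean to any abundant mean.

    Parameters are (K, G) and (K_a, G) arrays of cluster means sharing the
    embedding dimension G.
    """
    candidate_means = np.atleast_2d(np.asarray(candidate_means, dtype=float))
    abundant_means = np.atleast_2d(np.asarray(abundant_means, dtype=float))
    if abundant_means.size == 0:
        raise ValueError("separation undefined: no abundant clusters supplied")
    if candidate_means.shape[1] != abundant_means.shape[1]:
        raise ValueError("candidate and abundant means have different dimensions")
    return cdist(candidate_means, abundant_means).min(axis=1)


def compute_coverage(cluster_counts: np.ndarray) -> np.ndarray:
    """Fraction of subjects with at least one cell per cluster.

    ``cluster_counts`` is a (D, K) array of per-subject per-cluster cell
    counts n_dk.
    """
    counts = np.atleast_2d(np.asarray(cluster_counts))
    D = counts.shape[0]
    if D == 0:
        raise ValueError("coverage undefined: zero subjects")
    if (counts < 0).any():
        raise ValueError("negative cell counts")
    return (counts > 0).sum(axis=0) / D


def standardize_unit_interval(values: np.ndarray) -> np.ndarray:
    """Min–max rescale to [0, 1]; a constant vector maps to all 0.5.

    The constant case is the neutral point of the logistic prior (a feature
    carrying no between-cluster information contributes its calibration
    value), and avoids 0/0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot standardize an empty vector")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.full_like(v, 0.5)
    return (v - lo) / (hi - lo)


def logistic_prior(f, config: LogisticPriorConfig = LogisticPriorConfig()) -> np.ndarray:
    """Evaluate P(gamma=1) = expit(b0 + b1 . f) for feature rows ``f``.

    ``f`` is a single 2-vector or a (K, 2) array; returns a scalar or (K,)
    array of probabilities in (0, 1).
    """
    f_arr = np.asarray(f, dtype=float)
    scalar = f_arr.ndim == 1
    f_arr = np.atleast_2d(f_arr)
    if f_arr.shape[1] != len(config.b1):
        raise ValueError("feature dimension does not match b1")
    p = expit(config.b0 + f_arr @ np.asarray(config.b1, dtype=float))
    return float(p[0]) if scalar else p


@dataclass
class ClusterFeatureSet:
    """Frozen per-cluster features and their standardized form."""

    separation_raw: np.ndarray
    coverage_raw: np.ndarray
    config: LogisticPriorConfig = field(default_factory=LogisticPriorConfig)

    def __post_init__(self) -> None:
        self.separation_raw = np.asarray(self.separation_raw, dtype=float)
        self.coverage_raw = np.asarray(self.coverage_raw, dtype=float)
        if self.separation_raw.shape != self.coverage_raw.shape:
            raise ValueError("separation and coverage lengths differ")
        self.f1 = standardize_unit_interval(self.separation_raw)
        self.f2 = standardize_unit_interval(self.coverage_raw)

    @property
    def K_init(self) -> int:
        return self.separation_raw.shape[0]

    @property
    def f(self) -> np.ndarray:
        """(K, 2) standardized feature matrix."""
        return np.column_stack([self.f1, self.f2])

    def prior_probabilities(self) -> np.ndarray:
        """Logistic prior P(gamma_k = 1) for every cluster."""
        return logistic_prior(self.f, self.config)


def cluster_features(
    candidate_means: np.ndarray,
    abundant_means: np.ndarray,
    cluster_counts: np.ndarray,
    config: LogisticPriorConfig = LogisticPriorConfig(),
) -> ClusterFeatureSet:
    """Build the frozen feature set from initial means and subject counts."""
    sep = compute_separation(candidate_means, abundant_means)
    cov = compute_coverage(cluster_counts)
    if sep.shape != cov.shape:
        raise ValueError("means and counts imply different cluster numbers")
    return ClusterFeatureSet(sep, cov, config)
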