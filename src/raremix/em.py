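"""Post-hoc EM refinement of rare-cluster membership with entropy filtering.

After the sampler has called K_rare clusters rare, their cells are
re-examined against the K_a abundant clusters in a (K_rare + K_a)-component
Gaussian mixture.  Abundant components keep their means and variances fixed
throughout (they are estimated from the full dataset and should not be bent
toward the small candidate set); rare components and all mixing proportions
are re-estimated by EM.  Because the candidate set was pre-selected to be
depleted of abundant cells, the initial per-subject probability mass on the
abundant components is a small constant (0.1 by default, split equally over
the K_a components).

After convergence, each cell's responsibility row over all K_all components
is scored by its Shannon entropy (natural log); cells whose entropy exceeds
log(K_all)/10^3 — i.e. cells without an essentially one-hot assignment —
are removed from the rare calls, as are cells whose maximum responsibility
lies on an abundant component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .gibbs import Chain, MultiSubjectMatrix, _log_likelihood_matrix

__all__ = [
    "AbundantClusterParams",
    "EmState",
    "initialize_em",
    "e_step",
    "m_step",
    "run_em",
    "observed_loglik",
    "entropy_filter",
    "responsibility_entropy",
    "assign_final_labels",
    "default_entropy_threshold",
    "FILTERED",
]

FILTERED = -1  # final-label code for removed cells
_VAR_FLOOR = 1e-8


@dataclass
class AbundantClusterParams:
    """Fixed diagonal-Gaussian parameters of the abundant clusters."""

    means: np.ndarray       # (G, K_a)
    variances: np.ndarray   # (G, K_a) positive
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        if self.means.shape != self.variances.shape:
            raise ValueError("means and variances shapes differ")
        if (self.variances <= 0).any():
            raise ValueError("abundant variances must be positive")
        if not self.names:
            self.names = [f"abundant{k}" for k in range(self.K_a)]
        if len(self.names) != self.K_a:
            raise ValueError("names length mismatch")

    @property
    def K_a(self) -> int:
        return self.means.shape[1]

    @property
    def G(self) -> int:
        return self.means.shape[0]

    @classmethod
    def from_cells(cls, X: np.ndarray, labels, names=None) -> "AbundantClusterParams":
        """Empirical per-cluster mean/variance of abundant cells.

        ``labels`` may be any hashable cluster identifiers; clusters are
        ordered by first appearance unless ``names`` fixes the order.
        """
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels)
        if names is None:
            _, first = np.unique(labels, return_index=True)
            names = [labels[j] for j in np.sort(first)]
        means, variances = [], []
        for name in names:
            cells = X[labels == name]
            if cells.shape[0] < 2:
                raise ValueError(f"abundant cluster {name!r} has < 2 cells")
            means.append(cells.mean(axis=0))
            variances.append(np.maximum(cells.var(axis=0), _VAR_FLOOR))
        return cls(np.column_stack(means), np.column_stack(variances),
                   [str(n) for n in names])


@dataclass
class EmState:
    """Parameters of the K_all-component refinement mixture.

    Columns 0..K_rare-1 are the (mutable) rare components, the remaining
    K_a columns hold the fixed abundant parameters.  ``loglik`` traces the
    observed-data log-likelihood over iterations.
    """

    pi: np.ndarray       # (D, K_all)
    mu: np.ndarray       # (G, K_all)
    sigma2: np.ndarray   # (G, K_all)
    K_rare: int
    loglik: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.allclose(self.pi.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("pi rows must lie on the simplex")
        if (self.sigma2 <= 0).any():
            raise ValueError("sigma2 must be positive")
        if not 0 <= self.K_rare <= self.pi.shape[1]:
            raise ValueError("K_rare out of range")

    @property
    def K_all(self) -> int:
        return self.pi.shape[1]

    def copy(self) -> "EmState":
        return EmState(self.pi.copy(), self.mu.copy(), self.sigma2.copy(),
                       self.K_rare, list(self.loglik))


def initialize_em(
    chain: Chain,
    rare_clusters: np.ndarray,
    abundant: AbundantClusterParams,
    abundant_mass: float = 0.1,
) -> EmState:
    """Build the initial EM state from MCMC posterior means.

    Rare components take the posterior means of (mu, sigma2, pi) for the
    detected rare clusters; per subject, the rare mixing proportions are
    rescaled to total ``1 - abundant_mass`` and the abundant components
    split ``abundant_mass`` equally (no size information about abundant
    clusters is assumed for the candidate set).
    """
    rare_clusters = np.atleast_1d(np.asarray(rare_clusters, dtype=int))
    if rare_clusters.size == 0:
        raise ValueError("no rare clusters detected: nothing to refine")
    if not 0.0 < abundant_mass < 1.0:
        raise ValueError("abundant_mass must lie in (0, 1)")
    mu_rare = chain.mu.mean(axis=0)[:, rare_clusters]
    sig_rare = np.maximum(chain.sigma2.mean(axis=0)[:, rare_clusters], _VAR_FLOOR)
    if mu_rare.shape[0] != abundant.G:
        raise ValueError("rare and abundant dimension counts differ")
    pi_rare = chain.pi.mean(axis=0)[:, rare_clusters]      # (D, K_rare)
    pi_rare = pi_rare / pi_rare.sum(axis=1, keepdims=True) * (1.0 - abundant_mass)
    K_a = abundant.K_a
    pi_ab = np.full((pi_rare.shape[0], K_a), abundant_mass / K_a)
    return EmState(
        np.hstack([pi_rare, pi_ab]),
        np.hstack([mu_rare, abundant.means]),
        np.hstack([sig_rare, abundant.variances]),
        K_rare=rare_clusters.size,
    )


def _log_joint(data: MultiSubjectMatrix, state: EmState) -> np.ndarray:
    """(N, K_all) log[pi_dk * prod_g N(X | mu, sigma2)] with log(0) = -inf."""
    ll = _log_likelihood_matrix(data.X, state.mu, state.sigma2)
    with np.errstate(divide="ignore"):
        return ll + np.log(state.pi[data.subject])


def e_step(data: MultiSubjectMatrix, state: EmState) -> np.ndarray:
    """Responsibilities omega_dik, the posterior of Z under current params."""
    logw = _log_joint(data, state)
    m = logw.max(axis=1, keepdims=True)
    if not np.isfinite(m).all():
        raise FloatingPointError("zero total density for at least one cell")
    w = np.exp(logw - m)
    return w / w.sum(axis=1, keepdims=True)


def observed_loglik(data: MultiSubjectMatrix, state: EmState) -> float:
    """Observed-data log-likelihood sum_i log sum_k pi exp(loglik)."""
    return float(logsumexp(_log_joint(data, state), axis=1).sum())


def m_step(
    data: MultiSubjectMatrix, omega: np.ndarray, state: EmState
) -> EmState:
    """Closed-form M-step with abundant columns held fixed.

    pi_dk = mean responsibility within subject d (all components);
    mu, sigma2 = responsibility-weighted mean / variance pooled over all
    subjects (rare components only).  A rare component with zero total
    responsibility is frozen for this iteration.
    """
    D, K_all, K_r = state.pi.shape[0], state.K_all, state.K_rare
    new = state.copy()
    # mixing proportions: per-subject mean responsibility
    sums = np.zeros((D, K_all))
    np.add.at(sums, data.subject, omega)
    n_d = np.maximum(np.bincount(data.subject, minlength=D), 1)
    new.pi = sums / n_d[:, None]
    # renormalize subjects that do have cells (guard round-off); empty
    # subjects keep their previous proportions
    has_cells = np.bincount(data.subject, minlength=D) > 0
    new.pi[~has_cells] = state.pi[~has_cells]
    new.pi /= new.pi.sum(axis=1, keepdims=True)
    if K_r > 0:
        w = omega[:, :K_r]                       # (N, K_rare)
        tot = w.sum(axis=0)                      # (K_rare,)
        dead = tot <= 0.0
        if dead.any():
            warnings.warn(
                f"rare component(s) {np.flatnonzero(dead).tolist()} received "
                "zero responsibility; frozen for this iteration",
                RuntimeWarning,
                stacklevel=2,
            )
        safe = np.where(dead, 1.0, tot)
        mu_new = (data.X.T @ w) / safe[None, :]
        # weighted variance around the *updated* mean
        sq = (data.X ** 2).T @ w
        var_new = sq / safe[None, :] - mu_new ** 2
        var_new = np.maximum(var_new, _VAR_FLOOR)
        keep = ~dead
        new.mu[:, :K_r][:, keep] = mu_new[:, keep]
        new.sigma2[:, :K_r][:, keep] = var_new[:, keep]
    return new


def run_em(
    data: MultiSubjectMatrix,
    init: EmState,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[EmState, np.ndarray]:
    """Alternate E/M until the relative log-likelihood change drops below tol.

    The observed-data log-likelihood must be non-decreasing (abundant
    parameters are fixed, so this is a generalized EM with a guaranteed
    ascent property); a decrease beyond numerical slack aborts, since it
    can only indicate an implementation defect.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    state = init.copy()
    ll_old = observed_loglik(data, state)
    state.loglik.append(ll_old)
    omega = e_step(data, state)
    for _ in range(max_iter):
        state = m_step(data, omega, state)
        ll_new = observed_loglik(data, state)
        if ll_new < ll_old - 1e-8 * max(1.0, abs(ll_old)):
            raise FloatingPointError(
                f"log-likelihood decreased from {ll_old:.10g} to {ll_new:.10g}"
            )
        state.loglik.append(ll_new)
        omega = e_step(data, state)
        if abs(ll_new - ll_old) < tol * max(1.0, abs(ll_old)):
            break
        ll_old = ll_new
    return state, omega


def default_entropy_threshold(K_all: int) -> float:
    """The membership-ambiguity cutoff log(K_all) / 10^3 (natural log)."""
    if K_all < 1:
        raise ValueError("K_all must be >= 1")
    return float(np.log(K_all)) / 1e3


def responsibility_entropy(omega: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) of each responsibility row; 0 log 0 = 0."""
    w = np.asarray(omega, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(w > 0.0, w * np.log(w), 0.0)
    return -terms.sum(axis=1)


def entropy_filter(
    omega: np.ndarray, K_all: int | None = None, threshold: float | None = None
) -> np.ndarray:
    """Boolean mask of cells retained (entropy <= threshold).

    The default threshold is log(K_all)/10^3, which retains only cells with
    an essentially one-hot responsibility row.
    """
    omega = np.asarray(omega, dtype=float)
    if K_all is None:
        K_all = omega.shape[1]
    if threshold is None:
        threshold = default_entropy_threshold(K_all)
    return responsibility_entropy(omega) <= threshold


def assign_final_labels(
    omega: np.ndarray, mask: np.ndarray, K_rare: int
) -> np.ndarray:
    """Final per-cell labels: rare component index, or FILTERED (-1).

    A cell is filtered if its entropy mask is False or if its maximum
    responsibility over all components lies on an abundant component
    (those cells most likely belong to an abundant population).  Retained
    cells are labeled by the argmax over the rare components; argmax ties
    break to the lowest component index.
    """
    omega = np.asarray(omega, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if omega.shape[0] != mask.shape[0]:
        raise ValueError("omega and mask row counts differ")
    top_all = omega.argmax(axis=1)
    rare_label = omega[:, :K_rare].argmax(axis=1) if K_rare > 0 else np.zeros(
        omega.shape[0], dtype=int)
    labels = np.where(mask & (top_all < K_rare), rare_label, FILTERED)
    return labels.astype(int)
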