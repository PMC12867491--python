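"""Gibbs sampler for the multi-subject Gaussian mixture with a rare indicator.

Model
-----
Candidate cells from D subjects live in a G-dimensional embedding.  For
subject d, cell i and dimension g,

    X_dgi | Z_di = k   ~  N(mu_gk, sigma2_gk)
    P(Z_di = k)        =  pi_dk
    (pi_d1..pi_dK)     ~  Dirichlet(alpha_1..alpha_K)
    mu_gk              ~  N(eta_g, tau_mu2_g)
    sigma2_gk | gamma_k = 1  ~  Inv-Gamma(nu1, tau_sigma)
    sigma2_gk | gamma_k = 0  ~  Inv-Gamma(nu0, tau_sigma)
    P(gamma_k = 1)     =  expit(b0 + b1 . f_k)      (frozen features f_k)

with nu1 > nu0, so gamma_k = 1 corresponds to a prior that concentrates the
per-dimension variances near tau_sigma / nu1 — a *compact* cluster.  Cluster
parameters (mu, sigma2) are shared across subjects; only the mixing
proportions pi_dk are subject-specific, so the effective sample size for a
cluster is the pooled count n_k = sum_d n_dk.

Inference is a systematic-scan Gibbs sampler (Z -> pi -> mu -> sigma2 ->
gamma per iteration); all priors are conditionally conjugate, so every full
conditional is in closed form.  The inverse-gamma uses the shape–scale
parameterization with density proportional to x^{-(nu+1)} exp(-tau/x).

Clusters with posterior P(gamma_k = 1 | data) strictly greater than 0.5 are
called rare.  Labels are anchored to the initial candidate clusters: no
relabeling is performed, so gamma_k always indexes the k-th initial cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logit, expit

from .features import ClusterFeatureSet

__all__ = [
    "MultiSubjectMatrix",
    "ModelState",
    "PriorSpec",
    "Chain",
    "initial_state",
    "sample_assignments",
    "sample_proportions",
    "sample_means",
    "sample_variances",
    "sample_indicators",
    "run_mcmc",
    "posterior_rare_probability",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class MultiSubjectMatrix:
    """Candidate-cell embedding stacked over subjects.

    ``X`` is the (N, G) stacked matrix; ``subject`` holds integer subject
    codes in [0, D); ``subject_ids`` and ``cell_ids`` carry the original
    string identifiers.
    """

    X: np.ndarray
    subject: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.subject = np.asarray(self.subject, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (cells x dims)")
        if self.subject.shape != (self.X.shape[0],):
            raise ValueError("subject codes must be one per cell")
        if not self.subject_ids:
            D = int(self.subject.max()) + 1 if self.subject.size else 0
            self.subject_ids = [f"s{d}" for d in range(D)]
        if self.subject.size and self.subject.max() >= len(self.subject_ids):
            raise ValueError("subject code out of range")
        if (self.subject < 0).any():
            raise ValueError("negative subject code")
        if not self.cell_ids:
            self.cell_ids = [f"cell{j}" for j in range(self.X.shape[0])]
        if len(self.cell_ids) != self.X.shape[0]:
            raise ValueError("cell_ids length mismatch")

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def G(self) -> int:
        return self.X.shape[1]

    @property
    def D(self) -> int:
        return len(self.subject_ids)

    @property
    def n_d(self) -> np.ndarray:
        """Per-subject cell counts (D,)."""
        return np.bincount(self.subject, minlength=self.D)

    @classmethod
    def from_subject_list(cls, matrices, subject_ids=None) -> "MultiSubjectMatrix":
        """Stack a list of per-subject (n_d, G) matrices."""
        mats = [np.atleast_2d(np.asarray(m, dtype=float)) for m in matrices]
        Gs = {m.shape[1] for m in mats}
        if len(Gs) > 1:
            raise ValueError("subjects have differing dimension counts")
        subj = np.concatenate(
            [np.full(m.shape[0], d, dtype=int) for d, m in enumerate(mats)]
        ) if mats else np.empty(0, dtype=int)
        X = np.vstack(mats) if mats else np.empty((0, 0))
        ids = list(subject_ids) if subject_ids else [f"s{d}" for d in range(len(mats))]
        return cls(X, subj, ids)

    def subset(self, mask) -> "MultiSubjectMatrix":
        """Row-subset keeping the full subject roster."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return MultiSubjectMatrix(
            self.X[idx], self.subject[idx], list(self.subject_ids),
            [self.cell_ids[j] for j in idx],
        )


@dataclass
class ModelState:
    """One MCMC state of the mixture model."""

    Z: np.ndarray          # (N,) labels in [0, K)
    pi: np.ndarray         # (D, K) simplex rows
    mu: np.ndarray         # (G, K)
    sigma2: np.ndarray     # (G, K) positive
    gamma: np.ndarray      # (K,) in {0, 1}

    def validate(self) -> None:
        if not np.allclose(self.pi.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("pi rows do not sum to 1")
        if (self.sigma2 <= 0).any():
            raise ValueError("sigma2 must be positive")
        if not np.isin(self.gamma, (0, 1)).all():
            raise ValueError("gamma must be binary")

    @property
    def K(self) -> int:
        return self.pi.shape[1]

    def copy(self) -> "ModelState":
        return ModelState(self.Z.copy(), self.pi.copy(), self.mu.copy(),
                          self.sigma2.copy(), self.gamma.copy())


@dataclass
class PriorSpec:
    """Hyperparameters of the hierarchical mixture.

    ``eta`` and ``tau_mu2`` may be scalars or per-dimension (G,) vectors;
    the per-dimension empirical-Bayes defaults (grand mean / variance of the
    candidate cells) are built by :meth:`from_data`.  ``prior_probs`` are
    the frozen logistic prior values P(gamma_k = 1).
    """

    alpha: np.ndarray
    eta: np.ndarray
    tau_mu2: np.ndarray
    nu0: float
    nu1: float
    tau_sigma: float
    prior_probs: np.ndarray
    features: ClusterFeatureSet | None = None

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.eta = np.atleast_1d(np.asarray(self.eta, dtype=float))
        self.tau_mu2 = np.atleast_1d(np.asarray(self.tau_mu2, dtype=float))
        self.prior_probs = np.atleast_1d(np.asarray(self.prior_probs, dtype=float))
        if (self.alpha <= 0).any():
            raise ValueError("alpha must be positive")
        if (self.tau_mu2 <= 0).any():
            raise ValueError("tau_mu2 must be positive")
        if self.tau_sigma <= 0:
            raise ValueError("tau_sigma must be positive")
        if not (self.nu1 > self.nu0 > 0):
            raise ValueError("need nu1 > nu0 > 0")
        if ((self.prior_probs <= 0) | (self.prior_probs >= 1)).any():
            raise ValueError("prior_probs must lie in (0, 1)")

    @property
    def K(self) -> int:
        return self.prior_probs.shape[0]

    @classmethod
    def from_data(
        cls,
        data: MultiSubjectMatrix,
        features: ClusterFeatureSet,
        alpha: float | np.ndarray = 1.0,
        nu0: float = 2.0,
        nu1: float = 10.0,
        tau_sigma: float = 1.0,
        eta: np.ndarray | None = None,
        tau_mu2: np.ndarray | None = None,
    ) -> "PriorSpec":
        """Empirical-Bayes defaults: eta/tau_mu2 from the pooled cells."""
        K = features.K_init
        alpha_vec = np.full(K, float(alpha)) if np.ndim(alpha) == 0 else np.asarray(alpha, float)
        if eta is None:
            eta = data.X.mean(axis=0) if data.N else np.zeros(data.G)
        if tau_mu2 is None:
            if data.N > 1:
                tau_mu2 = np.maximum(data.X.var(axis=0), 1e-8)
            else:
                tau_mu2 = np.ones(data.G)
        return cls(alpha_vec, eta, tau_mu2, nu0, nu1, tau_sigma,
                   features.prior_probabilities(), features)


@dataclass
class Chain:
    """Post-burn-in MCMC draws stored as compact arrays.

    ``gamma`` is (S, K), ``pi`` is (S, D, K), ``mu`` and ``sigma2`` are
    (S, G, K); ``Z_last`` is the final assignment vector.  ``len(chain)``
    equals ``n_iter - n_burn``.
    """

    gamma: np.ndarray
    pi: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    Z_last: np.ndarray
    seed: int
    n_iter: int
    n_burn: int

    def __len__(self) -> int:
        return self.gamma.shape[0]

    @property
    def K(self) -> int:
        return self.gamma.shape[1]


def _log_likelihood_matrix(X: np.ndarray, mu: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
    """(N, K) matrix of sum_g log N(X_ig | mu_gk, sigma2_gk)."""
    inv = 1.0 / sigma2                                   # (G, K)
    const = -0.5 * (np.log(sigma2) + _LOG2PI).sum(axis=0)  # (K,)
    quad = (X ** 2) @ inv - 2.0 * (X @ (mu * inv)) + (mu ** 2 * inv).sum(axis=0)
    return const - 0.5 * quad


def sample_assignments(
    data: MultiSubjectMatrix, state: ModelState, rng: np.random.Generator
) -> np.ndarray:
    """Draw Z_di from the categorical full conditional, in log space.

    P(Z_di = k) is proportional to pi_dk * prod_g N(X_dgi | mu_gk,
    sigma2_gk); the log weights are max-subtracted before exponentiation
    and sampling is inverse-CDF on the normalized probabilities.
    """
    if data.N == 0:
        return np.empty(0, dtype=int)
    logw = _log_likelihood_matrix(data.X, state.mu, state.sigma2)
    logw = logw + np.log(state.pi[data.subject])
    m = logw.max(axis=1, keepdims=True)
    if not np.isfinite(m).all():
        raise FloatingPointError("degenerate state: all component densities are zero")
    p = np.exp(logw - m)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(data.N)
    Z = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return np.minimum(Z, state.K - 1)


def _counts_dk(Z: np.ndarray, subject: np.ndarray, D: int, K: int) -> np.ndarray:
    counts = np.zeros((D, K), dtype=int)
    np.add.at(counts, (subject, Z), 1)
    return counts


def sample_proportions(
    Z: np.ndarray,
    subject: np.ndarray,
    D: int,
    alpha: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw pi_d. from Dirichlet(alpha + n_d.) independently per subject."""
    K = alpha.shape[0]
    counts = _counts_dk(Z, subject, D, K)
    g = rng.standard_gamma(alpha[None, :] + counts)
    total = g.sum(axis=1, keepdims=True)
    # shape >= alpha_min > 0 makes an all-zero row essentially impossible,
    # but guard against underflow
    bad = total[:, 0] == 0.0
    if bad.any():
        g[bad] = 1.0
        total = g.sum(axis=1, keepdims=True)
    return g / total


def _cluster_sufficients(data: MultiSubjectMatrix, Z: np.ndarray, K: int):
    """Pooled per-cluster counts, sums and sums of squares, each per dim."""
    n_k = np.bincount(Z, minlength=K).astype(float)
    s1 = np.zeros((K, data.G))
    s2 = np.zeros((K, data.G))
    np.add.at(s1, Z, data.X)
    np.add.at(s2, Z, data.X ** 2)
    return n_k, s1.T, s2.T  # (K,), (G, K), (G, K)


def sample_means(
    data: MultiSubjectMatrix,
    Z: np.ndarray,
    sigma2: np.ndarray,
    eta: np.ndarray,
    tau_mu2: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw mu_gk from its conjugate normal full conditional.

    Variance v = (1/tau_mu2 + n_k/sigma2_gk)^-1 and mean
    v * (eta/tau_mu2 + sum_{cells in k} X / sigma2_gk); with n_k = 0 this is
    exactly the prior N(eta, tau_mu2).
    """
    K = sigma2.shape[1]
    n_k, s1, _ = _cluster_sufficients(data, Z, K)
    eta_col = eta[:, None]
    tau_col = tau_mu2[:, None]
    v = 1.0 / (1.0 / tau_col + n_k[None, :] / sigma2)
    m = v * (eta_col / tau_col + s1 / sigma2)
    return m + np.sqrt(v) * rng.standard_normal(sigma2.shape)


def sample_variances(
    data: MultiSubjectMatrix,
    Z: np.ndarray,
    mu: np.ndarray,
    gamma: np.ndarray,
    nu0: float,
    nu1: float,
    tau_sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw sigma2_gk from Inv-Gamma(nu_gamma + n_k/2, tau + RSS_gk/2).

    Shape–scale parameterization: Inv-Gamma(a, b) = b / Gamma(a, 1).
    """
    K = mu.shape[1]
    n_k, s1, s2 = _cluster_sufficients(data, Z, K)
    rss = s2 - 2.0 * mu * s1 + n_k[None, :] * mu ** 2
    rss = np.maximum(rss, 0.0)  # guard tiny negative round-off
    nu = np.where(gamma == 1, nu1, nu0)
    shape = nu[None, :] + 0.5 * n_k[None, :]
    scale = tau_sigma + 0.5 * rss
    return scale / rng.standard_gamma(np.broadcast_to(shape, mu.shape))


def invgamma_logpdf(x, shape, scale) -> np.ndarray:
    """log density of Inv-Gamma(shape, scale): b^a/G(a) x^-(a+1) e^(-b/x)."""
    x = np.asarray(x, dtype=float)
    return (shape * np.log(scale) - gammaln(shape)
            - (shape + 1.0) * np.log(x) - scale / x)


def sample_indicators(
    sigma2: np.ndarray,
    prior_probs: np.ndarray,
    nu0: float,
    nu1: float,
    tau_sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw gamma_k ~ Bernoulli(q_k) from its full conditional.

    log-odds(q_k) = logit(prior_k) + sum_g [log InvGa(sigma2_gk; nu1, tau)
    - log InvGa(sigma2_gk; nu0, tau)]; smaller variances push q_k up when
    nu1 > nu0.
    """
    log_ratio = (invgamma_logpdf(sigma2, nu1, tau_sigma)
                 - invgamma_logpdf(sigma2, nu0, tau_sigma)).sum(axis=0)
    q = expit(logit(prior_probs) + log_ratio)
    return (rng.random(prior_probs.shape[0]) < q).astype(int)


def conditional_indicator_probability(
    sigma2: np.ndarray,
    prior_probs: np.ndarray,
    nu0: float,
    nu1: float,
    tau_sigma: float,
) -> np.ndarray:
    """The Bernoulli probability q_k used by :func:`sample_indicators`."""
    log_ratio = (invgamma_logpdf(np.atleast_2d(sigma2), nu1, tau_sigma)
                 - invgamma_logpdf(np.atleast_2d(sigma2), nu0, tau_sigma)).sum(axis=0)
    return expit(logit(np.atleast_1d(prior_probs)) + log_ratio)


def initial_state(
    data: MultiSubjectMatrix,
    init_labels: np.ndarray,
    prior: PriorSpec,
) -> ModelState:
    """Deterministic initialization from the candidate-cluster labels.

    Means/variances are empirical per cluster (prior values for empty
    clusters), pi is the posterior-mean Dirichlet update of the label
    counts, and gamma starts at 1 wherever the logistic prior exceeds 0.5.
    """
    Z = np.asarray(init_labels, dtype=int)
    K = prior.K
    if Z.size and (Z.min() < 0 or Z.max() >= K):
        raise ValueError("init labels out of range for K clusters")
    D, G = data.D, data.G
    counts = _counts_dk(Z, data.subject, D, K)
    pi = (prior.alpha[None, :] + counts).astype(float)
    pi /= pi.sum(axis=1, keepdims=True)
    mu = np.tile(prior.eta[:, None], (1, K)).astype(float)
    prior_var = prior.tau_sigma / max(prior.nu0 - 1.0, 0.5)
    sigma2 = np.full((G, K), prior_var)
    for k in range(K):
        cells = data.X[Z == k]
        if cells.shape[0] >= 1:
            mu[:, k] = cells.mean(axis=0)
        if cells.shape[0] >= 2:
            sigma2[:, k] = np.maximum(cells.var(axis=0), 1e-8)
    gamma = (prior.prior_probs > 0.5).astype(int)
    return ModelState(Z, pi, mu, sigma2, gamma)


def gibbs_scan(
    data: MultiSubjectMatrix,
    state: ModelState,
    prior: PriorSpec,
    rng: np.random.Generator,
) -> ModelState:
    """One systematic scan: Z -> pi -> mu -> sigma2 -> gamma (in place)."""
    state.Z = sample_assignments(data, state, rng)
    state.pi = sample_proportions(state.Z, data.subject, data.D, prior.alpha, rng)
    state.mu = sample_means(data, state.Z, state.sigma2, prior.eta,
                            prior.tau_mu2, rng)
    state.sigma2 = sample_variances(data, state.Z, state.mu, state.gamma,
                                    prior.nu0, prior.nu1, prior.tau_sigma, rng)
    state.gamma = sample_indicators(state.sigma2, prior.prior_probs,
                                    prior.nu0, prior.nu1, prior.tau_sigma, rng)
    return state


def run_mcmc(
    data: MultiSubjectMatrix,
    init: ModelState,
    prior: PriorSpec,
    n_iter: int = 5000,
    n_burn: int = 2500,
    seed: int | None = None,
) -> Chain:
    """Run the Gibbs sampler and store post-burn-in draws.

    ``seed`` is mandatory: chains must be reproducible, and a silent
    time-based default would hide that.
    """
    if seed is None:
        raise ValueError("seed is required for a reproducible chain")
    if not 0 <= n_burn < n_iter:
        raise ValueError("need 0 <= n_burn < n_iter")
    rng = np.random.default_rng(seed)
    state = init.copy()
    state.validate()
    S = n_iter - n_burn
    D, G, K = data.D, data.G, prior.K
    gamma_tr = np.empty((S, K), dtype=int)
    pi_tr = np.empty((S, D, K))
    mu_tr = np.empty((S, G, K))
    sig_tr = np.empty((S, G, K))
    for it in range(n_iter):
        state = gibbs_scan(data, state, prior, rng)
        if not (np.isfinite(state.mu).all() and np.isfinite(state.sigma2).all()):
            raise FloatingPointError(f"non-finite state at iteration {it}")
        if it >= n_burn:
            s = it - n_burn
            gamma_tr[s] = state.gamma
            pi_tr[s] = state.pi
            mu_tr[s] = state.mu
            sig_tr[s] = state.sigma2
    return Chain(gamma_tr, pi_tr, mu_tr, sig_tr, state.Z.copy(),
                 int(seed), n_iter, n_burn)


def posterior_rare_probability(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster posterior P(gamma_k = 1 | data) and the rare-call set.

    The probability is the fraction of stored states with gamma_k = 1;
    clusters strictly above 0.5 are flagged rare (a cluster at exactly 0.5
    is not called).
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    probs = chain.gamma.mean(axis=0)
    rare = np.flatnonzero(probs > 0.5)
    return probs, rare
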