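"""Model/Results interface tying the pipeline together.

``RareCellMixtureModel`` is built from a candidate-cell embedding, the
initial candidate-cluster labels, and the abundant-cluster parameters; its
:meth:`fit` runs the Gibbs sampler, calls rare clusters at posterior
P(gamma > 0.5), refines membership with the post-hoc EM + entropy filter,
and returns a :class:`RareCellResults` carrying the chain, the calls, the
per-cell labels and a ``summary()`` table.  Group comparison hangs off the
results object.

Typical use::

    model = RareCellMixtureModel(data, init_labels, abundant)
    res = model.fit(n_iter=2000, n_burn=1000, seed=7)
    print(res.summary())
    table = res.compare_groups(groups, seed=7)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import em as _em
from . import features as _feat
from . import gibbs as _gibbs
from . import inference as _inf

__all__ = ["RareCellMixtureModel", "RareCellResults"]


class RareCellMixtureModel:
    """Hierarchical Bayesian mixture for multi-subject rare cell calling.

    Parameters
    ----------
    data
        Candidate-cell embedding as a :class:`~raremix.gibbs.MultiSubjectMatrix`.
    init_labels
        Initial candidate-cluster labels (one per cell, 0..K_init-1) from an
        upstream detector.
    abundant
        Fixed abundant-cluster parameters, used both as reference points for
        the separation feature and as the fixed components of the post-hoc EM.
    prior_config
        Coefficients of the logistic prior on the rare indicator.
    alpha, nu0, nu1, tau_sigma, eta, tau_mu2
        Hyperparameter overrides; see :class:`~raremix.gibbs.PriorSpec`.
    """

    def __init__(
        self,
        data: _gibbs.MultiSubjectMatrix,
        init_labels,
        abundant: _em.AbundantClusterParams,
        prior_config: _feat.LogisticPriorConfig = _feat.LogisticPriorConfig(),
        alpha: float = 1.0,
        nu0: float = 2.0,
        nu1: float = 10.0,
        tau_sigma: float = 1.0,
        eta=None,
        tau_mu2=None,
    ) -> None:
        self.data = data
        self.init_labels = np.asarray(init_labels, dtype=int)
        if self.init_labels.shape != (data.N,):
            raise ValueError("init_labels must have one entry per cell")
        if data.G != abundant.G:
            raise ValueError("data and abundant parameters disagree on G")
        self.abundant = abundant
        self.K_init = int(self.init_labels.max()) + 1 if data.N else 0
        if self.K_init < 1:
            raise ValueError("need at least one candidate cluster")

        cand_means = np.vstack([
            data.X[self.init_labels == k].mean(axis=0) for k in range(self.K_init)
        ])
        counts = np.zeros((data.D, self.K_init), dtype=int)
        np.add.at(counts, (data.subject, self.init_labels), 1)
        self.features = _feat.cluster_features(
            cand_means, abundant.means.T, counts, prior_config)
        self.prior = _gibbs.PriorSpec.from_data(
            data, self.features, alpha=alpha, nu0=nu0, nu1=nu1,
            tau_sigma=tau_sigma, eta=eta, tau_mu2=tau_mu2)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        abundant: _em.AbundantClusterParams,
        subject_col: str = "subject_id",
        cluster_col: str = "init_cluster",
        dim_cols=None,
        **kwargs,
    ) -> "RareCellMixtureModel":
        """Build from a tidy frame (one row per candidate cell).

        ``dim_cols`` defaults to every numeric column except the metadata
        columns; subjects and clusters are coded by first appearance.
        """
        if dim_cols is None:
            dim_cols = [c for c in frame.columns
                        if c not in (subject_col, cluster_col)
                        and pd.api.types.is_numeric_dtype(frame[c])]
        subj_codes, subj_ids = pd.factorize(frame[subject_col])
        clus_codes, _ = pd.factorize(frame[cluster_col])
        data = _gibbs.MultiSubjectMatrix(
            frame[dim_cols].to_numpy(dtype=float),
            subj_codes,
            [str(s) for s in subj_ids],
            [str(i) for i in frame.index],
        )
        return cls(data, clus_codes, abundant, **kwargs)

    def fit(
        self,
        n_iter: int = 5000,
        n_burn: int = 2500,
        seed: int | None = None,
        refine: bool = True,
        abundant_mass: float = 0.1,
        entropy_threshold: float | None = None,
        em_max_iter: int = 200,
        em_tol: float = 1e-6,
    ) -> "RareCellResults":
        """Run MCMC, call rare clusters, and (optionally) refine membership."""
        init = _gibbs.initial_state(self.data, self.init_labels, self.prior)
        chain = _gibbs.run_mcmc(self.data, init, self.prior,
                                n_iter=n_iter, n_burn=n_burn, seed=seed)
        probs, rare = _gibbs.posterior_rare_probability(chain)
        res = RareCellResults(model=self, chain=chain,
                              rare_probabilities=probs, rare_clusters=rare)
        if refine and rare.size > 0:
            state = _em.initialize_em(chain, rare, self.abundant,
                                      abundant_mass=abundant_mass)
            state, omega = _em.run_em(self.data, state,
                                      max_iter=em_max_iter, tol=em_tol)
            mask = _em.entropy_filter(omega, state.K_all,
                                      threshold=entropy_threshold)
            labels = _em.assign_final_labels(omega, mask, state.K_rare)
            res.em_state = state
            res.responsibilities = omega
            res.entropy = _em.responsibility_entropy(omega)
            res.final_labels = labels
        return res


@dataclass
class RareCellResults:
    """Fitted rare-cell calls with uncertainty and refined membership."""

    model: RareCellMixtureModel
    chain: _gibbs.Chain
    rare_probabilities: np.ndarray
    rare_clusters: np.ndarray
    em_state: _em.EmState | None = None
    responsibilities: np.ndarray | None = None
    entropy: np.ndarray | None = None
    final_labels: np.ndarray | None = None
    _group_results: dict = field(default_factory=dict, repr=False)

    # -- posterior summaries -------------------------------------------------
    @property
    def posterior_mean_pi(self) -> np.ndarray:
        """(D, K_init) posterior mean mixing proportions pi~_dk."""
        return self.chain.pi.mean(axis=0)

    @property
    def posterior_mean_mu(self) -> np.ndarray:
        return self.chain.mu.mean(axis=0)

    @property
    def posterior_mean_sigma2(self) -> np.ndarray:
        return self.chain.sigma2.mean(axis=0)

    def cluster_table(self) -> pd.DataFrame:
        """Per-cluster features, prior and posterior rare probabilities."""
        f = self.model.features
        df = pd.DataFrame({
            "cluster": np.arange(f.K_init),
            "separation_raw": f.separation_raw,
            "coverage_raw": f.coverage_raw,
            "f1": f.f1,
            "f2": f.f2,
            "prior_prob": f.prior_probabilities(),
            "posterior_prob": self.rare_probabilities,
        })
        df["is_rare"] = df["posterior_prob"] > 0.5
        return df

    def cell_table(self) -> pd.DataFrame:
        """Per-cell final labels after refinement (or raw calls without it)."""
        data = self.model.data
        df = pd.DataFrame({
            "cell_id": data.cell_ids,
            "subject_id": [data.subject_ids[d] for d in data.subject],
            "init_cluster": self.model.init_labels,
        })
        if self.final_labels is not None:
            rare_ids = self.rare_clusters
            lab = [
                str(rare_ids[l]) if l != _em.FILTERED else "FILTERED"
                for l in self.final_labels
            ]
            df["final_rare_label"] = lab
            df["entropy"] = self.entropy
            df["max_omega"] = self.responsibilities.max(axis=1)
        return df

    def summary(self) -> str:
        """Human-readable fit summary."""
        data = self.model.data
        lines = [
            "Rare-cell mixture model results",
            "=" * 47,
            f"cells: {data.N}   subjects: {data.D}   dims: {data.G}",
            f"candidate clusters: {self.model.K_init}   "
            f"abundant clusters: {self.model.abundant.K_a}",
            f"chain: {self.chain.n_iter} iterations "
            f"({self.chain.n_burn} burn-in), seed {self.chain.seed}",
            "",
            self.cluster_table().to_string(
                index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        if self.final_labels is not None:
            n_kept = int((self.final_labels != _em.FILTERED).sum())
            lines += [
                "",
                f"post-hoc EM: {len(self.em_state.loglik) - 1} iterations, "
                f"log-likelihood {self.em_state.loglik[-1]:.4f}",
                f"cells retained in rare clusters: {n_kept} / {data.N} "
                f"({data.N - n_kept} filtered)",
            ]
        elif self.rare_clusters.size == 0:
            lines += ["", "no rare clusters detected; refinement skipped"]
        return "\n".join(lines)

    # -- group inference -----------------------------------------------------
    def compare_groups(
        self,
        groups,
        weights=None,
        B: int = 999,
        seed: int | None = None,
        level: float = 0.05,
        exhaustive: bool | str = "auto",
        adjust: bool = False,
        clusters=None,
    ) -> _inf.GroupInferenceResult:
        """Permutation tests + credible intervals for rare-cluster proportions.

        ``groups`` maps subjects to 'P'/'C' (a dict keyed by subject id, or
        an array in subject order).  ``weights`` defaults to the number of
        candidate cells per subject.  Tests run on the clusters in
        ``clusters`` (default: the detected rare clusters).
        """
        data = self.model.data
        if isinstance(groups, dict):
            groups = np.array([groups[s] for s in data.subject_ids])
        groups = np.asarray(groups)
        if weights is None:
            weights = data.n_d
        design = _inf.GroupDesign(groups, np.asarray(weights, dtype=float),
                                  list(data.subject_ids))
        if clusters is None:
            clusters = self.rare_clusters
        clusters = np.atleast_1d(np.asarray(clusters, dtype=int))
        if clusters.size == 0:
            raise ValueError("no clusters to test")
        pi_hat = self.posterior_mean_pi[:, clusters]
        T = _inf.weighted_group_difference(pi_hat, design)
        p = _inf.permutation_test(pi_hat, design, B=B, seed=seed,
                                  exhaustive=exhaustive)
        ci = {
            j: _inf.credible_interval_difference(self.chain, design, int(k))
            for j, k in enumerate(clusters)
        }
        return _inf.significance_report(T, p, ci, cluster_ids=list(clusters),
                                        level=level, adjust=adjust)
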