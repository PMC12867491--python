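"""Patient-vs-control inference on rare-cluster mixing proportions.

For each rare cluster k the test statistic is the difference of
cell-count-weighted group means of the per-subject posterior mixing
proportions,

    T_k = sum_{d in P} w_d pi~_dk / sum_{d in P} w_d
        - sum_{d in C} w_d pi~_dk / sum_{d in C} w_d,

where pi~_dk is the posterior mean of pi_dk and the weight w_d is the
number of cells of subject d (candidate cells by default).  Significance is
assessed by permuting group labels at the subject level, keeping
{pi~_dk, w_d} fixed, with the two-sided "+1" p-value

    p_k = (1 + #{b : |T_k^(b)| >= |T_k|}) / (B + 1),

so p is never below 1/(B+1).  For small subject counts every distinct
label assignment can be enumerated instead of sampled.  Uncertainty in a
significant difference is summarized by the 2.5%/97.5% empirical quantiles
of the same statistic recomputed at every stored MCMC draw of pi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .gibbs import Chain

__all__ = [
    "GroupDesign",
    "GroupInferenceResult",
    "weighted_group_difference",
    "permutation_test",
    "credible_interval_difference",
    "significance_report",
    "benjamini_hochberg",
]


@dataclass
class GroupDesign:
    """Per-subject group labels ('P'/'C') and positive cell-count weights."""

    group: np.ndarray
    w: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group)
        self.w = np.asarray(self.w, dtype=float)
        if self.group.shape != self.w.shape:
            raise ValueError("group and w must have one entry per subject")
        labels = set(np.unique(self.group).tolist())
        if not labels <= {"P", "C"}:
            raise ValueError(f"group labels must be 'P'/'C', got {sorted(labels)}")
        if (self.w <= 0).any():
            raise ValueError("weights must be positive")
        if not self.subject_ids:
            self.subject_ids = [f"s{d}" for d in range(self.group.shape[0])]

    @property
    def D(self) -> int:
        return self.group.shape[0]

    @property
    def is_patient(self) -> np.ndarray:
        return self.group == "P"

    def require_both_groups(self) -> None:
        if self.is_patient.all() or (~self.is_patient).all():
            raise ValueError("both groups must be non-empty")


def _weighted_diff(pi_hat: np.ndarray, is_patient: np.ndarray, w: np.ndarray):
    """Weighted P-minus-C mean difference; pi_hat is (D,) or (D, K)."""
    wp = w * is_patient
    wc = w * ~is_patient
    return (wp @ pi_hat) / wp.sum() - (wc @ pi_hat) / wc.sum()


def weighted_group_difference(pi_hat: np.ndarray, design: GroupDesign):
    """Observed statistic T_k (scalar for (D,) input, (K,) for (D, K))."""
    design.require_both_groups()
    pi_hat = np.asarray(pi_hat, dtype=float)
    if pi_hat.shape[0] != design.D:
        raise ValueError("pi_hat must have one row per subject")
    out = _weighted_diff(pi_hat, design.is_patient, design.w)
    return float(out) if np.ndim(out) == 0 else out


def _enumerate_assignments(D: int, n_patient: int) -> np.ndarray:
    """All (C(D, n_patient), D) boolean patient-assignment matrices."""
    rows = np.zeros((comb(D, n_patient), D), dtype=bool)
    for r, idx in enumerate(combinations(range(D), n_patient)):
        rows[r, list(idx)] = True
    return rows


def permutation_test(
    pi_hat: np.ndarray,
    design: GroupDesign,
    B: int = 999,
    seed: int | None = None,
    exhaustive: bool | str = "auto",
) -> np.ndarray:
    """Two-sided subject-level permutation p-values via the "+1" rule.

    Random mode draws ``B`` label assignments uniformly (with replacement)
    among those preserving group sizes.  ``exhaustive=True`` (or "auto"
    with at most 2^12 distinct assignments) enumerates every assignment
    once; the observed assignment then plays the role of the "+1" term, so
    p = #{|T(b)| >= |T|} / #assignments exactly.
    """
    design.require_both_groups()
    pi_hat = np.atleast_2d(np.asarray(pi_hat, dtype=float).T).T  # (D, K)
    if pi_hat.shape[0] != design.D:
        raise ValueError("pi_hat must have one row per subject")
    T_obs = np.abs(_weighted_diff(pi_hat, design.is_patient, design.w))
    n_patient = int(design.is_patient.sum())
    n_total = comb(design.D, n_patient)
    if exhaustive == "auto":
        exhaustive = n_total <= 4096
    if exhaustive:
        assign = _enumerate_assignments(design.D, n_patient)
        T_perm = np.abs(np.stack(
            [_weighted_diff(pi_hat, a, design.w) for a in assign]))
        # observed assignment is one of the enumerated rows: exact p-value
        p = (T_perm >= T_obs[None, :] - 1e-12).mean(axis=0)
        return p
    if B < 1:
        raise ValueError("B must be >= 1")
    if seed is None:
        raise ValueError("seed is required for random permutations")
    rng = np.random.default_rng(seed)
    # uniform assignments preserving group sizes: ranks of iid uniforms
    ranks = rng.random((B, design.D)).argsort(axis=1).argsort(axis=1)
    assign = ranks < n_patient                       # (B, D) boolean
    wp = assign * design.w[None, :]
    wc = (~assign) * design.w[None, :]
    T_perm = np.abs((wp @ pi_hat) / wp.sum(axis=1, keepdims=True)
                    - (wc @ pi_hat) / wc.sum(axis=1, keepdims=True))
    count = (T_perm >= T_obs[None, :] - 1e-12).sum(axis=0)
    return (1.0 + count) / (B + 1.0)


def credible_interval_difference(
    chain: Chain, design: GroupDesign, cluster: int,
    levels: tuple[float, float] = (0.025, 0.975),
) -> tuple[float, float]:
    """Credible interval of the weighted group difference for one cluster.

    At every stored MCMC draw the statistic is recomputed from that draw's
    sampled pi_dk; the interval is the pair of empirical quantiles
    (linear interpolation between order statistics).  ``chain`` may also be
    a raw (S, D, K) array of pi draws.
    """
    design.require_both_groups()
    pi_draws = chain.pi if hasattr(chain, "pi") else np.asarray(chain, dtype=float)
    if pi_draws.shape[0] == 0:
        raise ValueError("empty chain")
    draws = pi_draws[:, :, cluster]                  # (S, D)
    T = _weighted_diff(draws.T, design.is_patient, design.w)  # (S,)
    lo, hi = np.quantile(T, levels, method="linear")
    return float(lo), float(hi)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (step-up, monotone)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class GroupInferenceResult:
    """Per-cluster statistic, p-value, credible interval and verdict."""

    table: pd.DataFrame

    def __str__(self) -> str:  # pragma: no cover - formatting convenience
        return self.table.to_string(index=False)


def significance_report(
    T: np.ndarray,
    p: np.ndarray,
    ci: dict[int, tuple[float, float]],
    cluster_ids=None,
    level: float = 0.05,
    adjust: bool = False,
) -> GroupInferenceResult:
    """Assemble the verdict table.

    A cluster is significant when p is strictly below ``level``; its
    direction comes from the credible-interval sign (entirely positive →
    patient-enriched, entirely negative → control-enriched, spanning zero
    → indeterminate).  ``adjust=True`` applies Benjamini–Hochberg before
    thresholding (off by default: the test is run at a per-cluster level).
    """
    T = np.atleast_1d(np.asarray(T, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if cluster_ids is None:
        cluster_ids = list(range(T.size))
    p_used = benjamini_hochberg(p) if adjust else p
    rows = []
    for j, cid in enumerate(cluster_ids):
        significant = p_used[j] < level
        lo, hi = ci.get(j, (np.nan, np.nan))
        if not significant:
            verdict = "ns"
        elif np.isnan(lo) or (lo <= 0.0 <= hi):
            verdict = "indeterminate"
        elif hi < 0.0:
            verdict = "control-enriched"
        else:
            verdict = "patient-enriched"
        rows.append({
            "cluster": cid, "T": T[j], "p": p[j],
            "p_adj": p_used[j] if adjust else np.nan,
            "ci_low": lo, "ci_high": hi, "verdict": verdict,
        })
    return GroupInferenceResult(pd.DataFrame(rows))
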