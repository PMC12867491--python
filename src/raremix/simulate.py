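"""Synthetic multi-subject datasets with planted abundant and rare clusters.

The generator works directly in the embedding (PC) space where the mixture
model lives: each cluster is a diagonal Gaussian, abundant clusters sit on
a dispersed lattice, and rare clusters are planted at a controlled distance
from their nearest abundant cluster with a controlled variance ratio.
Subject-specific mixing proportions are Dirichlet-distributed around target
fractions, rare clusters are present only in a configurable fraction of
subjects (coverage), and an optional two-group design multiplies rare
proportions per group.

Defaults describe a realistic desk-scale cohort: 8 subjects, 10
dimensions, 2 abundant clusters of unit-scale variance, one compact
(variance ratio 0.1) rare cluster at 6 abundant-SD separation, full
coverage, 3% rare fraction and 400–600 cells per subject.

``simulate_candidate_detector`` emulates the precision-limited upstream
rare-cell caller whose output the model refines: it returns all true rare
cells plus a controllable fraction of abundant cells injected as spurious
candidate clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .em import AbundantClusterParams
from .gibbs import MultiSubjectMatrix

__all__ = [
    "GroupSplit",
    "SimulationConfig",
    "SyntheticTruth",
    "CandidateSet",
    "simulate_pc_data",
    "simulate_group_effect",
    "simulate_candidate_detector",
]


@dataclass(frozen=True)
class GroupSplit:
    """Two-group design: first ``n_patients`` subjects are patients.

    Rare-cluster proportions are multiplied by the group's factor before
    renormalization, so (3, 1) plants a threefold patient enrichment and
    (1, 1) an exchangeable null.
    """

    n_patients: int
    patient_multiplier: float = 1.0
    control_multiplier: float = 1.0


@dataclass
class SimulationConfig:
    """Study-condition knobs of the generator (seed is mandatory)."""

    seed: int
    D: int = 8
    G: int = 10
    K_abundant: int = 2
    K_rare: int = 1
    cells_per_subject: tuple[int, int] = (400, 600)
    rare_fraction: float = 0.03
    separation_scale: float = 6.0
    compactness_ratio: float = 0.1
    coverage: float | tuple[float, ...] = 1.0
    group_split: GroupSplit | None = None
    lattice_spacing: float = 10.0
    proportion_concentration: float = 300.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.D < 1 or self.G < 1 or self.K_abundant < 1 or self.K_rare < 0:
            raise ValueError("D, G, K_abundant must be >= 1 and K_rare >= 0")
        lo, hi = self.cells_per_subject
        if not 1 <= lo <= hi:
            raise ValueError("cells_per_subject must be an increasing range >= 1")
        if not 0.0 < self.rare_fraction < 1.0:
            raise ValueError("rare_fraction must lie in (0, 1)")
        if self.K_rare * self.rare_fraction >= 1.0:
            raise ValueError("total rare fraction must stay below 1")
        if self.compactness_ratio <= 0:
            raise ValueError("compactness_ratio must be positive")
        cov = self.coverage_vector()
        if ((cov < 0) | (cov > 1)).any():
            raise ValueError("coverage must lie in [0, 1]")
        if self.group_split is not None and not (
                0 < self.group_split.n_patients < self.D):
            raise ValueError("group_split.n_patients must split D non-trivially")

    def coverage_vector(self) -> np.ndarray:
        cov = np.asarray(self.coverage, dtype=float)
        return np.broadcast_to(np.atleast_1d(cov), (max(self.K_rare, 1),)).copy()


@dataclass
class SyntheticTruth:
    """Ground truth for every latent quantity of a simulated dataset.

    Cluster order: abundant clusters 0..K_abundant-1, then rare clusters.
    ``true_gamma`` is 1 exactly for the planted rare clusters.
    """

    true_Z: np.ndarray
    true_gamma: np.ndarray
    true_pi: np.ndarray
    true_mu: np.ndarray
    true_sigma2: np.ndarray
    subject_groups: np.ndarray
    K_abundant: int
    K_rare: int
    covered_subjects: list[np.ndarray] = field(default_factory=list)
    effect_multipliers: np.ndarray | None = None

    @property
    def rare_cluster_ids(self) -> np.ndarray:
        return np.arange(self.K_abundant, self.K_abundant + self.K_rare)


@dataclass
class CandidateSet:
    """Output of the emulated upstream detector.

    ``indices`` selects candidate cells from the full dataset;
    ``init_labels`` are candidate-cluster labels 0..K_init-1 (planted rare
    clusters first, then spurious clusters); ``true_rare`` marks which
    candidate clusters are genuinely rare.
    """

    indices: np.ndarray
    init_labels: np.ndarray
    true_rare: np.ndarray

    @property
    def K_init(self) -> int:
        return self.true_rare.shape[0]


def _abundant_lattice(K_a: int, G: int, spacing: float) -> np.ndarray:
    """(G, K_a) dispersed means: origin plus spacing * unit vectors."""
    means = np.zeros((G, K_a))
    for k in range(1, K_a):
        axis = (k - 1) % G
        means[axis, k] = spacing * (1 + (k - 1) // G)
    return means


def simulate_group_effect(config: SimulationConfig) -> np.ndarray:
    """Per-subject multiplier applied to rare-cluster proportions."""
    mult = np.ones(config.D)
    if config.group_split is not None:
        gs = config.group_split
        mult[:gs.n_patients] = gs.patient_multiplier
        mult[gs.n_patients:] = gs.control_multiplier
    return mult


def simulate_pc_data(
    config: SimulationConfig,
) -> tuple[MultiSubjectMatrix, AbundantClusterParams, SyntheticTruth]:
    """Draw a full multi-subject dataset with planted rare clusters.

    Construction guarantees: realized coverage equals the configured
    coverage exactly (each covered subject contributes at least one cell to
    the rare cluster, each uncovered subject none), and the same seed gives
    a bit-identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    D, G, K_a, K_r = config.D, config.G, config.K_abundant, config.K_rare
    K = K_a + K_r
    lo, hi = config.cells_per_subject
    cov = config.coverage_vector()[:K_r] if K_r else np.empty(0)
    if K_r and (config.rare_fraction * lo < 1.0) and (cov > 0).any():
        raise ValueError(
            "infeasible config: rare_fraction x cells_per_subject < 1 in a "
            "covered subject"
        )

    ab_var = rng.uniform(0.8, 1.25, size=(G, K_a))
    ab_means = _abundant_lattice(K_a, G, config.lattice_spacing)

    mu = np.zeros((G, K))
    sigma2 = np.zeros((G, K))
    mu[:, :K_a] = ab_means
    sigma2[:, :K_a] = ab_var
    anchors = np.arange(K_r) % K_a if K_r else np.empty(0, dtype=int)
    for j in range(K_r):
        a = anchors[j]
        direction = rng.standard_normal(G)
        direction /= np.linalg.norm(direction)
        sd = float(np.sqrt(ab_var[:, a].mean()))
        mu[:, K_a + j] = ab_means[:, a] + config.separation_scale * sd * direction
        sigma2[:, K_a + j] = config.compactness_ratio * ab_var[:, a]

    # subjects containing each rare cluster, chosen uniformly given the seed
    covered: list[np.ndarray] = []
    for j in range(K_r):
        m = int(round(cov[j] * D))
        covered.append(np.sort(rng.choice(D, size=m, replace=False)))

    # target composition and per-subject Dirichlet proportions
    target = np.empty(K)
    rare_total = config.rare_fraction * K_r
    ab_share = rng.dirichlet(np.full(K_a, 5.0))
    target[:K_a] = (1.0 - rare_total) * ab_share
    target[K_a:] = config.rare_fraction
    pi = rng.dirichlet(config.proportion_concentration * target, size=D)

    effect = simulate_group_effect(config)
    for j in range(K_r):
        col = K_a + j
        pi[:, col] *= effect
        absent = np.setdiff1d(np.arange(D), covered[j])
        pi[absent, col] = 0.0
    pi /= pi.sum(axis=1, keepdims=True)

    groups = np.array(["C"] * D, dtype=object)
    if config.group_split is not None:
        groups[: config.group_split.n_patients] = "P"

    X_parts, subj_parts, Z_parts = [], [], []
    for d in range(D):
        n_d = int(rng.integers(lo, hi + 1))
        counts = rng.multinomial(n_d, pi[d])
        # construction guarantee: covered subjects keep >= 1 rare cell
        for j in range(K_r):
            col = K_a + j
            if d in covered[j] and counts[col] == 0:
                donor = int(np.argmax(counts[:K_a]))
                counts[donor] -= 1
                counts[col] += 1
        Z_d = np.repeat(np.arange(K), counts)
        rng.shuffle(Z_d)
        X_d = mu[:, Z_d].T + np.sqrt(sigma2[:, Z_d]).T * rng.standard_normal(
            (Z_d.size, G))
        X_parts.append(X_d)
        subj_parts.append(np.full(Z_d.size, d, dtype=int))
        Z_parts.append(Z_d)

    data = MultiSubjectMatrix(
        np.vstack(X_parts), np.concatenate(subj_parts),
        [f"s{d}" for d in range(D)],
    )
    truth = SyntheticTruth(
        true_Z=np.concatenate(Z_parts),
        true_gamma=np.concatenate([np.zeros(K_a, int), np.ones(K_r, int)]),
        true_pi=pi,
        true_mu=mu,
        true_sigma2=sigma2,
        subject_groups=groups,
        K_abundant=K_a,
        K_rare=K_r,
        covered_subjects=covered,
        effect_multipliers=effect,
    )
    abundant = AbundantClusterParams(ab_means, ab_var)
    return data, abundant, truth


def simulate_candidate_detector(
    truth: SyntheticTruth,
    noise_rate: float,
    seed: int,
    n_spurious: int = 1,
) -> CandidateSet:
    """Emulate a precision-limited upstream rare-cell detector.

    Candidates are all true rare cells (labeled by their planted cluster)
    plus ``round(noise_rate * n_rare)`` abundant cells injected as
    ``n_spurious`` spurious candidate clusters.  Each spurious cluster
    draws its cells from a single abundant cluster (cycling through them),
    so spurious clusters are diffuse and sit on top of an abundant
    population — the false-positive pattern the model is meant to reject.
    """
    if not 0.0 <= noise_rate < 1e6:
        raise ValueError("noise_rate must be non-negative")
    rng = np.random.default_rng(seed)
    rare_ids = truth.rare_cluster_ids
    rare_mask = np.isin(truth.true_Z, rare_ids)
    rare_idx = np.flatnonzero(rare_mask)
    n_rare = rare_idx.size
    # planted clusters first, labeled 0..K_rare-1
    remap = {int(c): j for j, c in enumerate(rare_ids)}
    labels = [np.array([remap[int(z)] for z in truth.true_Z[rare_idx]], int)]
    indices = [rare_idx]
    n_false = int(round(noise_rate * n_rare))
    K_r = truth.K_rare
    if n_false > 0:
        if n_spurious < 1:
            raise ValueError("n_spurious must be >= 1 when injecting noise")
        per = np.full(n_spurious, n_false // n_spurious)
        per[: n_false % n_spurious] += 1
        for s in range(n_spurious):
            if per[s] == 0:
                continue
            source = s % truth.K_abundant
            pool = np.flatnonzero(truth.true_Z == source)
            take = rng.choice(pool, size=min(per[s], pool.size), replace=False)
            indices.append(np.sort(take))
            labels.append(np.full(take.size, K_r + s, dtype=int))
        K_init = K_r + n_spurious
    else:
        K_init = K_r
    true_rare = np.concatenate([np.ones(K_r, int),
                                np.zeros(K_init - K_r, int)])
    return CandidateSet(np.concatenate(indices), np.concatenate(labels),
                        true_rare)
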