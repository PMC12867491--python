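# Methods

## Problem and model

Rare cell populations (operationally, below ~1–1.5% of cells) carry
disproportionate biological signal in scRNA-seq cohorts, but single-dataset
rare-cell detectors cannot pool evidence across subjects and consequently
admit many false positives. `raremix` refines the output of any upstream
candidate detector by jointly reclustering the candidate cells of all
subjects under a hierarchical Bayesian mixture and deciding, per candidate
cluster, whether it behaves like a genuine rare population.

Candidate cells live in a G-dimensional embedding (by default the leading
50 principal components of log-transformed counts). For subject
d = 1..D, cell i, dimension g, and candidate cluster k = 1..K_init:

    X_dgi | Z_di = k          ~  N(mu_gk, sigma2_gk)
    P(Z_di = k)               =  pi_dk
    (pi_d1, ..., pi_dK_init)  ~  Dirichlet(alpha_1, ..., alpha_K_init)
    mu_gk                     ~  N(eta_g, tau_mu2_g)
    sigma2_gk | gamma_k = 1   ~  Inv-Gamma(nu1, tau_sigma)
    sigma2_gk | gamma_k = 0   ~  Inv-Gamma(nu0, tau_sigma)
    P(gamma_k = 1)            =  1 / (1 + exp{-(b0 + b1' f_k)})

Cluster parameters (mu, sigma2) are shared across subjects; only the
mixing proportions pi_dk are subject-specific. The effective sample size
for learning a cluster is therefore the pooled count n_k = sum_d n_dk,
which is what stabilizes estimation for populations that are tiny within
any one subject.

The latent indicator gamma_k encodes the three hallmarks of a true rare
population:

* **compactness** — with nu1 > nu0, the gamma_k = 1 branch of the
  inverse-gamma prior concentrates per-dimension variances near
  tau_sigma / nu1; a diffuse cluster is better explained by the nu0 branch;
* **separation** — feature f_k^1, the minimum Euclidean distance from the
  cluster's mean to any abundant-cluster mean;
* **coverage** — feature f_k^2, the fraction of subjects in which the
  cluster has at least one cell.

Both features are min–max standardized to [0, 1] across the candidate
clusters and enter the logistic prior with fixed coefficients b0 = -1,
b1 = (1, 1), calibrated so that f = (0.5, 0.5) gives prior probability
exactly 0.5 and both features contribute equally. Features are computed
once from the *initial* candidate-cluster means and frozen for the entire
run: a prior that tracked the sampled means would not define a coherent
posterior. Clusters with posterior P(gamma_k = 1 | data) strictly greater
than 0.5 are called rare.

## Posterior computation

All priors are conditionally conjugate, so posterior inference is a
systematic-scan Gibbs sampler (Z → pi → mu → sigma2 → gamma per
iteration) with closed-form full conditionals:

* Z_di — categorical with mass ∝ pi_dk · prod_g N(X_dgi | mu_gk,
  sigma2_gk), computed in log space with row-wise max subtraction and
  inverse-CDF sampling;
* pi_d· — Dirichlet(alpha + n_d·) per subject;
* mu_gk — normal with variance (1/tau_mu2 + n_k/sigma2_gk)^-1 and the
  matching precision-weighted mean (the prior itself when n_k = 0);
* sigma2_gk — Inv-Gamma(nu_gamma_k + n_k/2, tau_sigma + RSS_gk/2), in the
  shape–scale parameterization with density ∝ x^-(nu+1) e^(-tau/x);
* gamma_k — Bernoulli with log-odds logit(prior_k) + sum_g
  [log InvGa(sigma2_gk; nu1, tau_sigma) − log InvGa(sigma2_gk; nu0,
  tau_sigma)].

Empty clusters are retained (their conditionals are proper priors) and are
never called rare unless the gamma chain says so. Labels are anchored to
the initial candidate clusters; no relabeling is performed, so gamma_k
indexes the k-th initial cluster throughout.

The sampler's joint correctness is validated by a Geweke-style
successive-conditional test (one Gibbs scan alternated with re-simulating
the data must leave the prior marginal of (mu, sigma2, gamma) invariant);
sigma2 moments are compared on the log scale because the nu0 = 2 branch
has no finite variance.

### Default hyperparameters

| parameter | default | units / meaning |
|---|---|---|
| alpha_k | 1 | symmetric Dirichlet concentration |
| eta_g | per-dimension grand mean of candidate cells | embedding units |
| tau_mu2_g | per-dimension empirical variance | embedding units² |
| nu0 | 2 | variance-prior shape, non-rare branch |
| nu1 | 10 | variance-prior shape, rare (compact) branch |
| tau_sigma | 1 | variance-prior scale (both branches) |
| n_iter / n_burn | 5000 / 2500 | chain length / burn-in |
| seed | required | no silent default |

eta and tau_mu2 are empirical-Bayes choices; one eta per dimension
generalizes a scalar prior mean, which matters because PC scores have very
different scales per dimension. nu0/nu1/tau_sigma set the *absolute*
variance scale that counts as compact (the nu1 branch favors sigma2 ≈
tau_sigma/nu1 = 0.1): if the embedding is rescaled, tau_sigma should be
rescaled with it. Sensitivity to nu0/nu1 is the main tuning axis and is
deliberately exposed rather than absorbed; rare calls are robust when the
rare-to-abundant variance ratio is well below (nu0/nu1), and degrade as it
approaches 1.

## Post-hoc EM refinement

Rare calls are cleaned at the cell level by embedding the K_rare detected
clusters in a mixture with the K_a abundant clusters (K_all = K_rare +
K_a). Abundant means/variances are estimated from the full dataset and
held fixed in the M-step; rare components and all mixing proportions are
re-estimated by EM from an initialization at the MCMC posterior means, with
per-subject abundant mass fixed at 0.1 split equally over the K_a abundant
components (the candidate set is pre-depleted of abundant cells, and no
per-cluster size information is assumed). Because only a subset of
parameters is maximized, this is a generalized EM and the observed-data
log-likelihood is still non-decreasing; the implementation asserts this
every iteration (slack 1e-8 relative) and stops when the relative change
drops below 1e-6 or after 200 iterations. A variance floor of 1e-8
prevents singleton collapse; a rare component receiving zero total
responsibility is frozen for that iteration with a warning.

Each cell's final responsibility row is scored by Shannon entropy (natural
log, 0·log 0 = 0). Cells with entropy above log(K_all)/10^3 — i.e. cells
without an essentially one-hot assignment — are removed, as are cells
whose largest responsibility falls on an abundant component. Filtered
cells are dropped from the rare calls and reported, not reassigned.

## Group-level inference

For each rare cluster, the patient-vs-control statistic is the difference
of cell-count-weighted group means of posterior-mean proportions,
T_k = sum_{d in P} w_d pi~_dk / sum w_d − (same over C), with weights
w_d = number of candidate cells of subject d by default (total cells per
subject can be supplied instead). Significance comes from subject-level
label permutations keeping {pi~_dk, w_d} fixed, two-sided, with the "+1"
rule p = (1 + #{|T(b)| ≥ |T|}) / (B + 1), B = 999 by default; for small D
every size-preserving assignment is enumerated and the p-value is exact.
pi~_dk is the posterior mean over post-burn-in draws (mean rather than
median, so the statistic is linear in the draws). Uncertainty is
summarized by the 2.5%/97.5% empirical quantiles (linear interpolation
between order statistics) of the same statistic recomputed at every stored
draw of pi. No multiple-testing correction is applied by default (the
test is run at a per-cluster level); Benjamini–Hochberg is available as an
option.

## Preprocessing

From raw counts: drop genes expressed in fewer than 5 cells (inclusive
boundary: a gene in exactly 5 cells is kept), natural log(1 + x), keep the
top 1000 genes by variance of the logged values (ties broken by input
order), PCA on the centered (unscaled) matrix to 50 components with a
deterministic sign convention (largest-magnitude loading positive).
**No per-cell library-size normalization is performed** — inputs are
expected to be raw or upstream-normalized counts; if library sizes vary
strongly, normalize before calling the pipeline.

## Synthetic data

The generator emulates the study conditions directly in PC space:
diagonal Gaussians (matching the model's per-dimension variance
assumption), abundant clusters on a lattice 10 SD apart with per-dimension
variances jittered in [0.8, 1.25], rare clusters planted at
`separation_scale` (default 6) abundant-SDs from their anchor with
variance `compactness_ratio` (default 0.1) times the anchor's, Dirichlet
subject proportions around a 3% rare fraction, and exact coverage (the
chosen covered subjects always contribute ≥ 1 rare cell, the rest none).
A two-group design multiplies rare proportions per group before
renormalization. The emulated candidate detector returns all true rare
cells plus `round(noise_rate · n_rare)` abundant cells as diffuse spurious
candidate clusters, each drawn from a single abundant cluster.

What the generator does **not** emulate: count-level noise (negative
binomial sampling, dropout), batch effects, non-Gaussian cluster shapes,
correlated dimensions, or detector errors other than whole-cluster false
positives. Passing tests therefore demonstrate correctness of the
inferential machinery under the model's own assumptions, not robustness to
real-data violations of them.

## Problem sizes and numerical choices

Validation runs use desk-scale instances chosen to make the statistical
checks sharp while keeping the suite fast: recovery runs use the default
8-subject, ~4000-cell datasets with 400-iteration chains across 10 seeds;
the joint-distribution check uses a 2-cluster, G = 2, 30-cell instance
with 3000 forward draws against a 30 000-scan successive-conditional chain
thinned by 10 (batch-means standard errors, 4-SE criterion); conjugate
full conditionals are checked against closed-form moments at 10^5 draws
(3-SE criterion); permutation type-I error uses 500 null replicates at
B = 999. Chains are deterministic given the seed; categorical draws use
inverse-CDF sampling on max-subtracted normalized exponentials, and all
density computations are in log space.

## Known limitations

* The compactness scale is absolute (tau_sigma), not adaptive to the
  embedding scale; standardized embeddings or an explicit tau_sigma are
  advised.
* Features are frozen at initialization; badly misplaced initial cluster
  means propagate into the prior.
* K_init is fixed by the upstream detector — no transdimensional moves.
* The EM never updates abundant parameters and never reassigns filtered
  cells to abundant clusters; it only prunes rare calls.
* Exchangeability across subjects is assumed by the permutation test;
  strong covariate structure between groups would violate it.
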