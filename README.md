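# raremix

Population-level rare cell type detection in multi-subject scRNA-seq data.

Rare cell populations — below roughly 1% of cells — carry outsized
biological signal (circulating tumor cells, unconventional immune
subsets), but any single subject contains too few of them for reliable
detection, and single-dataset detectors applied to pooled cohorts produce
many false positives. `raremix` takes the *candidate* rare cells proposed
by any upstream detector and re-evaluates them jointly across subjects
with a hierarchical Bayesian mixture model, keeping only candidate
clusters that look like genuine rare populations and only cells that
unambiguously belong to them.

## The model in brief

For subject d, cell i, embedding dimension g, and candidate cluster k:

    X_dgi | Z_di = k         ~  N(mu_gk, sigma2_gk)
    P(Z_di = k)              =  pi_dk,   (pi_d·) ~ Dirichlet(alpha)
    mu_gk                    ~  N(eta_g, tau_mu2_g)
    sigma2_gk | gamma_k = 1  ~  Inv-Gamma(nu1, tau_sigma)   (nu1 > nu0)
    sigma2_gk | gamma_k = 0  ~  Inv-Gamma(nu0, tau_sigma)
    P(gamma_k = 1)           =  expit(b0 + b1' f_k),  b0 = -1, b1 = (1, 1)

Cluster parameters are shared across subjects (pooled evidence); mixing
proportions pi_dk are subject-specific. The indicator gamma_k encodes the
three hallmarks of a true rare population: **compactness** (the nu1
variance branch favors tight clusters), **separation** (f_k^1 = minimum
distance from the cluster mean to any abundant-cluster mean) and
**coverage** (f_k^2 = fraction of subjects containing the cluster).
Inference is a conjugate Gibbs sampler; clusters with posterior
P(gamma_k = 1 | data) > 0.5 are called rare. A post-hoc EM against the
fixed abundant clusters then removes individual cells whose assignment
entropy exceeds log(K_all)/10^3 or whose best component is abundant, and
a subject-level permutation test on cell-count-weighted proportions
compares patients with controls. See `docs/methods.md` for the full
account.

## Worked example

Simulate a 10-subject cohort (5 patients, 5 controls) with one planted
compact, well-separated rare cluster enriched threefold in patients, let
the emulated upstream detector add an equal number of spurious candidates
from an abundant cluster, and fit:

```python
from raremix import RareCellMixtureModel, SimulationConfig, GroupSplit
from raremix.simulate import simulate_pc_data, simulate_candidate_detector

cfg = SimulationConfig(seed=3, D=10, group_split=GroupSplit(5, 3.0, 1.0))
data, abundant, truth = simulate_pc_data(cfg)
cand = simulate_candidate_detector(truth, noise_rate=1.0, seed=4)

model = RareCellMixtureModel(data.subset(cand.indices), cand.init_labels, abundant)
res = model.fit(n_iter=2000, n_burn=1000, seed=7)
print(res.summary())
```

```
Rare-cell mixture model results
===============================================
cells: 708   subjects: 10   dims: 10
candidate clusters: 2   abundant clusters: 2
chain: 2000 iterations (1000 burn-in), seed 7

 cluster  separation_raw  coverage_raw     f1     f2  prior_prob  posterior_prob  is_rare
       0          6.0200        1.0000 1.0000 0.5000      0.6225          1.0000     True
       1          0.1857        1.0000 0.0000 0.5000      0.3775          0.0000    False

post-hoc EM: 2 iterations, log-likelihood -6349.4535
cells retained in rare clusters: 354 / 708 (354 filtered)
```

The planted cluster (separation 6.0 abundant-SDs, present in all
subjects) gets posterior rare probability 1.0; the spurious candidate
cluster, sitting on top of an abundant population (separation 0.19), gets
0.0 and is rejected. The EM + entropy filter then keeps exactly the 354
genuine candidates and filters the 354 injected abundant cells. Group
inference recovers the planted patient enrichment:

```python
groups = dict(zip(data.subject_ids, truth.subject_groups))
print(res.compare_groups(groups, seed=7).table.to_string(index=False))
```

```
 cluster        T        p  p_adj   ci_low  ci_high          verdict
       0 0.298967 0.007937    NaN 0.230815  0.36896 patient-enriched
```

T is the cell-count-weighted patient-minus-control difference in the
cluster's mixing proportion; p is the exact subject-level permutation
p-value, and the 95% credible interval (0.23, 0.37) excludes zero.

The same pipeline is available from the shell:

```bash
raremix simulate --seed 3 --noise-rate 1.0 --out sim/
raremix fit --data sim/candidates.csv --meta sim/candidates_meta.tsv \
            --abundant sim/abundant_params.csv --seed 7 --out fit/
raremix infer --fit-dir fit/ --subjects sim/subjects.tsv --seed 7 --out infer.tsv
raremix preprocess --counts-csv counts.csv --out pcs.csv   # raw counts -> 50 PCs
```

## Layout

- `raremix.preprocessing` — counts → gene filter → log1p → HVG → PCA
- `raremix.features` — separation/coverage features, logistic prior
- `raremix.gibbs` — the hierarchical mixture and its Gibbs sampler
- `raremix.em` — post-hoc EM refinement and entropy filtering
- `raremix.inference` — permutation tests and credible intervals
- `raremix.simulate` — synthetic cohorts with planted rare clusters
- `raremix.model` — `RareCellMixtureModel` / `RareCellResults` front end
- `raremix.cli` — `raremix` command-line pipeline
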