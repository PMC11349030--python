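# bilingam

Joint estimation of multiple related directed acyclic graphs (DAGs) from
non-Gaussian data, with association-network priors.

## The problem

Directed functional connectivity studies — and many other multi-group
systems-biology settings — need to estimate a *directed* network per group
(e.g., per developmental stage) from data matrices whose rows are subjects
and whose columns are variables (regions of interest). Linear non-Gaussian
acyclic models (LiNGAM) can orient edges because non-Gaussian errors make
the causal order identifiable, but plain LiNGAM estimators degrade badly
when the per-group sample size `n` is small relative to the number of
variables `p`, and they ignore the fact that the groups' networks are
related.

`bilingam` addresses both issues by using *undirected association networks*
as a prior that restricts the DAG search space, and by estimating those
association networks jointly across groups so that shared structure
reinforces itself:

1. **Gaussianize** each group's data with the nonparanormal (Winsorized
   ECDF → normal quantile) transform.
2. **Distinct association networks** `E^d,k` per group via ψ-learning:
   partial correlations with correlation-screened reduced conditioning
   sets, tested with Fisher's z and Benjamini–Hochberg FDR control.
3. **Joint association networks** `E^c,k`: per-edge Fisher z-scores are
   combined across groups by a √n-weighted Stouffer meta-analysis; each
   group's evidence is coupled to the meta signal (coupling weight λ,
   default 1, renormalized to unit null variance) and re-tested.
4. **Prior matrix** `A^prior,k` over {0, −1}: −1 (edge status unknown)
   wherever the pair is in `E^d,k ∪ E^c,k`, 0 (both orientations excluded)
   elsewhere.
5. **Constrained DirectLiNGAM**: the causal order π^k is found by
   repeatedly extracting the most exogenous remaining variable under the
   pairwise maximum-entropy likelihood-ratio measure, skipping pairs the
   prior excludes; edge weights solve sparse regressions of each variable
   on its prior-permitted predecessors (adaptive lasso/BIC by default,
   restricted OLS optionally).

The model per group is the linear structural equation model
`X = Bᵀ X + ε` with independent non-Gaussian errors `ε`; `B` is the
weighted adjacency (`b_ij ≠ 0` ⇔ edge `i → j`) and acyclicity means some
permutation of `B` is strictly lower triangular.

The package also ships the matching simulator (random DAG families with
5 % edge turnover between groups and centered χ²(1) noise), evaluation
metrics (TPR, FDR, structural Hamming distance, Jaccard similarity), and a
network-analysis layer: degree-based hub detection (≥ mean + 2 sd),
module-wise edge flows with hypergeometric enrichment tests,
common/distinctive pattern extraction, and subsampling robustness curves.

## Worked example

```python
import numpy as np
from bilingam import (SimulationConfig, generate_study, bilingam,
                      confusion_counts, tpr_fdr, shd, detect_hubs)

cfg = SimulationConfig(K=3, p=40, N=600, d=1.0, seed=1)
truth, X_groups = generate_study(cfg)          # three related DAGs, n=200 rows each
res = bilingam(X_groups)                       # joint priors + constrained DirectLiNGAM

for k, (B_true, B_hat) in enumerate(zip(truth.B_list, res.B_list), start=1):
    c = confusion_counts(B_true, B_hat)
    tpr, fdr = tpr_fdr(c)
    print(f"group {k}: TPR={tpr:.3f}  FDR={fdr:.3f}  SHD={shd(B_true, B_hat)}")

hubs = detect_hubs(res.B_list[0], mode="out")
print("out-hubs in group 1:", hubs.hubs.tolist(), f"(threshold {hubs.threshold:.2f})")
```

prints

```
group 1: TPR=1.000  FDR=0.000  SHD=0
group 2: TPR=1.000  FDR=0.000  SHD=0
group 3: TPR=1.000  FDR=0.048  SHD=1
out-hubs in group 1: [22, 29] (threshold 1.84)
```

i.e. at `n = 200 > p = 40` the pipeline recovers essentially the whole
directed structure of each group (one false edge in group 3), and two
nodes in group 1 send out significantly more edges than average.

The same pipeline is available from the shell:

```sh
bilingam simulate --K 3 --p 40 --N 600 --d 1 --seed 1 --out-dir sim/
bilingam fit --groups sim/data_group1.csv sim/data_group2.csv sim/data_group3.csv --out-dir fit/
bilingam metrics --true sim/truth_B1.csv --est fit/B1.csv
bilingam analyze --graphs fit/B*.csv --modules modules.csv --out-dir analysis/
bilingam benchmark --K 3 --p 40 --N 600 --d 1 2 --reps 10 --out-dir bench/
```

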