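# kfcmiss

Adaptive kernel fuzzy c-means clustering for incomplete data.

Real-world tabular data — clinical measurements, assay panels, survey
responses — routinely arrive with missing cells, while most clustering
algorithms require a complete matrix. `kfcmiss` implements fuzzy c-means
under *kernelization of the metric* with per-cluster adaptive variable
weights, together with three principled ways to cluster data whose cells
are missing completely at random (MCAR), for analysts who want soft cluster
assignments, per-cluster variable relevance, and imputations that respect
the cluster structure.

## The model

Observations $x_i \in \mathbb{R}^p$ are compared to prototypes
$v_k \in \mathbb{R}^p$ (kept in the original data space) through one
Gaussian kernel per variable,
$K_j(x, v) = \exp\{-(x - v)^2 / 2\sigma_j^2\}$, so the feature-space
squared distance per variable is $2(1 - K_j)$. The algorithm minimizes

$$
J \;=\; 2\sum_{k=1}^{K}\sum_{i=1}^{n} u_{ki}^{m}
        \sum_{j=1}^{p} \lambda_{kj}\,\bigl(1 - K_j(x_{ij}, v_{kj})\bigr),
$$

subject to $\sum_k u_{ki} = 1$ (fuzzy memberships, fuzzifier $m > 1$) and
$\prod_j \lambda_{kj} = 1$ per cluster (adaptive variable weights:
$\lambda_{kj} > 1$ marks variable $j$ as locally discriminative for cluster
$k$). Coordinate descent alternates a fixed-point prototype update, a
closed-form geometric-mean weight update, and a closed-form membership
update; many random restarts are run and the best final $J$ wins.

Missing cells are handled by one of:

- **WDS** (whole-data): fit on complete rows, then assign each incomplete
  row to the nearest prototype under the *partial distance*
  $\varphi^2_{dp} = (p / I_i)\sum_{j\,\text{obs}} \lambda_{kj}\,2(1-K_j)$,
  where $I_i$ counts the row's observed variables;
- **PDS** (partial-distance): every update sums over observed cells only;
- **OCS** (optimal completion): missing cells become optimization
  variables, re-imputed each iteration as membership-weighted prototype
  averages — the fit returns a completed matrix;
- **mean / median**: central-imputation baselines.

Results are scored with the corrected Rand index, the class-weighted
F-measure, the overall error rate of classification (OERC) after an optimal
cluster-to-class assignment, and a consistency statistic
$d_k(j)$ comparing per-cluster moments before vs after imputation.

## Worked example

```python
import kfcmiss as kf

X, y = kf.generate_mixture(kf.iris_like_spec(seed=1))     # 150 x 4, 3 clusters
mask = kf.generate_mcar_mask(*X.shape, kf.MissingConfig(theta=0.10, seed=1))
ds = kf.apply_mask(X, mask, labels=y)                      # ~10% cells -> NaN

est = kf.AdaptiveKernelFuzzyCMeans(
    n_clusters=3, missing_strategy="ocs", n_init=20, random_state=42,
).fit(ds.values)

cm = kf.confusion_matrix(est.labels_, y)
print(kf.corrected_rand(cm), kf.oerc(cm))
rep = kf.consistency(ds, est.completed_X_, est.labels_)
print(rep.max)
```

Output:

```
missing fraction: 0.095
objective J = 29.7913 after 25 iterations
CR = 1.0000  FM = 1.0000  OERC = 0.0000
max consistency d_k(j) = 0.0139
```

The three generating components are recovered exactly despite ~10% of the
cells being missing (corrected Rand 1.0, zero error rate), and the
OCS-imputed values stay on each variable's original scale (all consistency
statistics below 0.014). The fitted `feature_weights_` show the last two
variables carrying weights 2.8–5.3 versus 0.1–0.7 for the first two: the
algorithm identifies them as the discriminative variables, mirroring how
petal measurements dominate the classic Iris benchmark.

The same workflow is available from the shell:

```sh
kfcmiss gen-synthetic --preset iris-like --seed 1 --out complete.csv
kfcmiss gen-missing --theta 0.10 --seed 1 --label-column label \
        --out masked.csv complete.csv
kfcmiss fit --strategy ocs --k 3 --starts 20 --seed 42 \
        --label-column label --outdir run/ masked.csv
kfcmiss benchmark --preset iris-like --k 3 --starts 20 --seed 1 --outdir bench/
```

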