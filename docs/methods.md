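# Methods

## Model and objective

The clusterer is fuzzy c-means under *kernelization of the metric*:
prototypes $v_k$ live in the original data space and only distances pass
through kernels. Each variable $j$ gets its own Gaussian kernel
$K_j(x,v) = \exp\{-(x-v)^2/2\sigma_j^2\}$; since $K_j(x,x) = 1$, the
feature-space squared distance contributed by variable $j$ is
$2\,(1 - K_j(x_{ij}, v_{kj})) \in [0, 2)$. A per-cluster weight vector
$\lambda_k > 0$ with $\prod_j \lambda_{kj} = 1$ expresses local variable
relevance, giving the criterion

$$
J = \sum_{k=1}^{K}\sum_{i=1}^{n} u_{ki}^m\,
    \varphi^2_{\lambda_k}(x_i, v_k),
\qquad
\varphi^2_{\lambda_k}(x_i, v_k) = \sum_{j=1}^p \lambda_{kj}\,
    2\bigl(1 - K_j(x_{ij}, v_{kj})\bigr),
$$

minimized over memberships $U$ (columns on the simplex), prototypes $V$ and
weights $\Lambda$ by coordinate descent:

1. **Prototype step** — the stationary condition gives a fixed-point map,
   the kernel-weighted mean
   $v_{kj} \leftarrow \sum_i u_{ki}^m K_j(x_{ij}, v_{kj})\,x_{ij} \big/
   \sum_i u_{ki}^m K_j(x_{ij}, v_{kj})$, evaluated at the previous
   prototype. One sweep per outer iteration by default
   (`inner_prototype_steps`); the map is a heuristic step toward the
   stationary point, so this step alone is *not* guaranteed monotone in J.
2. **Weight step** — with dispersions
   $S_{kj} = \sum_i u_{ki}^m\, 2(1 - K_j)$, the product-one-constrained
   minimizer is $\lambda_{kj} = (\prod_l S_{kl})^{1/p} / S_{kj}$, computed
   in log space. This step never increases J.
3. **Membership step** — the simplex-constrained minimizer
   $u_{ki} = [\sum_h (\varphi^2_{ki} / \varphi^2_{hi})^{1/(m-1)}]^{-1}$,
   computed via log-weights for stability. Never increases J.

Iteration stops when $|J^{(t+1)} - J^{(t)}| \le \varepsilon$ or after $T$
iterations. Because random initialization makes the descent land in local
minima, the fit runs `n_init` independent restarts (seeded by spawning from
one master seed) and keeps the smallest final J.

An unweighted baseline (`KernelFuzzyCMeans`) uses a single full-vector
Gaussian kernel with a scalar bandwidth and the same loop without the
weight step.

## Bandwidths

The per-variable bandwidth parameter $2\sigma_j^2$ is estimated once, before
fitting, as the average of the 0.1 and 0.9 quantiles of the squared
differences $(x_{ij} - x_{kj})^2$ over all unordered pairs of observed
entries of variable $j$ (linear-interpolation quantiles; the convention is
configurable). The whole-data strategy estimates bandwidths from complete
rows only, since it is a complete-case analysis; the partial-distance and
optimal-completion strategies use all observed pairs. Bandwidths are held
fixed throughout a fit — in particular they are *not* re-estimated from
OCS-imputed values between iterations, so the objective the completion
optimizes is stationary. A constant column makes the bandwidth zero and is
rejected at construction time (every variable must have at least two
observed values).

## Missing-data strategies

Missingness is represented by an indicator $I_{ij}$ (1 = observed) with
$I_i = \sum_j I_{ij}$ observed variables per row.

**Whole-data (WDS).** Fit on the complete rows only, then assign each
incomplete row crisply to $\arg\min_k$ of the partial distance
$\varphi^2_{dp}(x_i, v_k) = (p/I_i)\sum_j \lambda_{kj} 2(1-K_j)\,I_{ij}$;
fuzzy memberships for those rows are also computed from the partial
distances for reporting. A complete-case analysis is only advisable at low
missingness, so fits above a 25% missing fraction emit a warning (they do
not fail). At least K complete rows are required.

**Partial-distance (PDS).** The same coordinate descent with all sums
restricted to observed cells. Convergence is monitored on the rescaled
objective $J_{pd} = \sum_{k,i} u_{ki}^m (p/I_i)\,\varphi^2_{ki}$, while the
$p/I_i$ factor is omitted inside the membership ratios, where it cancels
row-wise. Two consequences worth stating plainly:

- the membership step minimizes both the scaled and unscaled criteria (the
  factor is constant within each row's simplex problem);
- the weight update, as defined, omits the row rescale from its
  dispersions, so it is the exact conditional minimizer of the *unscaled*
  masked criterion, not of $J_{pd}$. The per-iteration monotonicity
  diagnostics therefore track the unscaled criterion; overall convergence
  is still measured on $J_{pd}$.

A cluster-variable dispersion that underflows (all relevant cells masked)
is floored rather than allowed to produce infinite weights.

**Optimal completion (OCS).** Missing cells are auxiliary variables.
They are initialized uniformly over each variable's observed range
(seeded), and after each membership update every missing cell is replaced
by the membership-weighted prototype average
$x_{ij} \leftarrow \sum_k u_{ki}^m v_{kj} / \sum_k u_{ki}^m$ — a convex
combination of prototype coordinates, hence always inside their hull. This
update is the exact stationary point of the *Euclidean* weighted criterion
in $x_{ij}$; under the kernelized criterion it is the classical surrogate
step, adopted as defined. Convergence is measured on the completed-data
objective.

With no missing cells all three strategies reduce *exactly* (bit-for-bit,
not just approximately) to the base fit: indicator multiplications by 1.0,
rescales by $p/p$, and empty imputation sets are floating-point no-ops, and
the test suite pins this down.

**Central imputation baselines.** Mean or median per variable over observed
values, then the plain fit. Mean filling preserves each variable's mean
exactly and median filling never leaves the observed range, but both shrink
dispersion — the comparison the consistency diagnostics are built to expose.

## MCAR generator

Each cell of an $n \times p$ grid is masked independently with probability
$\theta$ (Bernoulli, independent of the data — the MCAR mechanism), from a
seeded PCG64 generator, so masks are bit-reproducible. A row guard (default
on) resamples any fully-masked row from the same stream: partial distances
and nearest-prototype assignment are undefined for empty rows, and no
update equation covers them. Raw i.i.d. masking is available by disabling
the guard. MAR/NMAR mechanisms and structured missingness patterns are out
of scope.

## Evaluation

- **Corrected Rand** — the adjusted-for-chance Rand index in its
  pair-counting (Hubert–Arabie) form, computed from the cluster-vs-class
  contingency table; cross-checked in the tests against both brute-force
  pair enumeration and scikit-learn.
- **F-measure** — class-weighted best-match form:
  $\mathrm{FM} = \sum_c (n_c/n)\max_k F_1(k, c)$ with precision
  $n_{kc}/n_{k\cdot}$ and recall $n_{kc}/n_{\cdot c}$. This is the variant
  that reproduces the published reference values (`kfcmiss.benchmarks`);
  of the 24 published F-measure cells, 22 reproduce exactly and 2
  contradict their own published contingency tables under *every* common
  variant tried (cluster-weighted, unweighted, diagonal-mapped,
  pair-counting), so they are recorded as source inconsistencies rather
  than matched.
- **OERC** — one minus the mapped accuracy after the one-to-one
  cluster-to-class assignment maximizing the contingency diagonal
  (Hungarian algorithm). On every published table this coincides with the
  majority labeling, and unlike majority labeling it is always well
  defined. One published OERC cell (45/215 = 0.209 printed as 0.200)
  likewise contradicts its own matrix.
- **Consistency** $d_k(j)$ — per cluster and variable, the absolute
  difference between the observed-cell mean and the completed-cell mean of
  that cluster's rows, standardized by the two variances. The printed form
  of the statistic is typographically ambiguous about a square root over
  the variance sum, so both $|\mu_0-\mu_1|/\sqrt{s_0^2+s_1^2}$ (default)
  and $|\mu_0-\mu_1|/(s_0^2+s_1^2)$ are implemented behind a flag; neither
  can be validated against published values, which depend on unpublished
  random masks. Sample variance (ddof = 1) by default, configurable.
  Clusters with fewer than two observed values for a variable yield NaN
  with a warning.
- **Imputation diagnostics** — Pearson correlation of a chosen variable
  pair and per-variable standard deviations before vs after completion,
  quantifying the variance underestimation of central imputation.

Printed-precision comparisons truncate toward zero (0.066666 prints as
0.0666), with a relative epsilon absorbing binary floating-point artifacts.

## Defaults and tunable parameters

| parameter | default | meaning |
|---|---|---|
| `m` | 2.0 | fuzzifier; memberships harden as m -> 1 |
| `tol` | 1e-10 | stop when the objective change falls below this |
| `max_iter` | 300 | iteration cap per restart |
| `n_init` | 100 | random restarts (reduce for exploratory runs) |
| `weight_init` | 1 | initial weights; a 1/p option exists, and either is inert because weights are recomputed before first use |
| `distance_floor` | 1e-12 | guards zero dispersions and zero distances |
| `theta` | — | MCAR per-cell missing probability |
| `row_guard` | on | forbid fully-missing rows in generated masks |

Prototypes are seeded with the plain fuzzy mean of the random memberships —
deterministic, scale-respecting, and the natural first iterate of the
fixed-point map (the update equations never define an initial prototype).
Crisp assignments break membership ties toward the lower cluster index.
When several clusters sit at (floored) zero distance from a point, its
membership is split equally among them — the standard fuzzy c-means
singularity convention.

## Synthetic benchmarks: what they show and what they do not

The generators draw diagonal-covariance Gaussian mixtures. The `iris-like`
preset (3 x 50 observations, 4 variables, one separable component and two
adjacent ones) and the `thyroid-like` preset (150/35/30 observations,
5 variables on heterogeneous scales, small components more dispersed)
reproduce the *structure* of the classic benchmarks — cluster sizes,
separability pattern, scale heterogeneity — not their correlation
structure: no update equation requires correlated variables, so none are
generated. Consequences: passing recovery tests demonstrates correct
optimization and strategy behavior under MCAR on well-structured data; they
do not certify performance on data with strong within-cluster correlations,
heavy tails, or non-Gaussian cluster shapes, and real-data error rates will
generally be higher than the synthetic ones.

Test and acceptance problem sizes were chosen to exercise every code path
at comfortable margins: mixtures of n = 150, conditional-optimality oracles
at n <= 10 against an SLSQP optimizer and 1000 random feasible
alternatives, 20 restarts for the recovery checks, and a 100 x 100 grid for
MCAR calibration against the central 99.9% binomial interval.

## Known limitations

- Only the Gaussian kernel is supported: the closed-form updates rely on
  K(x, x) = 1, and the weight/membership algebra on per-variable kernel
  sums. Linear, polynomial and Laplacian kernels would need different
  update derivations.
- Coordinate descent offers no global-optimality guarantee; multi-start
  mitigates but does not remove initialization dependence.
- The prototype fixed-point step can in principle overshoot (it is not
  asserted monotone); in practice convergence to |dJ| <= 1e-10 within 300
  iterations is the norm on separable data and is asserted on the fixtures.
- Categorical variables, sparse inputs and streaming data are out of scope;
  labels are treated as opaque categories.
- No significance testing or internal validity indices are provided.
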