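# Methods

This document defines the statistical model, the synthetic-data generator,
and the numerical conventions used throughout `surveybbn`.

## 1. Model

A discrete Bayesian belief network over variables $X_1,\dots,X_n$ is a
directed acyclic graph (DAG) plus one conditional probability table (CPT)
per node. The joint distribution factorizes as

$$P(x_1,\dots,x_n) \;=\; \prod_{i=1}^{n} P\big(x_i \mid \mathrm{Pa}(x_i)\big).$$

In this package the variables are the eight survey sections S1–S8, each
discretized into 2 or 3 ordered states (low/high or low/medium/high). CPTs
are stored as arrays of shape `(r_{p1}, ..., r_{pk}, r_i)` whose last axis
sums to one for every parent configuration.

### CPT estimation

Given integer-coded data, CPT rows are estimated with Laplace smoothing:

$$\hat P(x \mid pa) = \frac{N_{x,pa} + c}{N_{pa} + c\,r},$$

with pseudocount $c = 1$ by default and $r$ the child's state count. A
parent configuration never observed yields the uniform row. State spaces
come from the binning specification, not from the observed codes, so states
absent from a training fold still receive probability mass.

### BDeu score

Structures are ranked by the Bayesian–Dirichlet equivalent uniform (BDeu)
log marginal likelihood with equivalent sample size $s = 1$. For node $i$
with $r_i$ states and $q_i$ parent configurations, the family score is

$$\sum_{j=1}^{q_i}\left[\ln\frac{\Gamma(\alpha_{ij})}{\Gamma(\alpha_{ij}+N_{ij})}
 + \sum_{k=1}^{r_i}\ln\frac{\Gamma(\alpha_{ijk}+N_{ijk})}{\Gamma(\alpha_{ijk})}\right],
\qquad \alpha_{ijk} = \frac{s}{q_i r_i},\;\alpha_{ij}=\frac{s}{q_i},$$

computed with `scipy.special.gammaln`. The total score is the sum of family
scores (decomposability), which the searches exploit by caching family
scores.

### Exact inference

Posterior marginals are computed by variable elimination. Factors are the
CPTs restricted by hard evidence; elimination order is chosen greedily by
minimum degree on the moralized interaction graph. Virtual (soft) evidence
on a node enters as an extra likelihood factor $\ell(x) = q(x)/p(x)$
(Jeffrey-style update): conditioning on it makes the node's posterior equal
the target distribution $q$ while information propagates both along and
against arc directions. Evidence with zero total probability raises an
error rather than returning NaNs.

## 2. Synthetic-data generator

The generator's defaults reproduce the published study conditions: 122
trust rows, eight section columns, the published section means and standard
deviations, the published 8 × 8 section correlation matrix, per-section
reliabilities, and a 7% missingness rate.

### Section scores

Rows are drawn from a multivariate Gaussian with the configured means,
standard deviations and correlation matrix (Cholesky factorization), then
clipped to the [0, 10] score scale. At the default parameters clipping is
negligible (all means are ≥ 4 standard deviations from the scale limits
except S1, which is ≥ 8 SDs from 0). If the supplied correlation matrix is
not positive semidefinite it is repaired with the nearest-correlation
projection (`statsmodels.stats.correlation_tools.corr_nearest`); the
default matrix is already PSD (smallest eigenvalue ≈ 0.148), so repair is
an identity there.

### Item blocks

Each section's item block (6 or 7 questions) is built under compound
symmetry. The inter-item correlation $\rho$ is obtained by inverting the
Spearman–Brown / Cronbach relation

$$\alpha = \frac{m\rho}{1+(m-1)\rho}
\;\Longleftrightarrow\;
\rho = \frac{\alpha}{m - \alpha(m-1)}$$

for the section's target reliability $\alpha$ and item count $m$. Items are
constructed as $I_j = s + d_j$ where $s$ is the section score and the
deviations are centered Gaussians $d = \sqrt{\gamma}\,(z - \bar z)$ with

$$\gamma = \operatorname{Var}(s)\,\frac{m(1-\rho)}{1+(m-1)\rho},$$

so that (a) the row mean of the items equals the section score exactly, and
(b) the population Cronbach alpha of the block equals the target. The
recovered sample alpha converges to the target as $n$ grows (verified to
±0.01 at n = 50,000 in the acceptance suite).

### Missingness

MCAR injection removes exactly $\mathrm{round}(\text{rate} \times
\text{cells})$ cells — 68 cells for 7% of a 122 × 8 table — chosen uniformly
without replacement, redrawing in the (tiny-probability) event that a column
would become entirely missing. Mean imputation then fills each gap with its
column's observed mean, which preserves column means and cannot increase
column variances.

## 3. Discretization

Three binning methods produce cut points per column:

- **equal width**: $k-1$ evenly spaced edges between the column minimum and
  maximum;
- **equal frequency**: edges at the $j/k$ quantiles (an error is raised if
  ties collapse adjacent quantiles);
- **k-means**: deterministic 1-D Lloyd iterations initialized at the
  $(j+0.5)/k$ quantiles; edges are midpoints between adjacent sorted
  cluster centers. The initialization makes the procedure seed-free and
  reproducible; like all Lloyd variants it returns a local optimum of the
  within-cluster sum of squares (the test suite bounds it below by the
  dynamic-programming optimum over contiguous partitions).

Bins are half-open $[e_{j-1}, e_j)$ with values exactly on an edge assigned
to the upper bin (`searchsorted` with `side="right"`); values outside the
fitted range clamp to the extreme bins, so a spec fitted on training data
can always code test data. Specs round-trip through YAML text files.

Under the **mixed** scheme each column's state count $k \in \{2, 3\}$ is
chosen by maximizing the mean silhouette of the 1-D k-means clustering;
ties prefer the smaller $k$, and candidates exceeding the number of
distinct values are skipped. The within-cluster sum of squares per
candidate (the elbow curve) is reported as a diagnostic but never drives
the choice. The **two_state** and **three_state** schemes force $k$.

## 4. Structure learning

- **Bayesian Search (BS)**: hill climbing over add/delete/reverse arc moves
  from the empty graph, followed by seeded random-restart climbs; the
  best-scoring result wins. Moves must keep the graph acyclic and respect
  the parent limit (4 by default).
- **Greedy Thick Thinning (GTT)**: from the empty graph, repeatedly add the
  best positive-gain arc (thickening); then repeatedly delete the
  best-gain-to-remove arc (thinning); both phases stop when no move
  improves the BDeu score.
- **PC**: level-wise skeleton pruning using the G² conditional-independence
  test at $\alpha = 0.05$ (degrees of freedom $(r_x-1)(r_y-1)$ per
  non-empty conditioning stratum), separating sets recorded; unshielded
  colliders oriented from sepsets; Meek rules R1–R4 applied to closure. The
  resulting CPDAG is extended to a DAG by orienting remaining undirected
  edges in lexicographic order, avoiding cycles and new v-structures.

All tie-breaks are lexicographic, making every learner deterministic given
its seed.

## 5. Validation

Stratified k-fold cross-validation (default k = 10; at n = 122 folds have
12–13 rows). Stratification shuffles rows within each target class and
deals them round-robin with a continuous counter, keeping fold sizes within
one row of each other. For every fold the structure is held fixed, CPTs are
refit on the training rows, and each held-out row's target is predicted by
the posterior given all other nodes as hard evidence (argmax prediction;
full posteriors retained). Reported metrics:

- pooled confusion matrix (actual × predicted) and accuracy, with the
  rounded whole-percent figure alongside the exact value;
- AUC via the rank-based Mann–Whitney statistic with midrank tie handling;
  for 3-state targets, prevalence-weighted one-vs-rest AUC.

## 6. Sensitivity analysis

The doubling transform on a marginal $p$ boosts state $s$ to
$p' = \min(2 p_s,\, 1-\varepsilon)$ (ε = 10⁻⁶) and rescales the remaining
states by $(1-p')/(1-p_s)$, preserving their mutual ratios. The intervention
is imposed through virtual evidence with likelihood $q/p$, so the source's
posterior equals the doubled distribution exactly; `mode="do"` instead cuts
the source's incoming arcs and replaces its CPT (interventional semantics).
The two modes coincide on root nodes.

The **net effect** on a target is the relative percent change of its top
state's probability, $100\,(P'_{top}-P_{top})/P_{top}$. The influence scan
applies the doubling intervention at every node and tabulates net effects
on all others; pairs that are d-separated given no evidence are set to
exactly zero by construction (checked structurally via
`networkx.is_d_separator`), so isolated nodes show identically zero rows
and columns. Sources are ranked by the sum of absolute net effects.

The CPT perturbation scan multiplies each CPT entry by $1 \pm \delta$
(δ = 0.10) one at a time, renormalizes the row, and records the largest
absolute shift in the focus node's marginal per node, labelled high
(≥ 0.01), mild (≥ 10⁻⁶) or none.

## 7. Pipeline and reproducibility

The pipeline derives one sub-seed per stage from the master seed via
`numpy.random.default_rng([master, stage])`, so stages are independently
reproducible and all seeds stay below 2³¹. Every artifact file carries a
16-hex-digit SHA-256 hash of the full configuration in a header line. The
model grid covers 3 schemes × 3 algorithms; the "best" model maximizes
cross-validated accuracy with AUC as tie-break (earlier grid position as
final tie-break).

## 8. Numerical conventions

- Sample statistics use `ddof=1` (unbiased variance) throughout, including
  Cronbach alpha $\frac{m}{m-1}\left(1 - \sum_i \sigma^2_i / \sigma^2_T\right)$.
- Probability vectors are validated to sum to 1 within 10⁻⁹; CPT rows are
  renormalized after perturbation, never clipped silently.
- Factor products in variable elimination use broadcasting over aligned
  axes; no logarithmic rescaling is applied (networks here are small enough
  that underflow is not reachable).
- CSV serialization writes missing cells as `NA`; BIF export uses 10
  significant digits, sufficient to round-trip CPTs to 10⁻⁸.

## 9. Limitations

- The generator models section scores as clipped Gaussians with a fixed
  correlation matrix; it does not model trust-level covariates, temporal
  drift, or non-MCAR missingness.
- Compound symmetry is a single-factor approximation to real item
  covariance structure; it matches the target alpha but not arbitrary
  item-level correlation patterns.
- With 122 rows, learned structures vary with the discretization scheme and
  algorithm; single learned DAGs should be read as one member of a family
  of plausible models, not as causal ground truth.
- Virtual-evidence interventions are observational updates; use `mode="do"`
  when interventional semantics are required, and note that neither mode
  confers causal validity on arcs learned from observational data.
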