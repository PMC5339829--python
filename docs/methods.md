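# Methods

This note documents the statistical model behind `fcnet`, the meaning of
its parameters, the scope of the synthetic cohort generator, and the
numerical conventions used throughout. The package implements a
resting-state functional brain-network analysis of the kind used in
case–control connectome studies: regional time series are correlated,
thresholded into binary graphs across a sparsity range, summarized by
graph-theoretical metrics, compared between groups with permutation
tests, and fed to a linear classifier.

## Pipeline model

### Connectivity

Each subject contributes a `T x N` matrix of ROI time series (defaults:
`T = 200` volumes at `TR = 2 s`, `N = 90` regions with AAL-90 labels).
Optional preprocessing at the ROI level:

- **Nuisance regression** (`regress_nuisance`): ordinary least squares
  projection of each ROI series onto a column-wise design of confound
  regressors plus an intercept; the residuals are kept.
- **Band-pass filter** (`bandpass_filter`): zero-phase second-order
  Butterworth filter (applied forward and backward via
  `scipy.signal.sosfiltfilt`), default pass band 0.01–0.1 Hz.

Functional connectivity is the Pearson correlation between ROI pairs,
Fisher r-to-z transformed. Correlations are clamped to
`|r| <= 1 - 1e-15` before the transform so z stays finite. Edge-level
group statistics operate on these z values; network construction keeps
only positive connections (negative correlations are set to zero before
thresholding), a common choice for binary topological analysis.

### Network construction

Binary undirected networks are built by sparsity thresholding: at
sparsity `s` the strongest `K = round(s * N * (N - 1) / 2)` positive
edges are kept (round-half-up, so `N = 90, s = 0.10` gives `K = 401`).
The default analysis grid is `s = 0.10` to `0.34` in steps of `0.01`
(25 levels). Each level is annotated with two admissibility flags:

- **degree**: mean degree `>= 2 ln N`, the usual estimability condition
  for sparse-graph metrics;
- **smallworld**: the network's small-worldness `sigma > 1.1`.

### Graph metrics

On each binary network the package computes, per node and globally:
clustering coefficient `Cp`, characteristic path length `Lp` (mean
shortest path over reachable pairs; disconnected pairs are excluded by
default, or harmonically handled via efficiency), global efficiency
`Eglob`, local efficiency `Eloc`, degree, and betweenness. Shortest
paths use breadth-first search on the unweighted graph.

Normalized small-world indices compare the network to an ensemble of
degree-preserving randomized (Maslov–Sneppen rewired) null networks
(default 100 per subject): `gamma = Cp / <Cp_null>`,
`lambda = Lp / <Lp_null>`, `sigma = gamma / lambda`.

Each metric's curve over the sparsity grid is reduced to an area under
the curve (AUC) by trapezoidal integration (`numpy.trapezoid`); AUC
names are prefixed with `a` (`aCp`, `aLp`, `agamma`, ...). The AUC over
a 0.24-wide grid of a constant curve `c` is `0.24 c`, and of the
identity curve `f(s) = s` is `0.0528`; both are used as closed-form
checks.

### Group inference

- **Edgewise**: two-sample t-tests on Fisher-z values over all
  `N (N - 1) / 2` edges, with Benjamini–Hochberg FDR control; results
  export to BrainNet Viewer `.node`/`.edge` text formats.
- **AUC metrics**: permutation tests on the patient-minus-control mean
  difference. P-values use the add-one estimator
  `p = (1 + #{|delta_perm| >= |delta_obs|}) / (1 + n_perm)` with a
  `1e-12` comparison tolerance. With covariates, either a simple
  label-permutation on residualized values or a Freedman–Lane scheme is
  available. Nodal metrics are FDR-corrected per metric family; global
  metrics report `q = p`.
- **Clinical correlations**: Spearman rank correlations between
  patients' metric AUCs and clinical scores, Bonferroni-corrected over
  the tested (metric, scale) pairs.

### Classification

A maximum-uncertainty linear discriminant (MLDA) classifier separates
the groups from global AUC features (default `aLp`, `aCp`), evaluated by
leave-one-out cross-validation. Feature screening (two-sample t-test at
`alpha`) is nested inside the cross-validation loop by default to avoid
selection bias; a whole-sample selection mode is available for
comparison with studies that pre-select features on all subjects.
Significance comes from label permutations: the add-one p-value and a
z-score of the observed accuracy against the permutation-null mean and
standard deviation. The smallest attainable p is `1 / (n_perm + 1)`.

## Synthetic cohort generator

The generator produces two-group cohorts (patients and controls,
`n = 42` per group by default) of ROI time series with a planted,
parametrically controlled topological group difference, plus
demographics and clinical scores.

### Signal model

Each subject's time series are drawn as correlated Gaussian noise:
`x = L e`, with `L` the Cholesky factor of a ground-truth correlation
matrix `Sigma` and `e` i.i.d. standard normal, band-pass filtered to the
analysis band, plus white observation noise (`noise_sd`). The matrix
`Sigma` is built from latent factors, `Sigma = Lambda Lambda^T + D`,
where `D` fills the diagonal to exactly 1. Every node's squared factor
loadings are budgeted to sum to at most 1, so `Sigma` is a valid
correlation matrix by construction — no eigenvalue clipping or repair is
ever needed, and the planted edge values are exact.

### Planted topology

Nodes are split into 6 equal modules arranged in a ring. The factor set
comprises:

- **Mesh** (`mesh_coupling`): two hexagonal-geometry factors giving a
  smooth background — within-module pairs +0.10, adjacent modules
  +0.05, offset-2 modules −0.05, antipodal −0.10 by default.
- **Module factors** (`within_coupling`): one factor per module loading
  all its members, making modules internally dense (within-module
  correlations ≈ 0.3).
- **Vulnerable within-module factors** (`within_vulnerable`): a second,
  weaker within-module factor whose patient-group loading shrinks as
  `(1 - effect)^within_exponent`. Patients' modules are therefore
  slightly sparser at a fixed threshold, which lowers clustering.
- **Backbone cliques** (`backbone_coupling`): strong 4-node factors
  bridging adjacent modules (two designated nodes on each side), shared
  by both groups; they keep the thresholded graph connected.
- **Spokes** (`spoke_coupling`, `n_spokes`): strong two-node factors
  joining offset-2 module pairs. These are the **targeted edges**: in
  patients their loading is multiplied by
  `sqrt((1 - effect)^spoke_exponent)`, removing long-range shortcuts and
  raising path length.
- **Promoted pairs** (`promoted_coupling`, `n_promoted`): adjacent-module
  two-node factors present **only in patients**, ramping in as
  `min(effect / 0.6, 1)`. They replace the edge count lost from the
  attenuated spokes, so the sparsity threshold cuts both groups at the
  same depth; without them, thresholding would recruit noise edges in
  patients and dilute the contrast.

At `effect_size = 0` the two groups share an identical `Sigma`. The
default coupling values were chosen (and pre-registered before the
confirmatory runs) so that at `effect_size = 0.6`, `n = 40` per group,
the patient group shows increased `aLp` and decreased `aCp`, each
significant at `q < 0.05` in at least 80% of replicates.

`n_targeted_edges` restricts attenuation to the first `k` spokes. Note
that partial targeting together with the promoted redistribution can
overcommit a node's variance budget (an unattenuated spoke node may
also carry a promoted pair); such configurations are rejected at
construction with a parameter error — set `n_promoted = 0` when
targeting a subset.

### Demographics and clinical scores

Ages are truncated-normal per group (patients 27.3 ± 7.2, controls
29.8 ± 8.8, range 18–60); sex is assigned at a fixed female fraction
(16/42). Clinical scales (LSAS total/fear/avoidance, HAMD, HAMA) are
truncated normals with group-specific means and SDs chosen so that
two-sample t-statistics on the generated cohorts approximate a reference
clinical table. With `clinical_link > 0`, a per-subject latent severity
couples score draws to an individual jitter of the planted effect,
creating genuine metric–symptom correlations; by default scores are
independent of the signal.

### What the generator does NOT model

- No hemodynamics: time series are filtered Gaussian noise, not BOLD
  responses; no autocorrelation structure beyond the band-pass filter.
- No voxel level: no slice timing, realignment, normalization,
  smoothing, or motion artifacts; the generator starts at ROI series.
- No spatial embedding: module geometry is abstract; AAL labels are
  cosmetic and no anatomical adjacency is modelled.
- No negative planted couplings, no weighted-network ground truth
  beyond the factor model, no site/scanner effects, no missing data.

## Numerical choices

- All randomness flows through `numpy.random.SeedSequence` trees keyed
  by user seeds; every subject, null network, and permutation draw has a
  deterministic path, so runs are exactly reproducible and individual
  pieces can be regenerated in isolation.
- Edge counts use round-half-up (not banker's rounding) so thresholds
  match hand calculations.
- Permutation p-values use the add-one estimator with a `1e-12` tie
  tolerance; they can never be 0.
- Fisher transform clamps `|r|` at `1 - 1e-15`; AUC uses the composite
  trapezoid rule; BH-FDR uses the step-up procedure with monotonicity
  enforcement (`statsmodels` implementation).
- Maslov–Sneppen rewiring attempts `swap_factor x E` edge swaps and
  warns if the attempt budget is exhausted before the target swap count.

## Limitations

- The planted-effect defaults are calibrated for the default geometry
  (90 ROIs, 6 modules); other `n_rois`/`n_modules` combinations are
  structurally valid but their statistical power is uncalibrated.
- Binary undirected graphs only; weighted or directed analyses are out
  of scope.
- The MLDA classifier is intentionally minimal (two global AUC features
  by default); it is a methods demonstration, not a diagnostic tool.
- Synthetic clinical scores approximate group summary statistics only;
  item-level structure and score intercorrelations are not modelled.
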