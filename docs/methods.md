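# Methods

## The dispersion index

Dispersion operationalizes intraindividual variability *across* a profile
of tests at one occasion, as opposed to trial-to-trial response-time
inconsistency within a task. The computation is the classical
regression-based one:

1. **Orientation.** Every score is re-expressed so that higher values
   uniformly mean better performance; timed tests (TMT-A/B) and
   error-count tests (ADAS-Cog total, ANART) are negated.
2. **Age detrending.** Each oriented test is regressed on
   `[1, age_c, age_c²]`, with age centered at the sample mean before
   squaring. Centering only reconditions the design matrix; fitted values
   are unchanged. At least 4 usable rows per test are required (3
   parameters + 1 df); sparser tests are dropped to all-missing with a
   warning rather than fitted.
3. **T-standardization.** Residuals are scaled to mean 50, SD 10 (sample
   SD, n−1) per test, over that test's fitted rows. Standardization is
   within-sample; a norms-table plug-in would fit the same interface but
   population norms are out of scope. A literally constant column maps to
   T = 50 everywhere (a scatterless test at the group mean); a
   *non-constant* column whose residuals vanish to rounding level (a
   noise-free polynomial in age) is rejected as degenerate, because real
   data cannot produce it and it makes the T-scale undefined.
4. **ISD.** The per-person sample standard deviation (n−1) of the
   non-missing T-scores over the relevant profile: all 15 tests (ISD-BP),
   the 6 memory tests (ISD-Mem), or the 5 executive tests (ISD-EF). The
   n−1 denominator keeps the per-person variance estimate unbiased;
   profiles with fewer than 2 scores yield a missing ISD rather than 0.

**Exclusions.** Participants completing fewer than `min_fraction`
(default 0.5) of the battery are flagged, as are participants whose
ISD-BP exceeds the included-group mean + 3 SD — few observed tests make
the ISD estimate itself unstable, and the two flags travel together in
practice. Flagged rows carry a reason string; downstream contrasts drop
them.

**Composites.** COM-Mem / COM-EF are *proxies*: the mean of within-domain
T-scores, z-scored over the cohort. The psychometrically derived
composites they stand in for are fitted to a large external calibration
sample with item-response models and cannot be reproduced from score
totals; the proxy keeps the interface and the directionality, not the
exact weighting. Because the pipeline's composites are built from
age-detrended T-scores they are age-orthogonal by construction; the
strong negative composite–age correlations seen in raw data are a
property of the *non-detrended* scores, and the generator tests verify
them on composites built without the age regression.

**Correlation table.** Pearson r on pairwise-complete cases, p from the
t distribution with n−2 df. Tails are configurable per pair; the default
is two-tailed everywhere except dispersion–composite pairs, which are
tested one-tailed in the negative direction (more consistent performance
is hypothesized to accompany better aggregate performance). One-tailed
p = p_two/2 when r lies in the hypothesized direction, 1 − p_two/2
otherwise.

## Voxelwise inference

The skeleton is the set of voxels with mean FA strictly above 0.2.
Registration and skeleton projection are upstream concerns: all volumes
in a run must already share shape and affine exactly (checked, never
resampled), and subject maps are consumed as given.

**GLM.** Per voxel, OLS of the metric on `[1, nuisance..., predictor]`;
the statistic is the predictor's t with df = n − p. A rank-deficient
design is an error. An epsilon guard on the standard error keeps
perfectly explained voxels at a large finite t instead of infinity.

**TFCE.** `TFCE(v) = Σ_h e_h(v)^E h^H dh` over thresholds
`h = dh, 2dh, … ≤ max(stat)`, where `e_h(v)` is the voxel count of the
connected component of `{stat ≥ h}` containing v. Defaults E = 0.5,
H = 2, 26-connectivity, dh = max/100 — the established convention; all
configurable. Non-positive voxels enhance to 0. The implementation sweeps
thresholds from high to low with an incremental union-find (voxels
activate as h drops below their value and merge with active neighbors),
which makes the whole integral roughly O(n_steps × n_voxels) amortized
find operations; the test suite checks it against an independent
threshold-loop + connected-component-labeling implementation to machine
precision, and against the isolated-peak closed form h₀³/3.

**Permutation FWER.** One-tailed by default; the negative direction is
the same test on the negated predictor (verified exactly symmetric).
The null distribution collects the maximum TFCE value over the skeleton
for each permutation; voxelwise
`p_FWE = (1 + #{null max ≥ obs}) / (n_perm + 1)` (the add-one convention
avoids zero p-values, so the attainable minimum is 1/(n_perm+1)).
Corrected maps are stored as 1 − p_FWE, matching the "critical value"
convention of corrected-p imaging tools. With nuisance covariates the
scheme is Freedman–Lane: residuals from the nuisance-only model are
permuted and the full model refit. The nuisance design always contains
the intercept, so without covariates the scheme reduces to permuting
centered rows — a full row permutation as far as the t statistic is
concerned — keeping one code path. Permutations are drawn from a seeded
generator (bit-reproducible); `exhaustive=True` enumerates all n! row
permutations for small n. Fewer than 100 permutations is rejected as too
coarse for inference.

## The synthetic cohort

The generator emulates the structure the analysis assumes, with ground
truth exposed for every planted feature:

- **Cohort.** Ages truncated-normal (mean 72.0, SD 6.4, bounds 59–89
  years). A latent damage factor D ~ lognormal(0, 0.4) — right-skewed,
  strictly positive, *independent of age by construction* — stands in
  for diffuse white-matter damage.
- **Scores.** Oriented score = intercept + b·age_c + c·age_c² +
  λ·ability + ε with sd(ε) = σ·(1 + g·D). The age slopes put roughly a
  third of raw-score variance under the age trend (so raw composites
  correlate strongly and negatively with age); the per-test loadings λ
  vary so tests share an ability factor without being redundant; and the
  gain g maps damage into *within-person residual scatter*, which is what
  the ISD measures. D drives dispersion but not mean-level age trends,
  reproducing the dissociation in which dispersion is age-independent
  while composites are strongly age-graded. Per-test intercepts and
  residual SDs are scaled to each test's typical score range. The default
  g = 1 reproduces a realistic observed ISD-BP distribution
  (mean ≈ 9.1 T-score units, CV ≈ 0.3) and implies corr(ISD, D) ≈ 0.73 —
  the ISD is a deliberately *attenuated* readout of D, as any 15-item
  standard deviation must be.
- **Imaging.** The skeleton is the toy-atlas blocks plus a sparse random
  background (density 0.08); the emitted mean-FA volume reproduces it
  exactly under the FA > 0.2 rule. Per voxel: regional FA baseline
  (spread over [0.3, 0.8]) declining 0.003/year; MD baseline 0.7 (units
  10⁻³ mm²/s) rising 0.003/year; plus an MD increment in the effect
  regions (genu, bilateral anterior corona radiata, left SLF stand-ins
  by default) equal to β/√(1−β²) noise-SDs per SD of D, so that β is the
  correlation between standardized damage and the voxel value net of age
  (default β = 0.5). Spatial noise is white Gaussian smoothed with a
  σ = 1.5-voxel kernel and renormalized to unit variance before scaling —
  spatially correlated noise is what makes the familywise-error
  calibration honest, since the max-statistic null must absorb smooth
  chance clusters. FA is clipped to [0, 1], MD floored above 0.

**What the generator does not emulate:** realistic diffusion signal
formation, partial-volume and crossing-fiber effects, registration and
projection error, scanner/site effects, non-Gaussian score
distributions, or floor/ceiling truncation of test scales (scores are
Gaussian and can stray outside printed instrument ranges). Passing tests
therefore demonstrate the *statistical machinery* — exact
standardization, valid FWER, directional recovery — not clinical
fidelity of any particular dataset.

## Problem sizes and numerical choices

The default synthetic study uses n = 80 subjects on a 24×40×12 grid
(~1,800 skeleton voxels, fifteen 64–96-voxel regions) with 1,000
permutations; the null-calibration studies use 12-subject pure-noise
datasets on a 20×20×10 grid. These sizes make every end-to-end property
computable on a laptop while keeping the voxel count large enough for the
max-statistic correction to be meaningfully multiple.

Notable numerics: degenerate detrend columns are detected at relative
residual scatter ≤ 1e−8; the GLM epsilon guard is 1e−12 on the squared
standard error; TFCE thresholds are `k·dh` with k = 1…⌊max/dh⌋, so the
implementation and any reference share the same discretization exactly;
stage seeds for the study generator and pipeline are spawned
deterministically from the single user seed.

## Known limitations

- Planted-effect recovery through the *measured* ISD is intrinsically
  attenuated: with 15 tests and a realistic ISD distribution,
  corr(ISD, D) ≈ 0.73, so an effect planted at β = 0.5 against D acts at
  an effective ≈ 0.36 against ISD. At n = 80 this leaves weaker planted
  regions straddling the corrected-0.90 boundary: run-to-run recovery of
  planted voxels ranges roughly 45–80%, with non-planted regions staying
  at zero. Recovery near-certain requires either the latent factor
  itself as predictor (≈98% recovered) or a larger cohort.
- The proxy composites are not the psychometric composites; correlations
  involving them match in structure and sign convention, not in value.
- One-tailed inference is the default throughout the voxelwise module;
  two-sided questions need two runs (positive and negated predictor).
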