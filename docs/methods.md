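# Methods

This note documents the statistical model behind each stage, the parameters
that matter, the numerical choices, and what the synthetic cohorts do and do
not establish about real data.

## Synthetic cohorts (`netcog.simulate`)

The generator emulates an older-adult morphometry-and-cognition study as a
hierarchical linear model.

**Demographics.** Age is drawn from a truncated normal on `age_range`
(default 60–89 y). The parent location/scale are solved numerically so that
the *truncated* distribution has the configured mean and SD (default 69.5,
6.58) — reported sample moments describe the truncated cohort, not a parent
normal. Sex is Bernoulli (`female_fraction`, default 105/165; 1 = female).

**Latent cognition.** Two latent factors (executive function, episodic
memory) are drawn conditionally on standardized age with configured
age correlations (`age_effect_per_factor`, default −0.30 and −0.36) and a
configured mutual correlation (`latent_factor_correlation`, default 0.35 — a
typical EF–memory composite correlation in aging cohorts). Validation
rejects combinations whose implied conditional covariance is not PSD.

**Tasks.** The 11 battery indicators are `loading_matrix · factors + noise`.
The default loading matrix is the battery's reference two-block structure;
default noise SDs top each task's latent variance up to 1, so generating
loadings act as correlations of standardized tasks. Scores are mapped onto
each task's conventional raw scale (e.g. Trail Making B ≈ 77.7 ± 24.7 s) with
field-correct directions: reaction-time/completion-time/swap tasks are
emitted lower-is-better so the composites module's direction handling is
exercised end to end.

**Thickness.** Each vertex's standardized signal is
`c_g·g + c_tf·f + c_ta·z_age + c_e·ε`, where `g` is a participant-level
global component (`global_component`, default loading 0.5, giving
inter-vertex correlations ≈ 0.25 — real cortical thickness is globally
correlated, which is also why a cohort's whole-map statistics co-vary),
`c_tf`/`c_ta` are per-network couplings on a correlation scale (a planted
coupling of 0.4 yields vertex–factor correlations ≈ 0.4), and ε is smoothed
noise: iid normals moving-averaged over ±`spatial_smoothness` vertices
(default 5) within each network block, rescaled to unit variance. The mm
scale is set so the labeled-vertex mean has the configured global SD
(default 0.12 mm around 2.39 mm), after reserving the variance contributed
by the additive sex effect (+0.065 mm for females). Per-vertex SD comes out
near 0.24 mm.

**Area.** Vertex area is multiplicative:
`a₀ · m_i · (1 + 0.15 · local signal)`, with `m_i` a participant size factor
combining a 0.90 multiplicative female effect and a global size component
calibrated so total area has the configured mean/SD (157,614 ± 15,776 mm²)
including the sex contribution. Area–cognition couplings default to zero
(the emulated studies find surface area largely uncoupled from cognition in
older adults); thickness–area cross-coupling is left at zero rather than
guessing an undocumented value.

**What is not emulated.** No mesh geometry or 2-D smoothing kernels (the
1-D moving average preserves the only property downstream code is sensitive
to: correlated neighbors); no reconstruction error or manual-edit effects;
vertices are arranged in contiguous network blocks. Consequently, passing
tests show the *statistical machinery* is correct under the assumed
generative structure — not that real cortical data satisfy that structure.

## Composites (`netcog.composites`)

Winsorization is a single pass: mean and SD (ddof = 1) computed once from
the input, values beyond k = 3 SD clipped to the boundary. PCA runs on the
task correlation matrix; the first two components are retained by design
(fixed n = 2, not an automatic scree detector). Varimax uses Kaiser
(communality) normalization around `statsmodels`' rotation core
(tol 1e−6, ≤ 1000 iterations). Because rotation is identified only up to
sign and permutation, each component is sign-fixed so its largest-|loading|
task loads positively, and components are ordered by post-rotation variance
explained. That order is *not* stable across samples when the two components
explain similar variance, so the composite labels (executive_function,
episodic_memory) are assigned by overlap with the battery's executive block.
Composites are means of member-task z-scores, hence exactly mean-zero and
affine-invariant to raw task rescaling.

PCA loadings are systematically slightly larger than factor-model generating
loadings (components absorb unique variance); on default cohorts the two
components explain ≈ 0.29/0.26 of variance where the generating structure
implies 0.25/0.21. Consistency is therefore tested against the population
correlation matrix's own PCA+varimax solution rather than against the
generating loadings.

## Surface data (`netcog.surface`)

Matrices interchange as CSV (`%.17g` on write, round-trip float parsing on
read — bit-exact). Labels use codes 0–7, 0 = unlabeled/medial wall; `whole`
keeps 1–7. Robust scaling centers on the median and divides by the IQR
(25th–75th percentile, linear interpolation between order statistics — the
convention is unstated upstream and is pinned here for reproducibility).
Zero-IQR vertices are centered but divided by 1 rather than dropped, so
per-network vertex counts stay stable.

## Prediction (`netcog.predict`)

Folds are uniformly random, equal-size-as-possible, unstratified. Iteration
i draws its partition from sub-seed `(seed, i)`, so adding iterations never
changes earlier ones. Selection uses the Pearson-correlation t-test with
n − 2 df (raw p ≤ α; the thresholds are raw p-values, not FDR-corrected
levels). Folds where a threshold selects no vertex contribute no prediction
at that threshold and are tallied as an empty-fold fraction; a participant's
threshold-level prediction is the mean over the iterations in which they
received one, and the across-threshold average uses available thresholds
only — inference is run on that across-threshold average. Per-fold training
slopes are exported to diagnose sign-unstable (near-chance) models.

## Inference (`netcog.inference`)

The bootstrap is a case (pairs) bootstrap: rows are resampled jointly and
the statistic — including residualization and standardization — is recomputed
per resample. `p_boot` is one-sided (proportion of draws ≤ 0), matching an
alternative of a positive effect; intervals are reported at both 95%
(2.5/97.5) and 90% (5/95) coverage since both conventions appear in this
literature. In mediation, age is negated (so decline-consistent effects are
positive) and age/mediator/outcome are standardized, putting the
difference-of-betas on a correlation-like scale; the binary sex covariate is
left as coded. The difference-of-coefficients equals the product of paths
exactly for OLS — this identity is a standing regression test, not an
approximation.

## Vertex-wise maps (`netcog.vertexwise`)

One set of B resample index vectors is shared by all vertices (standard for
BSR maps; keeps a 5,000 × 300k computation tractable and the map coherent).
BSR = mean/SD (ddof = 1) of the draws; vertices with zero variance or
numerically degenerate draws (SD ≤ 1e−12, e.g. a vertex identical to the
target) are flagged undefined and excluded from counts. Counts default to
the positive tail (BSR ≥ t), with an absolute-value option, at thresholds
1.96/2.58/3.3/3.9. The permutation null shuffles BSR values across labeled
vertices (equivalently, shuffles labels — both modes are implemented and
agree); p is the plain proportion of null counts ≥ the empirical count, so
p = 0 is reportable with resolution 1/n_perm (logged). The null mean per
network equals the hypergeometric expectation
`(network size / labeled vertices) × whole-map count`.

Vertex-wise mediation maps use the product-of-paths closed form, vectorized
across vertices; equality with the scalar difference-of-betas is asserted in
tests to machine precision.

## Scaled-down defaults

Simulated cohorts default to 2,000 vertices (proportional to the 7-network
parcellation's share of a full-resolution cortical surface); tests and the
acceptance script use B = 200–500 bootstrap resamples, 2–10 CV iterations,
and 200–4,000 permutations. These sizes were chosen as the smallest at which
the statistical claims under test have adequate Monte-Carlo precision; the
full-scale settings (B = 5,000, 100 iterations, 100,000 permutations) are
plain parameters and remain the pipeline defaults in
`pipeline.DEFAULT_STUDY_CONFIG`.

## Known limitations

- The synthetic reference cohort (`netcog.synthetic_reference`) is a
  labelled stand-in for an undeposited participant-level dataset: it plants
  the published outlier counts and moment targets but cannot reproduce the
  original data's exact covariance; quantities estimated from it carry
  sampling error at n = 165.
- Couplings are specified on a correlation scale per network, identical for
  all vertices within a network; real effect topographies vary within
  networks.
- The area model's local coefficient of variation (0.15) and the thickness
  global loading (0.5) are plausibility choices, not fitted values.
- No cluster-extent inference, surface rendering, alternative learners, or
  FDR correction of the selection thresholds — all deliberately out of scope.
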