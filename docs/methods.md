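# Methods

## The analysis in brief

`qmrinorm` models per-ROI quantitative MRI metrics (R1, R2*, χ; medians,
IQR, skewness, normalized volumes, spatial gradients) as a function of age,
expresses individual measurements as deviations from the age-conditional
norm, and studies the structure of those deviations across metrics, across
nuclei, and between patient and control groups.  The stages run in a fixed
order: ROI metric extraction → covariate GLM → sex/hemisphere correction →
GP normative fit → deviation z-scores → correlation networks → group
comparison.  Everything downstream of map-space extraction operates on a
long-format table keyed by (subject, ROI, hemisphere, metric, statistic).

## ROI metrics

Medians are used in preference to means because parcellation labels are
never perfect at structure boundaries and the median resists partial-volume
outliers.  IQR uses linear-interpolated quantiles (Q75 − Q25); skewness is
the bias-corrected Fisher–Pearson form g1·√(n(n−1))/(n−2), appropriate for
small ROIs, and is undefined (NaN) below 3 voxels.

Spatial gradients fit the first-order model
q(x,y,z) = p0 + p1(x−x0) + p2(y−y0) + p3(z−z0)
by OLS over the ROI mask after one erosion with a 3×3×3 box element ("one
voxel in all directions", i.e. the full 26-neighbourhood).  Coordinates are
millimetres through the image affine (RAS assumed), so p1/p2/p3 are
units/mm along the lateral–medial, posterior–anterior and inferior–superior
axes; (x0, y0, z0) is the unweighted centre of mass of the *eroded* mask.
Right-hemisphere masks have their x-offsets sign-flipped before fitting so
the L–M gradient shares one direction convention across hemispheres and the
two sides can be pooled with a hemisphere regressor.  The positive
directions are fixed as P→A and I→S.  Fits are refused below 8 voxels; a
planar mask yields a rank warning and the flat axis's coefficient is NaN.
By default gradients are recommended only for putamen and caudate — the
other nuclei are too small at ~1 mm resolution — but any ROI passing the
8-voxel guard can be fitted.

Volumes are normalized by intracranial volume; for display the percent
change versus the cohort mean, V% = (V − V̄)/V̄ × 100, is used (cohort mean
of V% is identically zero).

## Covariate GLM and t→z

The design is [1, Age, Age², Sex, Hemisphere] with sex and hemisphere
centered ±½ so that residualization moves every observation to the cohort
average.  Age enters raw (not centered) together with its square; the
resulting Age/Age² collinearity inflates their individual standard errors
and is accepted as part of the model definition.  Hemisphere rows are
treated as independent observations; the within-subject correlation this
ignores is a documented simplification.  Fitting is QR-based OLS with
classical standard errors; t = β/se with ν = n − 5.

z-statistics are the sign-preserving quantile map z = Φ⁻¹(F_t(t; ν)),
evaluated through log-space tail probabilities (`scipy.special.ndtri_exp`)
so the map is finite, odd and strictly increasing even at |t| in the
thousands.  Agreement with the naive two-sided construction is not claimed
beyond |z| ≈ 8, where tail-probability implementations diverge.

## GP normative models

For each (ROI, metric, statistic), the sex/hemisphere-corrected values are
standardized (both axes) and fitted with a zero-mean GP whose kernel is

    k(a, a') = σ²_SE·exp(−(a−a')²/2ℓ²) + σ²_lin·a·a' + σ²_n·δ(a, a')

The linear term captures the dominant R2*/χ trends, the squared-exponential
term the curved (inverted-U) R1 trend; hyperparameters maximize the exact
log marginal likelihood with seeded L-BFGS restarts (default 5).  The
predictive standard deviation *includes* the noise variance: deviation
scores z = (y − m(a))/s(a) describe new observations, so |z| ≤ 1.96 is the
95% reference band for individuals, not for the mean trajectory.

Reference-cohort scores are k-fold cross-validated (default k = 10):
subjects are dealt into folds round-robin within age deciles (avoiding
age-extrapolating folds), both hemispheres of a subject share a fold, and
each subject is scored by the model fitted without its fold.  External
cohorts are first corrected with the *reference* cohort's GLM betas — the
`corrected` flag is enforced — then scored against the frozen full-data
model.  Models serialize to JSON (hyperparameters, standardization,
training arrays, correction betas) and rebuild without re-optimization.

Noise is modelled homoscedastically.  The generator can produce
age-dependent noise, and real qMRI variance grows with age; the posterior
sd still varies with data density but not with a true variance trend — a
known limitation.  A second caveat: plug-in maximum-likelihood
hyperparameters slightly underestimate predictive spread at n ≈ 260, so
held-out coverage of the 1.96 band averages ≈ 0.944 rather than 0.95
across seeds.

## Deviation structure and group comparison

Correlations are Pearson, pairwise-complete with a 3-pair minimum;
zero-variance columns give NaN cells.  Network edges require r ≥ threshold
with *positive* sign (the "networks of variation" reading); components come
from union-find.  Group comparisons use Welch's t-test (unequal variances —
the intended comparison is 44 controls vs 316 patients) with the
Welch–Satterthwaite dof and the convention t = 0, p = 1 for two degenerate
equal-mean groups.  BH-FDR is applied within one (metric, statistic)
family across ROIs (the family choice is configurable); hemispheres are
pooled per subject before testing.

## MP2RAGE R1 estimation

The forward model is the steady-state longitudinal-magnetization solution
of the MP2RAGE cycle (inversion with efficiency 0.96 → gap TA → GRE block
at α1·B1 → gap TB → GRE block at α2·B1 → gap TC, period TR), with each
stage composed as an affine map of Mz and the steady state obtained as its
fixed point.  Signals are read at block centres (linear encoding).  The
default protocol is TI1/TI2 = 700/2400 ms, TR = 6000 ms, α1/α2 = 6°/6°.
The per-block readout structure (n = 176 pulses, 7 ms spacing) is required
by the signal equations but rarely reported; both values are explicit
configuration with those defaults, and synthetic round trips are unaffected
as generation and matching share the protocol object.

Dictionary matching normalizes each simulated (S_TI1, S_TI2) pair to unit
norm over an (R1, B1) grid (defaults: R1 0.05–4.0 s⁻¹ step 0.005, B1 step
0.005) and returns the R1 maximizing the absolute complex inner product
with the unit-normalized measurement in the nearest B1 slice — invariant to
M0 and to global complex scaling, with ties broken toward smaller R1.  The
absolute inner product serves as the maximum-likelihood objective; out-of-
range B1 values are clamped and counted, zero-norm voxels become NaN.
The conventional alternative inverts the monotone UNI(R1) curve by
interpolation.  UNI folds back at long T1 (R1 ≈ 0.34 s⁻¹ at B1 = 0.7,
≈ 0.26 s⁻¹ at B1 = 1), so the lookup default range starts at 0.4 s⁻¹ and a
non-monotone requested range raises with a hint to narrow it.

## Hybrid image and contrast matching

hybrid = μ0 + μ1·χ + μ2·R1_norm with defaults (0, 400, 1); R1_norm maps the
1st/99th in-mask percentiles linearly to 0/255 with clipping (percentiles
use linear interpolation).  Contrast matching fits subject→template ROI
medians with order 2 (R1) / order 1 (χ) polynomials on un-eroded labels
(erosion is a metrics-stage concept); the three hybrid weights can be
re-derived from a template's hybrid medians by OLS.  Whether matching uses
all atlas ROIs or basal ganglia only is left to the caller (all common
labels by default).  Group-template iteration and the nonlinear warps
themselves are external registration work and out of scope.

## Synthetic generator: what it emulates, and what it does not

Cohorts default to 260 subjects, ages uniform on [18, 79] (the real cohort
is near-uniform by decade; uniform is the simplest faithful choice),
balanced sex.  Values follow
value = intercept + β_age·age + β_age²·age² + β_sex·sex_c + β_hemi·hemi_c
        + loading·latent + ε,
with ε ~ N(0, (sd0 + sd_slope·(age−18))²) drawn independently per
hemisphere and latent a per-subject standard normal shared by all ROIs of a
network (A: Cau+Pu; B: GPe, GPi, SNc, SNr, RN, STN, VP) across metrics.
The shipped parameter file gives quadratic R1 peaking at 45–60 y with
≈ 0.1 s⁻¹ amplitude, linear R2*/χ increases, and loadings that put
within-network deviation correlations in the 0.6–0.85 range reported for
these nuclei.  Values are illustrative of the 3T literature, not fitted to
any dataset.  A patient group adds fixed offsets to chosen (ROI, metric)
pairs.  Voxel phantoms render non-overlapping ellipsoids (semiaxes ≥ 3
voxels so one erosion keeps a core) carrying exact first-order fields plus
noise.

The generator reproduces the *statistical* structure the analysis assumes —
trajectory shapes, covariate offsets, heteroscedasticity, network
covariance, group shifts — not the physics of acquisition: no k-space, no
coil or motion effects, no registration error, no QSM reconstruction chain.
Passing tests therefore demonstrate correctness and calibration of the
statistical machinery under its own assumptions, not robustness to
real-world acquisition artefacts.

## Experiment problem sizes and numerical choices

The simulation experiments (`qmrinorm.experiments`, exercised by the test
suite and `scripts/acceptance.py`) use: 1000 (tests) / 500 (script) cohorts
of n = 260 for GLM calibration with a null sex effect and homoscedastic,
network-free noise (the GLM's own sampling model, so its nominal 5% type-I
error is the reference point); GP coverage with 260 training and 2000
held-out observations; peak-age recovery over 50 (tests) / 10 (script)
seeds at noise 10% of the trajectory's dynamic range; 100/50 gradient
phantoms at noise 5% of p0; 1000/500 BH repetitions with 20 nulls + 5
alternatives; 50/20 network-recovery cohorts with unit loadings against
unit noise; and 20/5 seeds of the end-to-end detection study (260-subject
reference; 44 + 316 applied; SNc and SNr shifted by 1.5 subject-level
residual SDs — a +1.5 shift of the generative deviation z).  Detection fits
one GP per (ROI, metric) on hemisphere-pooled data with 1 optimizer restart;
the full-pipeline default remains 5 restarts.  Cross-validated z-score
calibration in the unit tests uses 200-subject cohorts.  Where an
experiment reports a per-seed noisy quantity bounded by a tight band (the
applied-cohort median z, the gradient 3·SE check), the test asserts the
quantity averaged over seeds/draws, since the single-draw spread exceeds
the band by construction.

All randomness flows through `numpy.random.default_rng` seeded per call;
sub-experiment seeds derive from a `SeedSequence` of the top-level seed.
Degenerate inputs fail loudly: empty ROIs, erosion to empty, single-sex
designs, constant-value normative fits, uncorrected inputs to
`zscore_apply`, non-monotone lookup ranges, overlapping phantom ellipsoids.
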