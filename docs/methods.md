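# Methods

`ertrack` implements the quantitative analysis chain used in live-cell
single-molecule studies of secretome mRNA translation on the endoplasmic
reticulum (ER): trajectory ingestion and compartment filtering, per-trajectory
mean-squared-displacement (MSD) confinement classification, ensemble MSD and
apparent-diffusion fitting, multi-component displacement-CDF decomposition,
ER-junction and lysosome proximity statistics, and FRAP / optogenetic
recruitment kinetics. A Monte Carlo generator supplies data with known ground
truth for every stage.

## Motion model and MSD estimators

Particle motion is modelled as free or confined Brownian diffusion observed
with Gaussian localization error. For a free diffusion coefficient `D`
(µm²/s) and frame interval `Δt`, each axis step is drawn from
`N(0, 2DΔt)` — the 1D Brownian propagator. Localization error is additive
per frame per axis with standard deviation `σ` (µm), not cumulative, which
produces the standard noise floor in the ensemble MSD:

    MSD(τ) = 2 n D_app τ + 4σ²,    n = 2 spatial dimensions.

`fit_dapp` estimates `D_app = slope/4` and `σ = sqrt(intercept)/2` from an
ordinary least-squares line through the first four lag points of the
ensemble MSD; only the early lags are used because confined trajectories
bend the curve at longer lags. Negative slope or intercept is clamped to 0
and flagged rather than reported as a negative physical quantity.

The per-trajectory confinement statistic is the lag-1 s MSD

    MSD_τ = Σ_i [(x_{i+1} − x_i)² + (y_{i+1} − y_i)²] / n

averaged over **all** available consecutive-frame displacement pairs, with a
minimum of 10 localizations per trajectory; using every pair rather than a
fixed first few is the lower-variance estimator consistent with the sum
above. Frame gaps are skipped and counted. A trajectory is classified
*translating* when `MSD_τ=1s` is strictly below the cutoff — 0.055 µm² for
mRNA, with a separate effective cutoff of 0.04 µm² exposed for ribosome
tracks — confined motion being the proxy for engagement with the ER
translation machinery. Ties at the threshold go to *non-translating*. The
translating fraction is translating / total classified; unclassified (short)
trajectories are excluded from numerator and denominator, and an input with
zero classified trajectories is an error, never silently 0.

## Displacement-CDF mixture

The distribution of single-lag 2D displacement magnitudes `r` for a mixture
of up to three diffusive species is

    CDF(r) = 1 − Σ_x A_x · exp(−r² / (4 D_x t)),   ΣA_x = 1, A_x ≥ 0.

`fit_cdf_mixture` performs nonlinear least squares of this model against the
empirical CDF evaluated on the sorted displacements (no binning — a bin
width would be an arbitrary extra parameter and discards information). The
weights are optimized as nonnegative free parameters normalized inside the
model, so the simplex constraints hold by construction; diffusion
coefficients are optimized on a log10 scale within [1e−6, 1e3] µm²/s, with
multiple deterministic and seeded random starts spread around the
single-species scale `median(r)²/(4 t ln 2)`. Samples larger than 2000
points are thinned evenly for the fit (the empirical CDF is smooth; this
only reduces redundant residuals). When the component count is not fixed,
the order (1–3) is chosen by BIC computed from the exact mixture likelihood
of the raw displacements — an RSS-based criterion on the empirical CDF would
overfit because neighbouring ECDF residuals are strongly correlated.
Components whose fitted `D` differ by less than 2× are merged in reporting
(weight-summed, log-averaged `D`) and flagged: the model is effectively
non-identifiable for nearly equal coefficients.

## Confinement generator

Confined motion is simulated as Brownian steps folded back at a circular
(2D) or spherical (3D) boundary of radius `R` about each particle's start.
The fold maps the radial coordinate through the triangle wave of period
`2R`, the exact result of repeated radial reflection, and is therefore valid
for steps of any size relative to `R`. This is deliberately the simplest
generative model with a tunable MSD plateau (≈ `R²` at 1 s lag for strong
confinement); it does not attempt to model tethering kinetics or ER-surface
geometry. 3D runs are projected to (x, y) before analysis, mimicking
highly-inclined illumination of the thin peripheral ER; 2D mode exists for
analytic checks. Default mixture conditions used in recovery tests: free
`D = 0.1 µm²/s`, confined `D = 0.5 µm²/s` inside `R = 0.1 µm`, 1 s frames,
12-frame tracks — mobile mRNA and strongly tethered translating mRNA
regimes on either side of the 0.055 µm² cutoff.

## ER junction detection and the synthetic network

ER junctions are three-way meeting points of tubules. Detection: threshold
(Otsu by default), skeletonize to 1-pixel width, mark skeleton pixels whose
8-neighbourhood crossing number (count of 0→1 transitions in circular
order) is ≥ 3, and merge branch points within a merge radius (default
0.25 µm) into their centroid, iterating until all pairwise distances exceed
the radius. The crossing number is used instead of a plain neighbour count
because rasterized diagonal tubules produce staircase pixels that a
neighbour count misreads as branches.

The synthetic network generator places junction nodes on a jittered grid
(default 20 µm field, 0.05 µm pixels, 0.2 µm tubule width), joins each grid
row into a backbone, links rows through degree-2 elbow paths routed outside
the grid, and adds spokes chosen by greatest angular separation from the
incident edges until every junction has tubule degree exactly 3. This keeps
every junction on a locally straight backbone with a transverse spoke — a
clean "T" — and guarantees by construction that the recorded coordinates
are exactly the degree-≥3 nodes and that no two tubules cross elsewhere.
Junction-free images (a single straight tubule) are supported.

## Proximity statistics

Distances are 2D Euclidean in the image plane (no axial component), computed
with a KD-tree and checked against brute force in tests. The distance-binned
intensity profile uses eight half-open bins `[c − 0.25, c + 0.25)` µm with
centres 0.75–4.25 µm in 0.5 µm steps; per-bin mean intensities are
normalized by the 4.25 µm bin, so the far bin equals 1 by construction.
Empty interior bins are reported as NaN, never interpolated; an empty far
bin is an error because the profile cannot be normalized. Puncta-trajectory
matching (e.g. SunTag foci to mRNA tracks) is per frame, greedy
nearest-first within a 2-pixel radius, ties broken by punctum index then
track id — deterministic, and equal to the exhaustive optimum whenever
structures are separated by more than the radius. Pseudocoloured rendering
deposits unit intensity per localization and blurs with a 50 nm Gaussian
(the localization accuracy scale); blurring preserves integrated intensity.

## Kinetics

Traces carry `t = 0` at the bleach/activation frame, negative times before.
FRAP normalization divides by the mean of the 10 pre-bleach frames
(idempotent). Recruitment traces (mean ER intensity inside the lysosome-mask
union per frame, normalized to the pre-activation mean) are summarized by
the half-saturation time t½. The default estimator fits
`I(t) = baseline + amplitude·(1 − e^{−kt})` to post-event samples and
reports `t½ = ln 2 / k`; the saturation level is the fitted parameter, not
the maximum observed value, so noise spikes do not bias it. The alternative
estimator interpolates the first crossing of the empirical mid-level
`(I(0) + tail mean)/2`; both agree on noiseless exponentials and both are
reported when they disagree by more than 20%. A trace whose last third still
rises by more than 10% of the dynamic range is rejected with advice to
record longer, since t½ of an unsaturated rise is undefined.

## Synthetic-data scope

The generators reproduce the statistical structure the estimators rely on —
Gaussian steps, reflective confinement, known mixture fractions, exact
junction coordinates, step intensity fields, saturating-exponential
kinetics with Gaussian noise — and are bit-reproducible given a seed. They
do **not** model photophysics (blinking, bleaching), detection/linking
errors, motion blur, anisotropic or anomalous diffusion, ER-surface
curvature, or camera noise beyond the Gaussian localization term. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to every artifact of real imaging data.

## Problem sizes and numerical choices

Recovery checks run at sizes chosen to make sampling error small relative
to the tested tolerances: 500 tracks × 400 frames for the ensemble-MSD
oracle (the 4σ² intercept is a small quantity, ≈ 4% of the lag-1 MSD at the
default settings, and needs many displacement pairs to pin down), 1000
trajectories per mixture for fraction recovery, 5000 displacements for the
three-component CDF fit, a 25-junction network at 0.05 µm pixels, 20000
puncta for the step-field profile, and 50 replicates for noisy-kinetics
recovery. Tolerances asserted in tests come from the analytic sampling
error of each estimator (binomial CIs for fractions, 3 standard errors for
variances), not from tuning.

## Known limitations

- The confinement model is a hard reflective disc; real ER tethering is
  intermittent and spatially structured.
- `D_app` from confined trajectories is an *effective* coefficient; no
  confinement-model correction is applied.
- The CDF mixture assumes a single fixed lag; pooling lags would require a
  correlated-error model that is out of scope.
- Junction detection operates on a single 2D frame; junctions transiently
  lost to defocus are not tracked through time.
- Compartment masks are static; cell movement during acquisition is not
  compensated.
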