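# Methods

## Coordinate system and data model

All profiles are defined on 768 equidistant A-scan positions on the
peripapillary circle; sample *i* sits at angle `360·i/768`° in the
laterality-normalized TSNIT frame (0° temporal, 90° superior, 180° nasal,
270° inferior). Right-eye scans are stored directly in this frame; left-eye
scans are stored in native device orientation and mirrored about the
temporal–nasal axis (`out[i] = in[(768−i) mod 768]`, an involution) before
any cross-eye arithmetic. The analysis unit is the per-subject difference
profile `delta[i] = OS[i] − OD[i]` (µm, normalized frame) together with age
(years) and the signed interocular scanning-radius difference
`rd = radius_OS − radius_OD` (µm).

Under this sign convention a population in which right eyes are thicker has
a *negative* mean difference; the headline "right eyes 1.5 µm thicker"
appears as a global mean near −1.5 µm.

## Reliability filtering and missing data

A pair enters the analysis only if **both** eyes satisfy all three criteria,
each inclusive: signal quality ≥ 20 dB, ≥ 50 averaged B-scans, and a missing
or unreliable A-scan fraction ≤ 2.5%. Sub-threshold missing runs inside
passing scans are filled by linear interpolation around the circle (the
profile is periodic, so gaps across the temporal seam are interior gaps);
non-missing samples are never altered. Pairs with only one reliable eye are
excluded and counted.

## Pointwise testing and empirical bands

At each location a two-sided one-sample t-test of the difference against
zero is computed (equivalent to the paired test on the two eyes); p-values
are Bonferroni-multiplied by the fixed factor 768 and capped at 1, with
zero-variance locations flagged degenerate and reported as p = 1 rather
than dropped, keeping the adjustment conservative. The global difference
averages each subject's 768 locations first, then tests that scalar.
Empirical quantile bands use linear interpolation of order statistics
(type-7), the numpy default; the convention matters little at cohort sizes
in the hundreds and is stated here because reimplementations often differ
in the tails.

## Bundle peaks

Each eye's normalized profile is smoothed by a circular moving average of
±12°. The window includes every sample whose angular distance to the
center is at most the halfwidth: `floor(12 / 0.46875) = 25` samples per
side, 51 in total. The superotemporal peak is the maximum of the open
superior half-circle (0°, 180°), the inferotemporal peak the maximum of
(180°, 360°); ties break toward the smaller angle and a flat half-circle is
flagged degenerate rather than assigned an arbitrary peak. The interpeak
angle is measured through the temporal pole, `sup + (360 − inf)`, so a
larger value means bundles spread further from the temporal axis — this
makes interocular interpeak comparisons directly interpretable. Population
statistics are paired OS−OD shifts with t-tests; the variance of the
interpeak-angle difference explained by the radius difference is the R² of
the simple linear regression, which for a single regressor coincides with
the one-way analysis-of-variance fraction. Peak-shift differences are
folded into (−180°, 180°] as signed circular differences.

## The normative engine

Per location, the difference is Gaussian with

- `mu = beta_mu · (1, a, a², a³, r, r², r³)` and
- `log sigma = beta_logsigma · (1, a, a², a³, r, r², r³)`,

where `a` and `r` are age and signed radius difference, centered and scaled
by cohort constants stored in the atlas (raw powers after standardization;
orthogonal polynomials would fit identically but make stored coefficients
harder to port). The log link guarantees positive sigma for any
coefficient values. Each of the 12 optional terms may enter or leave,
giving 4096 candidate models enumerated in a fixed lexicographic bit order;
the candidate minimizing `AIC = 2k − 2·loglik` (k = number of coefficients,
intercepts included) is selected independently at each location — no
spatial coupling, exactly one model per location. AIC ties within 1e−8
break toward fewer parameters, then enumeration order, for determinism.

Fitting maximizes the exact likelihood by alternating (i) an exact
weighted-least-squares update of the mean coefficients given sigma and
(ii) a Fisher-scoring update of the log-sigma coefficients using the
constant expected information `2·Xsᵀ Xs`, step-halved until the likelihood
does not decrease. Both steps are monotone, so the iteration converges
deterministically from its OLS initialization (mean = OLS fit, log-sigma
intercept = log residual RMS); convergence is declared when successive
log-likelihood changes fall below 1e−10, with one deterministically
jittered restart before a fit is flagged non-converged. Non-converged
candidates are skipped and counted during selection; a location where no
candidate converges falls back to an intercept-only fit and is flagged.
Agreement of the achieved maxima with an independent quasi-Newton
optimizer is verified in the test suite to ~1e−12.

The assembled atlas stores, per location, the term mask, coefficients,
log-likelihood, AIC and convergence flag, plus the standardization
constants, training covariate ranges, a coordinate-convention tag and
provenance metadata, serialized as JSON with full float precision so that
save → load → predict is bit-identical. Quantile prediction is
`mu + sigma·Φ⁻¹(p)` at the nearest grid location; queries outside the
training covariate range are answered but carry an extrapolation warning.

A separate first-stage screen fits, per location, the 4×4 grid of
{none, age, |rd|, both} linear mean/variance models and records the
AIC-best label — a cheap map of *where* covariates matter, independent of
the exhaustive second stage. The screen uses the absolute radius
difference; the full engine uses the signed one, whose polynomial basis
subsumes magnitude effects through even powers.

## Synthetic cohorts and their oracle

The generator emulates the statistical structure the analysis assumes. Per
subject: age uniform over the configured range (the simplest adequate
stand-in for a decade-stratified population survey; configurable), radius
difference Normal(0, 30 µm) truncated at ±4 SD so that dispersion-field
positivity can be validated on a bounded covariate box. The right-eye
profile is a baseline plus two wrapped-Gaussian bundle humps (defaults:
62 µm baseline; humps of 75/80 µm at 70°/290° with 26° width — a realistic
double-hump profile with peaks near 140 µm); the left eye takes the same
shape with hump centers displaced by the configured interocular peak
shifts, plus a structured difference field drawn per location as
`m(θ,a,r) + s(θ,a,r)·Z`, plus independent per-sample measurement noise
(2 µm) in each eye. Hence the exact generating law of the difference is

    mu(θ,a,r)    = base_shifted(θ) − base(θ) + m(θ,a,r)
    sigma(θ,a,r) = sqrt(s(θ,a,r)² + 2·noise_sd²)

which `true_normative` returns — the oracle all recovery and coverage tests
compare against. Mean/SD fields and their per-year and per-µm modulations
are smooth angular fields (constant + wrapped-Gaussian bumps + harmonics),
JSON-serializable for reproducible configuration files. `s` is affine in
the covariates under the default identity link; the optional log link makes
log-sigma exactly linear in the covariates, which is the representable
truth used by the recovery and calibration studies. The covariate
reference point is the age-range midpoint and rd = 0.

The study-scale defaults place a +11 µm superonasal and a −10.5 µm nasal
bump on the mean-difference field with its circular average pinned at
−1.53 µm, dispersion largest at the two bundle humps (~6 µm SD vs ~1.8 µm
temporally), left-eye peak shifts of +1.55° (superior, nasal) and +4.42°
(inferior, temporal), and age/radius modulations concentrated around the
bundles with a region temporal to the inferior bundle where eyes grow more
alike with age. Population studies report most of these patterns
graphically rather than numerically, so the defaults are chosen to be
qualitatively comparable, not matched; per-location SD magnitudes in
particular are a judgment call.

What the generator does **not** emulate: OCT speckle and segmentation
failure modes, disease (glaucomatous thinning), spatial correlation of the
difference field along the circle (locations are conditionally
independent), age-stratified sampling, and any non-Gaussian tail behavior.
Passing recovery and coverage tests therefore demonstrate correctness of
the estimation machinery under the stated model class, not the adequacy of
that class for any particular clinical population.

## Verification study sizes and numerical choices

The acceptance studies run at desk scale, chosen to balance statistical
resolution against a single-core run of minutes: parameter recovery uses
cohorts of 2000 subjects with full 4096-model selection at 16 evenly
spaced locations over 5 seeds (3×3 covariate grid at ages 30/49.5/69 and
rd −30/0/+30 µm, 10% relative tolerance on both mu and sigma); coverage
calibration trains on 500 subjects with the degree-1 candidate basis at
all 768 locations and evaluates ~20,700 held-out differences per tail;
family-wise error uses 200 null cohorts of 100 subjects. The two-point
closed form (mu = 1, sigma = 1, AIC = 4 + 2(1 + log 2π) ≈ 9.6758) checks
the MLE variance convention (divisor n, not n−1).

Degenerate inputs are handled explicitly rather than silently: zero-
variance responses and exact mean fits raise; flat half-circles flag
degenerate peaks; zero-variance locations flag degenerate tests. Floating
sums over locations are computed in fixed index order, which is why
eye-swap antisymmetry holds bit-exactly, not just approximately.

## Known limitations

- Norms are only as good as the Gaussian location-scale class; heavy tails
  or skew in real difference distributions would distort extreme
  percentiles precisely where clinical interest is highest.
- Locations are modeled independently; no information is pooled along the
  circle, so per-location coefficient maps are noisier than a spatially
  smoothed alternative would be (a deliberate match to the per-location
  design, not a statistical optimum).
- The scanning radius is consumed as given; its estimation from device
  focus settings, and any error in it, are upstream of this package.
- The CSV reader expects the documented schema; no proprietary OCT formats
  are parsed.
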