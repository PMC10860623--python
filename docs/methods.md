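# Methods

This note documents the models implemented in `betakin`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Spectral model

Each sensor site is a pair of orthogonal planar-gradiometer-like channels.
Per channel the power spectral density is estimated with Welch's method:
non-overlapping 1024-sample Hamming windows, density scaling, trailing
partial segment dropped (a 180 s recording at 600 Hz gives 105 segments and
a 0.586 Hz grid). The site-level spectrum is the vector sum
PSD_vec = √(PSD₁² + PSD₂²), which makes the measure invariant to the
orientation of the underlying source relative to the two gradiometers.

The spectrum is modelled as an aperiodic background plus periodic
(oscillatory) peaks. The background is a fixed-mode power law,

    log10 P(f) = offset − χ · log10 f,     2 ≤ f ≤ 48 Hz,

with no knee and no explicit peak model. It is fitted robustly: an
ordinary least-squares fit in log-log space, followed by one refit that
excludes bins whose *positive* residual exceeds 2.5 residual standard
deviations. Oscillatory peaks sit above the background, so this one-sided
trimming suppresses their leverage while leaving a noiseless power law
fitted exactly (machine precision; verified against a two-point analytic
solve). The 2.5 SD cut is a conventional outlier threshold; the unit tests
check that a synthetic 20 Hz peak moves the fitted exponent by less than
0.05. Multi-peak Gaussian decomposition is deliberately out of scope: the
downstream phenotypes need only the background parameters and the residual.

The periodic profile is the linear-unit residual P(f) − 10^offset·f^(−χ).
Its beta-band summary uses the signed residual for peak finding (argmax
over 14–30 Hz, reported only if positive) and the zero-clipped residual
for the band AUC (trapezoidal rule): power is nonnegative by definition,
but clipping before peak finding would invent peaks in noise troughs.
Offset units are log10 of (signal unit)²/Hz; with signals in T/cm the
study-like operating point is near −23.

Channel selection over an ROI of candidate pairs is automated: mode
`rest-peak` takes the pair with the largest periodic beta peak at rest;
mode `modulation` takes the pair whose beta residual drops most from rest
to a movement condition (a stand-in for selecting the movement-modulated
frequency by visual inspection). Ties break to the lowest pair index so
selection is deterministic.

An optional zero-phase Hamming-window FIR bandpass (2–48 Hz) is provided
but off by default in the pipeline: the synthetic generator is already
band-limited, so the filter would only add edge transients.

## Beta-event model

Events are defined on a narrow-band amplitude envelope. The channel pair
is polyphase-resampled to 200 Hz and high-pass filtered at 2 Hz
(zero-phase 4th-order Butterworth). A complex Morlet bank spans 7–47 Hz in
1 Hz steps with n_cycles = f/2 (constant ~80 ms temporal sigma);
magnitudes are averaged over the grid frequencies within ±1.5 Hz of the
subject's peak beta frequency and combined across channels by vector sum,
giving one nonnegative envelope. The envelope is smoothed with a Gaussian
kernel of 100 ms FWHM (σ = FWHM / 2√(2 ln 2), reflected edges; kernel
shape is otherwise unspecified in the event literature and Gaussian is the
standard choice). The event threshold is the 75th percentile of the full
smoothed envelope (linear-interpolation percentile; at ~36,000 samples the
percentile convention is numerically irrelevant but it is fixed and
documented). Maximal runs of samples *strictly above* the threshold
lasting at least 50 ms (10 samples at 200 Hz, ≥ after rounding) are
events; events touching the recording edges are kept.

Per recording, ten phenotypes: mean, median, population SD and robust
maximum (mean of the top ⌈0.05·n⌉ values) of event duration and of event
amplitude; the event rate (count / recording duration); and the
waiting-time dispersion C_V = σ/μ. Event amplitude is the within-event
envelope maximum by default (`amp_measure="mean"` is available). Waiting
times are offset→next-onset gaps by default (`gap_mode="onset_to_onset"`
is available); population (ddof 0) SDs are used throughout for internal
consistency with C_V's σ. With fewer than two events the dispersion is
undefined (NaN); with none, all summaries except the zero rate are NaN.

### What a relative threshold can and cannot recover

A fixed-percentile threshold pins the total supra-threshold time at
exactly 25 % of the recording, so the event *count* is approximately
0.25·T divided by the mean detected-event duration. Consequently the
detected rate saturates near 1/s for stationary inputs across a wide range
of true burst rates (simulations here: true 0.5→1.5/s gives detected
1.16→0.95/s). At the study-like operating point — burst occupancy ≈ 26 %,
just above the 25 % exceedance — counts are faithful (detected
1.00–1.07/s at true 1.0/s), and with highly prominent bursts >90 % of
detected events coincide with planted bursts. The narrow between-subject
range of event rates reported for real recordings is consistent with this
property of the definition. Users comparing groups on the event-rate
phenotype should keep in mind that it compresses true rate differences.

## Heritability model

Phenotype vector y over n siblings in F families: y = μ1 + g + e with
cov(g) = σ²_g·R and cov(e) = σ²_e·I, where R is block diagonal with ones
on the diagonal and the full-sibling coefficient of relationship 0.5
within families. Heritability is h² = σ²_g/(σ²_g + σ²_e). Dominance and
shared-environment components are not modelled (genetic vs residual only)
— a stated limitation; with sibling data alone the shared-environment and
genetic contributions are confounded, and the permutation null tests
family aggregation, not its mechanism.

Estimation is maximum likelihood (REML is available as an option; the
permutation null makes significance robust to the choice). The fit
exploits the family-block structure in closed form: for a given h², the
per-unit-variance block covariance is C = (1 − h²/2)I + (h²/2)J, whose
inverse and determinant are analytic (C⁻¹ = [I − b/(a+mb)·J]/a with
a = 1 − h²/2, b = h²/2, m the family size), and the intercept and total
variance have closed-form profile solutions. The profile log-likelihood
is evaluated on an h² grid of step 10⁻³ over [0, 1] — the likelihood is
bounded and smooth there, so a grid argmax plus parabolic refinement is
globally reliable, sidesteps boundary-constrained optimizers, and
vectorizes across thousands of permutations. Unit tests verify equality
(|Δh²| ≤ 10⁻³) with an independent brute-force 2-D grid search of the
exact Gaussian likelihood on small pedigrees, and agreement in expectation
with the ANOVA sib-ICC moment estimator (ĥ² = 2·ICC) on balanced designs.

Preparation follows pedigree-tool conventions: phenotypes with negative
median are multiplied by −1 (whether the original convention flipped
all-negative or any-negative phenotypes is not determinable; the
median-sign rule is the documented choice here, and h² is invariant to it
anyway); a rank-based inverse-normal transform with Blom offsets,
Φ⁻¹((r − 3/8)/(n + 1/4)), is available as a separate mode. Missing values
drop the subject for that phenotype only; singleton families still inform
the mean and total variance. A zero-variance phenotype is flagged
degenerate rather than fitted.

Significance: the family labels are reshuffled uniformly (equivalently,
subjects are permuted across the fixed family blocks) n_perm = 6,000
times; k counts permutations whose fitted h² is ≥ the observed h² — ties
included, so an observed h² of 0 gives k = n_perm and p = 1 — and
p = k/n_perm. Nothing prevents a permutation from reconstituting an
original sibship, which if anything is conservative. The observed
statistic inside the permutation test uses the same grid-resolution
estimator as the permuted ones so that ties are exact. Bonferroni
correction over the 30-test battery declares significance at
p < 0.05/30; adjusted p = min(1, 30p). Effect sizes are single-group
Cohen's D = M/S on the (sign-flipped) feature scale.

### Null calibration of the permutation p

Under a true h² of zero the boundary-constrained estimator returns exactly
0 for about half of cohorts, and those cohorts get p = 1 exactly. The
p-value distribution is therefore *valid but superuniform*: P(p ≤ x) ≤ x
for all x, with an atom of mass ≈ 0.5 at p = 1. It is not, and cannot be,
exactly uniform — a property of any one-tailed test of a
boundary-constrained statistic with ties counted as exceedances, not of
this implementation. The property suite asserts the two facts that do
hold: a one-sided Kolmogorov–Smirnov test finds no anticonservatism, and
p/(1 − q) is uniform conditional on a nonzero observed estimate (q the
boundary mass of the permutation null).

## Synthetic-data generator

The generator defines the study conditions for all tests.

Pedigree: 100 families — 91 with two siblings, 8 with three, 1 with four —
totalling 210 subjects; arbitrary sibship lists are supported.

Phenotypes: y_i = mean + g_i + e_i with g_i = √0.5·a_fam + √0.5·a_i,
a ~ N(0, h²V_p), e ~ N(0, (1−h²)V_p), giving sib covariance 0.5·h²·V_p
exactly and independence across families.

Signals: per subject a two-channel, 180 s, 600 Hz pair. The aperiodic
background is Gaussian noise shaped in the frequency domain so its
one-sided PSD is 10^offset·f^(−χ) exactly in expectation (amplitude
∝ f^(−χ/2), DC bin zeroed); each channel gets an independent background.
Bursts arrive as a homogeneous Poisson process (overlaps sum linearly —
the observed waiting-time dispersion ≈ 1 is consistent with near-Poisson
timing), each a Hanning-windowed sinusoid at the beta frequency with
random phase, projected into the two channels with fixed orthogonal
weights (cos θ, sin θ), θ = 45° by default so the vector-sum logic is
exercised nontrivially.

Defaults (the study-like operating point): offset −23 (log10 (T/cm)²/Hz),
exponent 1.05, beta frequency 20 Hz, burst rate 1.0/s. Burst amplitudes
are log-normal (median 6×10⁻¹², log-sigma 0.4): right-skewed, and sized so
that burst peaks stand a few-fold above the in-band background envelope
after wavelet filtering — note that a 200 ms burst is shorter than the
~500 ms Morlet support at 20 Hz, which attenuates its envelope relative to
stationary noise, so the raw amplitude must exceed the naive in-band noise
RMS by more than the target envelope ratio. Burst durations are log-normal
with median 200 ms and log-sigma 0.75, chosen so the simulated durations
carry study-like right skew (mean ≈ 265 ms vs median 200 ms) and burst
occupancy ≈ 26 % sits just above the 75th-percentile exceedance.

All randomness derives from one root seed; per-subject and per-phenotype
streams are split with `numpy.random.SeedSequence` keyed by a CRC32 of the
subject/phenotype label, so runs are bit-reproducible and any subject can
be regenerated in isolation.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: no sensor geometry or forward model (exactly one
channel pair per hemisphere-equivalent; ROI selection over 15 pairs is
exercised only on constructed profiles), no cardiac/ocular/movement
artifacts, no head-position effects or vendor artifact suppression, no
knee in the aperiodic spectrum, no task condition, no age/sex structure,
and phenotype distributions are Gaussian by construction whereas several
real phenotypes are not (the inverse-normal mode exists for that reason).
Parameter-recovery results here certify the estimation machinery, not the
biology.

## Pipeline and sizes

`run_all` executes simulate → spectra → bursts → herit, persists every
stage as TSV/HDF5 and writes a manifest (config, package versions, output
SHA-256 hashes). The demonstration configuration uses 10 two-sib families,
30 s recordings and 200 permutations and completes in seconds; the
full-scale preset (`RunConfig.study()`) is 100 families / 210 subjects,
180 s, 6,000 permutations. Tests and the acceptance script use 200-cohort
ensembles for heritability recovery, 20 recordings for signal-level
recovery, and 5,000 families for the sib-correlation limit; these sizes
give Monte-Carlo standard errors comfortably below the tolerances they are
checked against.

## Known limitations

- Sibling-only relatedness (0.5): no half-sibs, twins, parents or
  genotype-based kinship; no covariates (none were applicable here).
- Single intercept mean model; no age/sex adjustment.
- The event-rate phenotype saturates under the relative threshold (above).
- The aperiodic fit is fixed-mode; spectra with a knee below 48 Hz would
  bias offset and exponent.
- ML variance components are slightly downward biased at n = 210 relative
  to REML; the boundary at h² = 1 additionally pulls high-heritability
  estimates down by ~0.01–0.03. Both effects are inside the recovery
  tolerances used here.
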