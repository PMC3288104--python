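# Methods

This note documents the models implemented in `gabashift`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Two-tissue-compartment model

The reversible 2TC model has tissue impulse response

    h(t) = K1/(α2 − α1) · [(k3 + k4 − α1) e^(−α1 t) + (α2 − k3 − k4) e^(−α2 t)],
    α(1,2) = ((k2 + k3 + k4) ∓ sqrt((k2 + k3 + k4)² − 4 k2 k4)) / 2.

For non-negative rate constants the discriminant is bounded below by
(k2 − k4)², so the eigenvalues are always real.  The tissue curve is the
convolution of h with the metabolite-corrected plasma input, evaluated in
closed form: exponential × exponential on the tri-exponential tail of the
fitted input, and exponential × linear-segment on the piecewise-linear
pre-peak portion.  (The pre-peak convolution admits an exact closed form
because the interpolated input is piecewise linear; a fine-grid numerical
convolution oracle in the test suite guards the whole expression to
<1e−4 relative error.)  The repeated-eigenvalue case (k3 = 0, k2 = k4) is
handled by the analytic limit C = K1[f(α) − (k3 + k4 − α) f′(α)], with the
derivative of the single-exponential convolution taken by central
difference (step 1e−6·α); the case has measure zero and the limit is
exercised explicitly in the tests.

**Frame prediction** is the interval average of the model curve over each
frame (8-point Gauss–Legendre per frame), not a midpoint evaluation —
emission data are acquired as per-frame integrals.  **Fitting** minimizes
Σ durationᵢ·(obsᵢ − predᵢ)² — weights equal to frame acquisition time,
with no count-rate term — by multi-start bounded least squares
(four starts: K1 ∈ {0.2, 0.5} crossed with uniform k-seeds {0.05, 0.2};
bounds K1 ∈ (0, 2], k ∈ (0, 1] min⁻¹ for numerical safety only) followed
by an unconstrained Levenberg–Marquardt refit from the best bounded
solution, whose result is final.  Convergence flags and weighted residual
norms are reported rather than silently repairing non-physical solutions.
V_T is always recomputed from the fitted rate constants, so the
`FitResult.vt == vt(params)` identity holds to machine precision.

Decay correction is assumed already applied to both plasma and PET data;
the module performs none.

## Input function

The parent fraction f(t) = a·exp(−b·t) + c and the tri-exponential tail
Σ Aᵢ·exp(−λᵢ(t − t_peak)) are both fitted by *separable* (variable-
projection) least squares: only the rates are nonlinear parameters, the
amplitudes (and plateau) being solved linearly at each step.  Multi-start
over log-spaced rate seeds protects against local minima; ties are broken
by the smallest rate-vector norm.  Rates are kept positive by optimizing
their logarithms; amplitudes are left free.  All plasma fits are
unweighted (frame-duration weighting applies only to the kinetic fit).

The peak is the sample-time maximum (earliest sample wins ties).  Before
the peak the measured samples are linearly interpolated — the bolus shape
is preserved rather than extrapolated from the tail.  AUC = pre-peak
trapezoid + Σ Aᵢ/λᵢ; clearance = dose/AUC, converted to L/h only at the
reporting layer.

The free fraction is the mean plasma ultrafiltrate/total ratio divided by
the mean saline ratio (filter-retention correction).  The correction
formula is a package choice — retention is measured in the assay protocol
but the combining rule is not standardized — so the uncorrected value is
returned alongside.

## Lassen analysis

Per subject, ordinary least squares of (V_T,base − V_T,post) on V_T,base
across the ten component ROIs; slope = ΔBP, x-intercept = V_ND estimate,
affinity shift = 1 − slope.  OLS (not orthogonal regression) matches the
study convention; ODR is available as an off-by-default option since both
axes carry measurement error.  Group results are unweighted means ± SD of
the per-subject fits — not a pooled regression.  A zero slope leaves the
x-intercept undefined (flagged NaN, excluded from the group x-intercept
summary); negative or >1 shifts are reported raw, never truncated.

## Group statistics

Paired two-tailed t-tests with paired-difference Cohen's d
(mean(base − post)/SD(base − post); an increase post-drug gives negative
d, matching the reporting convention).  Percent change is the mean of
per-subject ratios, deliberately not recomputable from group means.  The
repeated-measures ANOVA is the split-plot design with each
subject × condition *scan* as the experimental unit: condition is the
between-scan factor, region the within-scan factor.  This mirrors the
study's stated design even though condition is, strictly, within-subject;
a fully-repeated two-way alternative is provided and labeled as such.
The implementation delegates to `pingouin.mixed_anova`; an independent
sums-of-squares decomposition in the test suite verifies it to 1e−10.
The Kolmogorov–Smirnov normality pre-check for Pearson correlations uses
a normal reference with estimated (sample) mean and SD; no Lilliefors
correction, and no multiple-testing correction anywhere (uncorrected
α = 0.05).

## EEG time-frequency analysis

The Morlet parameter "7" is interpreted as ω₀, the carrier-to-envelope
ratio of mo(x) ∝ exp(−x²/2)·exp(iω₀x); the kernel amplitude is normalized
so a unit-amplitude sinusoid yields peak power 1 at every analysis
frequency (tested for frequency independence).  The printed wavelet
formula admits a reading where the constant is a prefactor; the ω₀
interpretation is the standard one and is configuration-exposed.  The 20
sub-bands spanning 14–80 Hz are linearly spaced (spacing unspecified in
the protocol; linear chosen, config-exposed), placing the "42 Hz" sub-band
at 41.79 Hz — the summary routine snaps to the nearest sub-band with a
warning.  Baseline correction subtracts mean pre-cue (−300…−100 ms) power
per channel and frequency; ratio correction is available by option.
Epochs are demeaned before the transform: the truncated kernel has
non-zero partial sums at the epoch edges, so a DC offset would otherwise
bleed into edge power.

Artifact rules reject a trial when any channel's within-epoch range
exceeds 200 µV or any consecutive-sample step exceeds 60 µV (strict
inequalities; the boundary values are kept).  ICA-based blink/ECG removal,
re-referencing, channel interpolation and montage handling are out of
scope — the module consumes cleaned epochs.

## Synthetic-data generator

The generator defines the study conditions the tests run under:

* **Plasma**: the parent curve rises linearly from 0 to a peak at 1 min
  (the bolus shape before the peak is not specified by the protocol;
  linear is this package's choice) and decays as three exponentials
  (defaults A = 8, 3, 1 kBq/mL; λ = 2.0, 0.3, 0.03 min⁻¹).  Totals are
  parent / parent-fraction with f(t) = 0.55·exp(−0.15 t) + 0.40, sampled
  every 6 s for 2 min then sparsely to 90 min (≈34 samples), metabolite
  fractions at the seven protocol times.
* **TACs**: forward 2TC prediction + 5% blood volume × total plasma +
  Gaussian noise with SD = noise_scale·sqrt(prediction/frame-duration) —
  a stand-in for counting statistics chosen to motivate the
  frame-duration weighting of the fit.  Default regional baseline V_T
  targets follow the high-dose-arm magnitudes (5.1–7.2 mL g⁻¹ across the
  ten ROIs, K₁ 0.26–0.42 mL g⁻¹ min⁻¹, k₄ = 0.1 min⁻¹, V_ND = 1 mL g⁻¹);
  the pons is simulated with k₃ = 0 (pure nondisplaceable uptake).
* **Affinity shift**: the post-drug scan scales k₃/k₄ by the shift s —
  implemented as a *decrease in k₄*, the affinity interpretation — with
  K₁ and k₂ untouched, so V_T,post = V_ND + s·(V_T,base − V_ND) holds
  exactly before noise.  Cohort runs draw per-subject shifts from
  N(group mean, 0.1); group means are 1.0 (low-dose regime) and 1.27
  (high-dose regime).
* **EEG**: pink (1/f) noise of 10 µV SD plus a Hann-windowed 42 Hz burst
  confined to 500–1500 ms post-cue with an independent uniform phase per
  trial (induced, not evoked), amplitude 1 µV (low-control) vs 2 µV
  (high-control), 70%/30% low/high trial mix.  In cohort runs the
  high-condition amplitude grows with the subject's true shift so a
  PET–EEG correlation exists by construction.

Everything is driven by `numpy` `SeedSequence`-derived streams; identical
seeds give bit-identical outputs.

What the generator does *not* emulate — and hence what green tests do not
establish about real data: scanner effects (attenuation, scatter, motion,
reconstruction artifacts), non-Gaussian counting noise at low counts,
plasma dispersion/delay between sampling site and brain, regional
heterogeneity of the affinity shift, metabolite-fraction measurement
error, and realistic EEG artifact topographies or volume conduction.

## Problem sizes and runtimes

Simulation-based checks use sizes that keep the full suite to a few
minutes on one core: 100-draw sweeps for the forward-model oracle,
20 noiseless + 100 noisy fits for parameter recovery (noise calibrated so
the four 15 s frames have ≈10% coefficient of variation), 1000
simulations for the Pearson type-I-error check, 100–200 trials for EEG
properties, and 2–9 subject cohorts for pipeline runs.  A nine-subject
end-to-end run takes under two minutes.

## Known limitations

* B_max and K_D are never separately estimated — only composite outcome
  measures (V_T, BP_P, BP_ND, affinity shift) are identifiable here.
* No reference-tissue or graphical (Logan) V_T estimation; no voxelwise
  fitting.
* The unconstrained final refit can, on pathological noisy data, return
  parameters outside physiological ranges; diagnostics are reported
  rather than constraints imposed.
* Whether published free-fraction values include the saline retention
  correction is ambiguous; both corrected and raw values are returned.
* The x-intercept of a near-zero-slope Lassen fit is numerically
  unstable; consumers should check `x_intercept_defined` and the slope SD.
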