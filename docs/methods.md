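# Methods

## The measurement model

An ERG electrode sums the extracellular response of many photoreceptors.
The analysis treats the eye as a small set of receptor classes whose
contributions mix additively in units of quantum catch: for a monochromatic
flash of quantal flux I at wavelength λ under adaptation state *a*,

    Q(λ, a) = I · Σ_i k_i(a) · R_i(λ; λ_max,i)

where R_i is a visual-pigment absorbance template and k_i(a) a
dimensionless, adaptation-specific scaling factor.  The voltage response is
assumed to be a single monotone function of catch that is common to all
stimuli of a session — this is what licenses the central trick of the
method: converting a monochromatic amplitude into the *equivalent intensity*
of white light that would have produced it, via the V-log(I) calibration,
cancels the response nonlinearity entirely as long as the calibration has
the correct shape.

### V-log(I) calibration

"Logarithmic model" is read as V linear in log10 intensity.  The
intensity axis is shifted so the weakest ladder step sits at x = 0 (the
axis-origin reading of "start at log(0)"); the fit is ordinary least squares
on the before/after-averaged ladder.  The inverse `x_eq = (V − b)/a` is
closed-form, which is why this parameterisation was preferred over fitting a
saturating curve.  Amplitudes outside the calibrated span are extrapolated
and flagged per data point, never rejected.

### Sensitivity and its normalisation

`S(λ) = 10^(x_eq(λ) − x_eq,max)` peaks at exactly 1 per individual.  The two
stimulus rounds are averaged on the amplitude scale *before* the intensity
transform (the alternative — transforming each round first — applies the
nonlinear inversion to noisier values; averaging first minimises that bias).
Ties at the maximum resolve to the shortest wavelength, with a warning.
Averages across individuals are arithmetic means with sample SD and are
**not** renormalised, so averaged maxima fall below 1.

Two consequences of this normalisation are worth knowing because they are
properties of the method itself, not bugs:

* **Peak-selection bias.**  Each individual's curve is divided by its own
  noisy maximum.  Where several grid wavelengths nearly tie at the peak
  (519/529/550 nm for a 527 nm pigment), the selected maximum is biased
  upward, so the averaged sensitivity near the reference peak is biased
  slightly *down* and scaling-factor ratios against it are biased *up*.
  The effect grows with the response-noise level; the test suite pins the
  mechanism by comparing against large-sample oracle simulations rather
  than against the noise-free curve.
* **Cross-receptor leakage in k_i.**  The LW template still contributes
  ~2% at the UV grid peak (358 nm), so measured k_UV ratios carry a small
  LW admixture even at zero noise.  The zero-noise invariants in the tests
  therefore compare against forward-algebra values that include this
  leakage, which the pipeline reproduces to 1e-8.

### Template fitting

The fitted template is a modified log-normal α-band,
`R(λ) = exp(−a·x²·(1 + b·x + c·x²))` with `x = log10(λ/λ_max)` and the
published constants a = 380, b = 6.09, c = 3b²/8; the two free parameters
are (λ_max, amplitude).  A free amplitude is required because averaged
curves peak below 1.  An optional β-band (A = 0.29, λ_m = 340 nm, a = 247,
b = 3.59) is off by default — for a UV pigment it would double-count the
main peak — and can be enabled for LW fits.  A Govardovskii-type A1
nomogram is available behind the same interface as an independent shape
family for robustness comparisons; it is not used for the headline numbers.

Fits are Levenberg–Marquardt least squares (lmfit) with a multistart every
10 nm across the λ_max bounds, keeping the best objective; the template is
mildly multimodal and a single start can stall on a shoulder.  Identical
inputs give identical fits.  Only wavelengths inside the bounds window
(UV: 300–450 nm, LW: 450–650 nm) enter each fit: receptors are estimated on
the adaptation state that isolates them, but dark-adapted data retain a
visible UV peak that a single LW template cannot represent, so windowing is
required for the single-receptor model to be well-specified.  The standard
error of λ_max comes from the local curvature of the solution, the residual
standard error is `sqrt(SSR/(n − 2))`, and the reported p-value is the
conventional parameter-significance t = estimate/SE — a fitting-machinery
convention, not a biological test.  The quoted ± values on fitted peaks are
these standard errors.

### Sex screen and pooling

Per adaptation state, a Kruskal–Wallis rank test (hand-implemented from the
rank formula with tie correction; chi-square reference, df = groups − 1)
compares per-individual sensitivities in each receptor's peak region
(529 nm under dark/dim adaptation; the mean of 352 and 358 nm under bright
green).  Pooling the sexes requires every screen to pass at α (default
0.05).  When a screen fails, per-sex fits are emitted with a warning.  A
`pooling` policy ("screen"/"always"/"never") exists because a correctly
calibrated screen still blocks pooling in a predictable fraction of
no-effect datasets, which Monte-Carlo studies of the pooled estimator must
bypass.

### Third-receptor scan

The qualitative question "is a blue receptor needed?" is made quantitative
as a nested-model comparison on the pooled residuals from all adaptation
states.  The two-receptor baseline refits the UV and LW template amplitudes
freely per adaptation (λ_max fixed at the fitted values; per-adaptation
amplitudes are needed because each averaged curve carries its own
normalisation).  The alternative adds one fixed-shape template with a
single non-negative amplitude shared across adaptations, profiled over
candidate peaks (default 400–500 nm in 5 nm steps; both fits are linear
least squares, so the profile is exact).  The best candidate is tested with
an extra-sum-of-squares F statistic (1 numerator df, proper residual df)
and the p-value is Bonferroni-corrected over the number of candidates so
the profiled test does not exceed its nominal size.  The scan's
`rse_two/rse_three` fields are RMS residuals with a common denominator n —
monotone for the nested pair by construction — while the textbook
`sqrt(SSR/(n−p))` can invert when the SSR gain is smaller than the df loss.

## The synthetic-data generator

`simulate_study` emulates the full stimulus design: an 8-step white ladder
(5.97e12–4.95e16 photons/cm²·s, log-spaced between the stated endpoints)
flashed before and after each series, two randomised rounds of 17
monochromatic wavelengths (334–649 nm) at 1.04e14 photons/cm²·s, three
adaptation states (dark; dim green 551 nm at 7e12; bright green 551 nm at
7e15 quanta/s/cm²), and 10 individuals per sex with no true sex effect.

The response world is deliberately self-consistent with the analysis: the
voltage is `V = max(0, a·(log10 Q − log10 Q_floor) + b + ε)` with
`Q_floor` the catch of the weakest white flash, so the calibration the
analysis fits is exactly the generating law and the whole pipeline is
invertible at zero noise.  An optional Naka–Rushton mode
(`V = Vmax·Qⁿ/(Qⁿ + Kⁿ)`) breaks that self-consistency on purpose: a
monotone response still preserves the position of the sensitivity maximum,
but the logarithmic calibration is then misspecified and fitted peaks
shift — a robustness probe, not a default.

Default parameters and why:

| parameter | default | rationale |
|---|---|---|
| UV / LW λ_max | 364 / 527 nm | the receptor pair the default study emulates |
| k_UV per state (dark/dim/bright) | 0.4 / 0.7 / 1.0 | UV anchored at bright green; partial expression elsewhere |
| k_LW per state | 1.0 / 0.35 / 0.02 | LW anchored at dark; bright green suppresses it to "minimal contribution" |
| slope a | 2.0 mV/decade | ~8 mV response at the brightest white flash, typical insect ERG scale |
| intercept b | 0.5 mV | small positive response at the weakest flash |
| white_catch_constant | 1e-3 | broadband light spread across the spectrum catches a small fraction per receptor; keeps mono responses above the floor |
| noise_sd | 0.25 mV | gives averaged-sensitivity SDs of roughly 10–20% of S at mid-sensitivity, a realistic ERG error-bar scale |
| n_per_sex | 10 | the dark-adapted cohort size of the emulated design |

What the generator does **not** emulate: raw voltage traces, electrode
drift, adaptation kinetics during the 15-min adaptation periods, the lamp's
actual spectrum (white light is a single flat-catch constant),
individual-to-individual parameter variation (all animals share one truth;
the only variation is response noise), or attrition of individuals between
adaptation states.  Passing tests therefore demonstrate that the analysis
inverts its own assumed measurement model at realistic noise — not that
those assumptions hold for any particular eye.

The response floor matters in one corner: under bright-green adaptation
with the LW receptor fully suppressed, long-wavelength flashes fall below
the zero-response floor (no depolarisation — the same regime the QC
exclusion rule targets at the whole-animal level).  Measured sensitivities
there saturate at the floor value, and the zero-noise invariants account
for it explicitly.

## Numerical choices and degenerate inputs

* LM tolerances are tightened to 1e-13 so zero-noise fits recover
  parameters to well under 0.01 nm.
* λ_max estimates at the fitting bounds are flagged, not fatal; their SE
  may be undefined (reported as NaN).
* Degenerate calibrations (one intensity, flat response) and all-zero
  monochromatic series raise typed errors.
* Scaling-factor peaks off the measured grid map to the nearest grid
  wavelength (recorded in metadata); linear interpolation is available as
  an option.
* Session files store floats via `repr`, so write→read→write is
  byte-identical.

## Problem sizes in the test suite

Monte-Carlo tests use 200 replicates for λ_max recovery, 1000 single-state
cohorts for the screen's type-I error, 200 + 100 replicates for the
third-receptor scan's size and power, and a 2000-individual oracle for the
cohort-averaging check; the full suite and the acceptance script each run
in a couple of minutes on one CPU.

## Known limitations

* The deposited-data adapter reads the package's own session dialect; the
  original acquisition files must be converted to amplitude tables first.
* No bootstrap or Bayesian uncertainty on λ_max; the curvature SE is the
  only uncertainty reported, matching the conventions of the emulated
  analysis.
* The scan assumes the third receptor's scaling is tied across adaptation
  states; a receptor that appears under only one adapting light would be
  tested with reduced power.
* The Kruskal–Wallis screen tests peak-region sensitivity only; a sex
  difference confined to spectral shape away from the peaks would pass it.
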