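# ergspectra

Electroretinogram (ERG) spectral-sensitivity analysis for compound eyes:
white-light intensity calibration, equal-quantal spectral series, opsin
template fitting across chromatic-adaptation states, and a statistical test
for an unmodelled receptor class.

## Who this is for

Visual ecologists and sensory physiologists who record ERG flash responses
from insect eyes and want to turn amplitude tables into receptor peak
sensitivities (λ_max), with the receptor classes isolated by coloured
adapting lights.  The package also ships a forward simulator of the whole
experiment, so every analysis stage can be validated against a known ground
truth before touching real recordings.

## The method

For each individual and adaptation state, the white-flash intensity ladder
(flashed before and after the spectral series, then averaged) defines a
V-log(I) calibration: with `x = log10(I) − log10(I_min)` the response is fit
as `V = a·x + b` by ordinary least squares.  Each monochromatic flash
amplitude (two randomised rounds at equal quantal flux, averaged per
wavelength) is inverted through this curve into an equivalent log-intensity
`x_eq`, and the spectral sensitivity is

    S(λ) = 10^(x_eq(λ) − x_eq,max)

so each individual's curve peaks at exactly 1.  After a per-adaptation
Kruskal–Wallis screen confirms no male/female difference, curves are pooled
and averaged, and a two-parameter visual-pigment template (modified
log-normal α-band; free λ_max and amplitude) is fit by multistart
Levenberg–Marquardt least squares — the long-wavelength (LW) receptor on
dark-adapted data, the UV receptor on bright-green-adapted data where the LW
receptor is suppressed.  Adaptation scaling factors

    k_i(adaptation) = S(λ_peak,i, adaptation) / S(λ_peak,i, reference_i)

anchor each receptor at the state that maximises it (LW → dark, UV → bright
green), and the summed model `M(λ) = Σ_i k_i·R_i(λ)` overlays every
adaptation.  An extra-sum-of-squares F scan over candidate blue templates
(400–500 nm, one shared amplitude, Bonferroni-corrected) quantifies whether
a third receptor is needed.

## Worked example

```python
from ergspectra import StimulusProtocol, StudyConfig, fit_study, simulate_study
from ergspectra.simulate import default_truth

protocol = StimulusProtocol()            # 17 λ, 8 white steps, 3 adaptations
truth = default_truth(seed=1)            # UV 364 nm + LW 527 nm, 10+10 animals
sessions = simulate_study(protocol, truth)
result = fit_study(sessions, protocol, StudyConfig(scan_third_receptor=True))

group = result.groups["pooled"]
for name in ("LW", "UV"):
    fit = group.fits[name]
    print(f"{name} lambda_max = {fit.lambda_max_hat:.1f} +/- "
          f"{fit.lambda_max_se:.1f} nm (RSE {fit.residual_standard_error:.3f})")
print(f"k_LW(dim green)    = {group.scaling.get('LW', 'dim_green'):.3f}")
print(f"k_LW(bright green) = {group.scaling.get('LW', 'bright_green'):.3f}")
print(f"third receptor detected: {group.scan.detected} "
      f"(p = {group.scan.p_value:.3f})")
```

prints

```
LW lambda_max = 528.7 +/- 1.1 nm (RSE 0.026)
UV lambda_max = 365.0 +/- 1.1 nm (RSE 0.039)
k_LW(dim green)    = 0.626
k_LW(bright green) = 0.021
third receptor detected: False (p = 1.000)
```

The fitted peaks recover the simulated 527/364 nm receptors to within about
one standard error; the scaling factors show the dim green adapting light
halving the LW contribution and the bright green light suppressing it to ~2%
(the dim-green value sits above the generating constant 0.35 because of a
known normalisation bias of the method, see `docs/methods.md`); and the
blue-receptor scan correctly finds no evidence for a third class.

The same analysis is available from the shell:

```
ergspectra simulate --seed 1 -o sessions.csv
ergspectra fit --sessions sessions.csv -o results/ --scan-third-receptor
ergspectra batch --replicates 50 --seed 0 -o batch.csv
```

Every command writes a JSON manifest (config snapshot, input digests, seed)
next to its outputs.

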