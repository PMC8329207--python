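"""Forward simulator for ERG spectral-sensitivity studies.

The simulated world is a compound eye containing a small set of receptor
classes whose contributions mix additively in the ERG.  For a monochromatic
flash at wavelength λ and quantal flux I under adaptation state *a*, the
effective quantum catch is

    Q(λ, a) = I · Σ_i k_i(a) · R_i(λ; λ_max,i)

where R_i is the receptor's absorbance template and k_i(a) the
adaptation-dependent scaling (anchored to 1 at the state maximising receptor
*i*).  White flashes catch Q = c_white · I through a single flat efficiency
constant (the lamp spectrum is not modelled).  The voltage response is

    V = max(0, a_V·(log10 Q − log10 Q_floor) + b_V + ε),  ε ~ N(0, σ²)

with Q_floor the catch of the weakest white-ladder flash, so the calibration
axis starts at zero at the weakest white intensity — the same logarithmic
form the analysis fits, making the pipeline exactly self-consistent at zero
noise.  An optional Naka–Rushton response mode (V = Vmax·Qⁿ/(Qⁿ+Kⁿ))
exercises the analysis against a saturating physiological nonlinearity.

All randomness (response noise, flash-order permutations) flows from a single
seed through one generator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .protocol import StimulusProtocol
from .sessions import ERGSession
from .templates import OpsinTemplate, template_sensitivity


@dataclass(frozen=True)
class Receptor:
    """One simulated receptor class."""

    label: str
    lambda_max: float              # nm
    backend: str = "stavenga"
    beta_band: bool = False

    def template(self) -> OpsinTemplate:
        return OpsinTemplate(lambda_max=self.lambda_max, amplitude=1.0,
                             backend=self.backend, beta_band=self.beta_band)


@dataclass(frozen=True)
class GroundTruth:
    """Everything the simulator needs to generate a study.

    ``ki`` maps receptor label -> adaptation label -> scaling factor; each
    receptor with an entry in ``reference_map`` must have k = 1 there.
    """

    receptors: tuple[Receptor, ...]
    ki: Mapping[str, Mapping[str, float]]
    reference_map: Mapping[str, str | None]
    vlogi_slope: float = 2.0            # mV per log10 unit
    vlogi_intercept: float = 0.5        # mV at the weakest white flash
    white_catch_constant: float = 1e-3  # catch efficiency of white light
    noise_sd: float = 0.25              # mV, additive response noise
    n_per_sex: int = 10
    seed: int = 0
    response_mode: str = "log"          # "log" | "naka_rushton"
    nr_vmax: float = 9.0                # mV; Naka–Rushton mode only
    nr_exponent: float = 1.0
    nr_half_catch: float | None = None  # default: mid white-ladder catch
    #: λ_max shift (nm) applied to male individuals' receptors; 0 = no
    #: sex effect (used to construct positive controls for the sex screen).
    male_lambda_shift_nm: float = 0.0

    def __post_init__(self):
        if not self.receptors:
            raise ValidationError("truth needs at least one receptor")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for rec in self.receptors:
            if not 300.0 < rec.lambda_max < 700.0:
                raise ValidationError(
                    f"lambda_max {rec.lambda_max} nm outside (300, 700)")
            if rec.label not in self.ki:
                raise ValidationError(f"no ki row for receptor {rec.label!r}")
        for rec_label, ref in self.reference_map.items():
            if ref is None:
                continue
            k = self.ki[rec_label].get(ref)
            if k is None or not np.isclose(k, 1.0, rtol=0, atol=1e-12):
                raise ValidationError(
                    f"ki({rec_label!r}, {ref!r}) must equal 1 at the "
                    "reference adaptation")
        if self.response_mode not in ("log", "naka_rushton"):
            raise ValidationError(f"unknown response_mode "
                                  f"{self.response_mode!r}")


def default_truth(**overrides) -> GroundTruth:
    """The study conditions the default simulations emulate.

    Two receptors (UV at 364 nm, LW at 527 nm); bright-green adaptation
    suppresses the LW receptor almost completely while dark adaptation
    maximises it; the UV receptor is anchored at bright green.
    """
    base = dict(
        receptors=(Receptor("UV", 364.0), Receptor("LW", 527.0)),
        ki={
            "UV": {"dark": 0.4, "dim_green": 0.7, "bright_green": 1.0},
            "LW": {"dark": 1.0, "dim_green": 0.35, "bright_green": 0.02},
        },
        reference_map={"UV": "bright_green", "LW": "dark"},
    )
    base.update(overrides)
    return GroundTruth(**base)


def truth_to_dict(truth: GroundTruth) -> dict:
    d = {
        "receptors": [{"label": r.label, "lambda_max": r.lambda_max,
                       "backend": r.backend, "beta_band": r.beta_band}
                      for r in truth.receptors],
        "ki": {rec: dict(row) for rec, row in truth.ki.items()},
        "reference_map": dict(truth.reference_map),
    }
    for name in ("vlogi_slope", "vlogi_intercept", "white_catch_constant",
                 "noise_sd", "n_per_sex", "seed", "response_mode", "nr_vmax",
                 "nr_exponent", "nr_half_catch", "male_lambda_shift_nm"):
        d[name] = getattr(truth, name)
    return d


def truth_from_dict(d: Mapping) -> GroundTruth:
    d = dict(d)
    d["receptors"] = tuple(
        Receptor(**r) if isinstance(r, Mapping) else r
        for r in d["receptors"])
    return GroundTruth(**d)


def inject_third_receptor(truth: GroundTruth, lambda_max: float,
                          relative_ki: float,
                          label: str = "blue") -> GroundTruth:
    """Return a copy of ``truth`` with an extra receptor class added.

    The new receptor gets the same scaling factor ``relative_ki`` under every
    adaptation state (no reference anchoring); the original is unchanged.
    """
    if not 300.0 < lambda_max < 700.0:
        raise ValidationError("lambda_max must lie in (300, 700) nm")
    if relative_ki <= 0:
        raise ValidationError("relative_ki must be positive")
    if label in {r.label for r in truth.receptors}:
        raise ValidationError(f"receptor label {label!r} already present")
    adapt_labels = set()
    for row in truth.ki.values():
        adapt_labels.update(row)
    ki = {rec: dict(row) for rec, row in truth.ki.items()}
    ki[label] = {a: relative_ki for a in adapt_labels}
    refs = dict(truth.reference_map)
    refs[label] = None
    return replace(truth,
                   receptors=truth.receptors + (Receptor(label, lambda_max),),
                   ki=ki, reference_map=refs)


def _responses(catch: np.ndarray, truth: GroundTruth, q_floor: float,
               rng: np.random.Generator) -> np.ndarray:
    if truth.response_mode == "log":
        v = (truth.vlogi_slope * (np.log10(catch) - np.log10(q_floor))
             + truth.vlogi_intercept)
    else:
        k_half = truth.nr_half_catch
        if k_half is None:
            k_half = np.sqrt(q_floor) * np.sqrt(catch.max())  # mid-range
        qn = catch ** truth.nr_exponent
        v = truth.nr_vmax * qn / (qn + k_half ** truth.nr_exponent)
    if truth.noise_sd > 0:
        v = v + rng.normal(0.0, truth.noise_sd, size=v.shape)
    return np.maximum(v, 0.0)


def simulate_study(protocol: StimulusProtocol, truth: GroundTruth,
                   seed: int | None = None,
                   nonresponder_ids: Sequence[str] = (),
                   ) -> list[ERGSession]:
    """Generate one full study: every individual × every adaptation state.

    Individuals are labelled ``f01..`` / ``m01..``; any id listed in
    ``nonresponder_ids`` emits zero amplitude to every flash (a dead
    preparation, for exercising the quality-control exclusion).  The output
    is deterministic given the seed (``truth.seed`` unless overridden).
    """
    if len(protocol.white_intensities) < 2:
        raise ValidationError("degenerate white ladder")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    wl = np.asarray(protocol.mono_wavelengths)
    white = np.asarray(protocol.white_intensities)
    q_floor = truth.white_catch_constant * white.min()
    nonresponders = set(nonresponder_ids)

    individuals = [(f"f{i + 1:02d}", "female") for i in range(truth.n_per_sex)]
    individuals += [(f"m{i + 1:02d}", "male") for i in range(truth.n_per_sex)]

    sessions: list[ERGSession] = []
    for ind_id, sex in individuals:
        shift = truth.male_lambda_shift_nm if sex == "male" else 0.0
        sumkr = {}
        for state in protocol.adaptation_states:
            total = np.zeros_like(wl, dtype=float)
            for rec in truth.receptors:
                template = OpsinTemplate(lambda_max=rec.lambda_max + shift,
                                         backend=rec.backend,
                                         beta_band=rec.beta_band)
                total += (truth.ki[rec.label][state.label]
                          * template_sensitivity(template, wl))
            sumkr[state.label] = total
        for state in protocol.adaptation_states:
            dead = ind_id in nonresponders
            white_catch = truth.white_catch_constant * white
            v_before = _responses(white_catch, truth, q_floor, rng)
            v_after = _responses(white_catch, truth, q_floor, rng)
            mono: list[tuple[int, float, float]] = []
            for rnd in range(1, protocol.rounds_per_series + 1):
                order = rng.permutation(len(wl))
                catch = protocol.mono_intensity * sumkr[state.label][order]
                v = _responses(catch, truth, q_floor, rng)
                for j, idx in enumerate(order):
                    amp = 0.0 if dead else float(v[j])
                    mono.append((rnd, float(wl[idx]), amp))
            if dead:
                v_before = np.zeros_like(v_before)
                v_after = np.zeros_like(v_after)
            sessions.append(ERGSession(
                individual_id=ind_id, sex=sex,
                adaptation_label=state.label,
                white_before=[(float(i), float(v)) for i, v
                              in zip(white, v_before)],
                white_after=[(float(i), float(v)) for i, v
                             in zip(white, v_after)],
                mono_responses=mono,
            ).validate(protocol))
    return sessions
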