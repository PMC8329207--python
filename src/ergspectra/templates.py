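"""Visual-pigment absorbance templates and adaptation scaling factors.

Two template backends are provided behind one interface:

``stavenga``
    The modified log-normal α-band, R(λ) = exp(−a·x²·(1 + b·x + c·x²)) with
    x = log10(λ/λ_max), using the published constants a = 380, b = 6.09,
    c = 3b²/8; an optional β-band (A = 0.29, λ_m = 340 nm, a = 247, b = 3.59)
    can be added for long-wavelength pigments.

``govardovskii``
    The rhodopsin A1 nomogram α-band (with optional Gaussian β-band), kept as
    an independent shape family for robustness comparisons.

Both evaluate to 1 at λ_max when ``amplitude = 1`` (the Govardovskii α-band
is renormalised to its peak).  The fit's two free parameters are
(λ_max, amplitude); the shape constants stay fixed but are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ValidationError

# modified log-normal α/β-band constant presets
STAVENGA_ALPHA = {"a": 380.0, "b": 6.09, "c": 3 * 6.09**2 / 8}
STAVENGA_BETA = {"amplitude": 0.29, "lambda_max": 340.0,
                 "a": 247.0, "b": 3.59, "c": 3 * 3.59**2 / 8}

TEMPLATE_BACKENDS = ("stavenga", "govardovskii")


def _lognormal_band(wavelengths: np.ndarray, lambda_max: float,
                    a: float, b: float, c: float) -> np.ndarray:
    x = np.log10(wavelengths / lambda_max)
    return np.exp(-a * x**2 * (1 + b * x + c * x**2))


def _govardovskii_alpha(wavelengths: np.ndarray,
                        lambda_max: float) -> np.ndarray:
    x = lambda_max / wavelengths
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    b, c = 0.922, 1.104
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    s = 1.0 / (np.exp(A * (a - x)) + np.exp(B * (b - x))
               + np.exp(C * (c - x)) + D)
    peak = 1.0 / (np.exp(A * (a - 1.0)) + np.exp(B * (b - 1.0))
                  + np.exp(C * (c - 1.0)) + D)
    return s / peak


def _govardovskii_beta(wavelengths: np.ndarray,
                       lambda_max: float) -> np.ndarray:
    lm_beta = 189.0 + 0.315 * lambda_max
    bandwidth = -40.5 + 0.195 * lambda_max
    return 0.26 * np.exp(-(((wavelengths - lm_beta) / bandwidth) ** 2))


@dataclass(frozen=True)
class OpsinTemplate:
    """A pigment absorbance curve with free (λ_max, amplitude)."""

    lambda_max: float                 # nm
    amplitude: float = 1.0            # dimensionless vertical scale
    backend: str = "stavenga"
    beta_band: bool = False
    #: α-band shape constants; defaults to the backend's published set
    shape: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.lambda_max <= 0:
            raise ValidationError("lambda_max must be positive")
        if self.backend not in TEMPLATE_BACKENDS:
            raise ValidationError(f"unknown backend {self.backend!r}")

    def sensitivity(self, wavelengths) -> np.ndarray:
        return template_sensitivity(self, wavelengths)


def template_sensitivity(template: OpsinTemplate, wavelengths) -> np.ndarray:
    """Evaluate R(λ) for a template; vectorised over wavelengths."""
    wl = np.asarray(wavelengths, dtype=float)
    if np.any(wl <= 0):
        raise ValidationError("wavelengths must be positive")
    if template.backend == "stavenga":
        consts = dict(STAVENGA_ALPHA)
        if template.shape:
            consts.update(template.shape)
        r = _lognormal_band(wl, template.lambda_max, **consts)
        if template.beta_band:
            beta = STAVENGA_BETA
            r = r + beta["amplitude"] * _lognormal_band(
                wl, beta["lambda_max"], beta["a"], beta["b"], beta["c"])
    else:
        r = _govardovskii_alpha(wl, template.lambda_max)
        if template.beta_band:
            r = r + _govardovskii_beta(wl, template.lambda_max)
    return template.amplitude * r


@dataclass
class AdaptationScaling:
    """Scaling factors k_i per (receptor, adaptation state).

    Each receptor is anchored to 1 at its reference adaptation (the state
    maximising that receptor's sensitivity); all factors are non-negative.
    """

    receptor_labels: tuple[str, ...]
    adaptation_labels: tuple[str, ...]
    ki: np.ndarray                          # rows receptors, cols adaptations
    reference_map: dict[str, str | None]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ki = np.asarray(self.ki, dtype=float)
        if self.ki.shape != (len(self.receptor_labels),
                             len(self.adaptation_labels)):
            raise ValidationError("ki shape mismatch")
        if np.any(self.ki < 0):
            raise ValidationError("ki must be non-negative")
        for rec, ref in self.reference_map.items():
            if ref is None:
                continue
            if not np.isclose(self.get(rec, ref), 1.0, rtol=0, atol=1e-12):
                raise ValidationError(
                    f"ki({rec}, {ref}) must be 1 at the reference adaptation")

    def get(self, receptor: str, adaptation: str) -> float:
        i = self.receptor_labels.index(receptor)
        j = self.adaptation_labels.index(adaptation)
        return float(self.ki[i, j])


def compute_ki(averaged_by_adaptation: Mapping[str, "SpectralSensitivity"],
               peak_wavelengths: Mapping[str, float],
               reference_map: Mapping[str, str],
               interpolate: bool = False) -> AdaptationScaling:
    """Adaptation scaling from measured sensitivities at the receptor peaks.

    For receptor *i* with peak wavelength λ_i and reference adaptation r_i,
    k_i(adaptation) = S_measured(λ_i, adaptation) / S_measured(λ_i, r_i);
    reference cells equal 1 by construction.  Peaks off the measured grid are
    mapped to the nearest grid wavelength (recorded in ``meta``) unless
    ``interpolate`` is set, in which case S is linearly interpolated.
    """
    adapt_labels = tuple(averaged_by_adaptation)
    receptor_labels = tuple(peak_wavelengths)
    for rec in receptor_labels:
        ref = reference_map.get(rec)
        if ref not in adapt_labels:
            raise ValidationError(
                f"reference adaptation {ref!r} for {rec!r} missing from data")
    rows = []
    mapped: dict[str, float] = {}
    for rec in receptor_labels:
        peak = float(peak_wavelengths[rec])
        ref = reference_map[rec]

        def s_at(label: str) -> float:
            sens = averaged_by_adaptation[label]
            wl = np.asarray(sens.wavelengths, dtype=float)
            if interpolate:
                return float(np.interp(peak, wl, np.asarray(sens.values)))
            idx = int(np.argmin(np.abs(wl - peak)))
            mapped[rec] = float(wl[idx])
            return float(np.asarray(sens.values)[idx])

        s_ref = s_at(ref)
        if s_ref <= 0:
            raise ValidationError(
                f"reference sensitivity for {rec!r} is not positive")
        rows.append([s_at(label) / s_ref for label in adapt_labels])
    return AdaptationScaling(
        receptor_labels=receptor_labels,
        adaptation_labels=adapt_labels,
        ki=np.asarray(rows),
        reference_map=dict(reference_map),
        meta={"peak_wavelengths": dict(peak_wavelengths),
              "grid_mapped_peaks": mapped,
              "interpolated": interpolate},
    )


@dataclass(frozen=True)
class ModelCurve:
    """Summed receptor model M(λ) = Σ_i k_i·R_i(λ) for one adaptation."""

    adaptation_label: str
    wavelengths: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray    # raw / max(raw) over the evaluated grid


def sum_model(templates: Mapping[str, OpsinTemplate],
              scaling: AdaptationScaling,
              adaptation: str,
              wavelengths) -> ModelCurve:
    """Evaluate the summed receptor-contribution model for one adaptation."""
    if adaptation not in scaling.adaptation_labels:
        raise ValidationError(f"unknown adaptation {adaptation!r}")
    wl = np.asarray(wavelengths, dtype=float)
    raw = np.zeros_like(wl)
    for rec, template in templates.items():
        raw = raw + scaling.get(rec, adaptation) * template.sensitivity(wl)
    return ModelCurve(adaptation_label=adaptation, wavelengths=wl,
                      raw=raw, normalized=raw / raw.max())
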