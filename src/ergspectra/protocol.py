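"""Stimulus protocol: the experiment design an ERG study follows.

A protocol records the monochromatic wavelength grid flashed at equal quantal
flux, the ascending white-light intensity ladder used for calibration, and the
chromatic-adaptation states under which the whole series is repeated.  The
defaults reproduce a standard insect compound-eye ERG design: 17 monochromatic
lights between 334 and 649 nm at 1.04e14 photons/cm²·s, an 8-step white ladder
from 5.97e12 to 4.95e16 photons/cm²·s, and three adaptation states (dark, dim
green and bright green at 551 nm).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError

DEFAULT_MONO_WAVELENGTHS: tuple[float, ...] = (
    334.0, 352.0, 358.0, 382.0, 398.0, 418.0, 431.0, 449.0, 468.0,
    501.0, 519.0, 529.0, 550.0, 569.0, 599.0, 620.0, 649.0,
)
DEFAULT_MONO_INTENSITY = 1.04e14  # photons/cm²·s, equal quantal flux per flash

#: 8 log-spaced steps spanning the measured ladder endpoints.
DEFAULT_WHITE_INTENSITIES: tuple[float, ...] = tuple(
    float(v) for v in np.geomspace(5.97e12, 4.95e16, 8)
)


@dataclass(frozen=True)
class AdaptationState:
    """One chromatic-adaptation condition (``adapting_wavelength=None`` = dark)."""

    label: str
    adapting_wavelength: float | None = None  # nm
    adapting_intensity: float | None = None   # quanta/s/cm²


DEFAULT_ADAPTATION_STATES: tuple[AdaptationState, ...] = (
    AdaptationState("dark"),
    AdaptationState("dim_green", 551.0, 7e12),
    AdaptationState("bright_green", 551.0, 7e15),
)


@dataclass(frozen=True)
class StimulusProtocol:
    """Complete stimulus design for one ERG study.

    Invariants are enforced at construction: the wavelength grid is strictly
    positive and unique, the white ladder strictly ascending with >= 2 steps,
    and at most one adaptation state may be dark.
    """

    mono_wavelengths: tuple[float, ...] = DEFAULT_MONO_WAVELENGTHS
    mono_intensity: float = DEFAULT_MONO_INTENSITY
    white_intensities: tuple[float, ...] = DEFAULT_WHITE_INTENSITIES
    adaptation_states: tuple[AdaptationState, ...] = DEFAULT_ADAPTATION_STATES
    flash_duration_ms: float = 100.0
    rounds_per_series: int = 2

    def __post_init__(self):
        object.__setattr__(self, "mono_wavelengths",
                           tuple(float(w) for w in self.mono_wavelengths))
        object.__setattr__(self, "white_intensities",
                           tuple(float(i) for i in self.white_intensities))
        object.__setattr__(self, "adaptation_states",
                           tuple(self.adaptation_states))
        wl = self.mono_wavelengths
        if len(wl) == 0 or any(w <= 0 for w in wl):
            raise ValidationError("mono_wavelengths must be strictly positive")
        if len(set(wl)) != len(wl):
            raise ValidationError("mono_wavelengths must be unique")
        wi = self.white_intensities
        if len(wi) < 2:
            raise ValidationError("white ladder needs at least 2 intensities")
        if any(b <= a for a, b in zip(wi, wi[1:])):
            raise ValidationError("white_intensities must be strictly ascending")
        if self.mono_intensity <= 0:
            raise ValidationError("mono_intensity must be positive")
        n_dark = sum(1 for s in self.adaptation_states
                     if s.adapting_wavelength is None)
        if n_dark > 1:
            raise ValidationError(
                "at most one adaptation state may be dark "
                f"(found {n_dark})")
        labels = [s.label for s in self.adaptation_states]
        if len(set(labels)) != len(labels):
            raise ValidationError("adaptation labels must be unique")
        if self.rounds_per_series < 1:
            raise ValidationError("rounds_per_series must be >= 1")

    @property
    def adaptation_labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.adaptation_states)

    def adaptation(self, label: str) -> AdaptationState:
        for s in self.adaptation_states:
            if s.label == label:
                return s
        raise KeyError(label)

    # -- config I/O ---------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mono_wavelengths"] = list(self.mono_wavelengths)
        d["white_intensities"] = list(self.white_intensities)
        d["adaptation_states"] = [asdict(s) for s in self.adaptation_states]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        d = dict(d)
        if "adaptation_states" in d:
            d["adaptation_states"] = tuple(
                AdaptationState(**s) if isinstance(s, dict) else s
                for s in d["adaptation_states"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "StimulusProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
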