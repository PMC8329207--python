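"""V-log(I) calibration and the spectral-sensitivity transform.

The calibration step fits, per individual and adaptation state, a logarithmic
intensity-response model to the white-flash ladder: with
x = log10(I) − log10(I_min) (so the axis starts at zero at the weakest flash),
the response is V = a·x + b by ordinary least squares, averaging the ladders
flashed before and after the spectral series.  Monochromatic flash amplitudes
are then inverted through this curve into equivalent log-intensities x_eq, and
the spectral sensitivity is

    S(λ) = 10^(x_eq(λ) − x_eq,max)

so that each individual's curve peaks at exactly 1.  Because the transform is
(V − b)/a followed by a difference, S is invariant to any affine rescaling of
the amplitudes once the calibration is refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import CalibrationError, DegenerateFitError, FitError, ValidationError
from .sessions import ERGSession


@dataclass(frozen=True)
class VLogICurve:
    """Fitted linear response model on the shifted log-intensity axis."""

    slope: float          # mV per log10 intensity unit
    intercept: float      # mV, response at the weakest ladder intensity
    x_offset: float       # log10(I_min): subtracted from log10(I)
    r_squared: float
    x_range: tuple[float, float]   # valid calibration span, (0, x_max)
    n_points: int

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_vlogi(session: ERGSession) -> VLogICurve:
    """Fit the V-log(I) calibration for one session.

    Before/after amplitudes are averaged per ladder intensity first; ladders
    with dropouts in one series simply average over what is present.
    """
    per_intensity: dict[float, list[float]] = {}
    for series in (session.white_before, session.white_after):
        for intensity, amp in series:
            per_intensity.setdefault(float(intensity), []).append(float(amp))
    if len(per_intensity) < 2:
        raise FitError("need >= 2 distinct white intensities to calibrate")
    intensities = np.array(sorted(per_intensity))
    v = np.array([np.mean(per_intensity[i]) for i in intensities])
    x_offset = float(np.log10(intensities.min()))
    x = np.log10(intensities) - x_offset
    if np.ptp(v) == 0:
        raise DegenerateFitError("zero variance in white responses")
    xbar, vbar = x.mean(), v.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    slope = float(np.sum((x - xbar) * (v - vbar)) / sxx)
    intercept = float(vbar - slope * xbar)
    ssr = float(np.sum((v - slope * x - intercept) ** 2))
    sst = float(np.sum((v - vbar) ** 2))
    return VLogICurve(slope=slope, intercept=intercept, x_offset=x_offset,
                      r_squared=1.0 - ssr / sst,
                      x_range=(0.0, float(x.max())), n_points=len(x))


def equivalent_log_intensity(curve: VLogICurve, amplitude,
                             return_flags: bool = False):
    """Invert the calibration: amplitude (mV) -> shifted log10 intensity.

    Values outside the calibrated span are extrapolations; they are flagged
    (when ``return_flags``) but never rejected.
    """
    if curve.slope <= 0:
        raise CalibrationError(
            f"calibration slope must be positive, got {curve.slope}")
    amp = np.asarray(amplitude, dtype=float)
    x_eq = (amp - curve.intercept) / curve.slope
    if return_flags:
        lo, hi = curve.x_range
        return x_eq, (x_eq < lo) | (x_eq > hi)
    return x_eq


@dataclass
class SpectralSensitivity:
    """S(λ) on the wavelength grid, per-individual or averaged.

    Per-individual curves peak at exactly 1 by construction; averages of
    normalised curves are not renormalised, so their maxima may fall below 1.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    adaptation_label: str
    grouping: str = "per-individual"   # per-individual | per-sex | pooled
    sd: np.ndarray | None = None       # present only when averaged
    n: int = 1                         # contributing individuals
    extrapolated: np.ndarray | None = None
    peak_tied: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ValidationError("wavelengths/values shape mismatch")
        if np.any(self.values <= 0):
            raise ValidationError("sensitivity values must be positive")


def sensitivity_spectrum(session: ERGSession,
                         curve: VLogICurve | None = None,
                         ) -> SpectralSensitivity:
    """Transform one session's mono amplitudes into a sensitivity spectrum.

    The rounds are averaged per wavelength on the amplitude scale first, then
    converted to equivalent log-intensities and normalised at the series
    maximum.  Ties at the maximum resolve to the shortest wavelength (with a
    warning and a flag on the result).
    """
    if curve is None:
        curve = fit_vlogi(session)
    per_wl: dict[float, list[float]] = {}
    for _rnd, wl, amp in session.mono_responses:
        per_wl.setdefault(float(wl), []).append(float(amp))
    if not per_wl:
        raise ValidationError("session has no mono responses")
    wavelengths = np.array(sorted(per_wl))
    amps = np.array([np.mean(per_wl[w]) for w in wavelengths])
    if np.all(amps == 0):
        raise ValidationError("all mono responses are zero: no maximum defined")
    x_eq, flags = equivalent_log_intensity(curve, amps, return_flags=True)
    imax = int(np.argmax(x_eq))          # first index on ties
    tied = bool(np.sum(x_eq == x_eq[imax]) > 1)
    if tied:
        warnings.warn("tie at the sensitivity maximum; using the shortest "
                      "wavelength", stacklevel=2)
    s = np.power(10.0, x_eq - x_eq[imax])
    return SpectralSensitivity(
        wavelengths=wavelengths, values=s,
        adaptation_label=session.adaptation_label,
        grouping="per-individual", extrapolated=flags, peak_tied=tied,
        meta={"individual_id": session.individual_id, "sex": session.sex})


def average_sensitivities(curves: Sequence[SpectralSensitivity],
                          grouping: str) -> SpectralSensitivity:
    """Per-wavelength mean and SD across individuals (no renormalisation)."""
    if not curves:
        raise ValidationError("no curves to average")
    first = curves[0]
    for c in curves[1:]:
        if not np.array_equal(c.wavelengths, first.wavelengths):
            raise ValidationError("wavelength grids differ")
        if c.adaptation_label != first.adaptation_label:
            raise ValidationError("adaptation labels differ")
    stack = np.vstack([c.values for c in curves])
    mean = stack.mean(axis=0)
    sd = (stack.std(axis=0, ddof=1) if len(curves) > 1
          else np.zeros_like(mean))
    return SpectralSensitivity(
        wavelengths=first.wavelengths.copy(), values=mean, sd=sd,
        adaptation_label=first.adaptation_label, grouping=grouping,
        n=len(curves))
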