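"""Rank statistics for the male/female sensitivity screen.

Pooling the sexes before curve fitting is only justified when no sex
difference in sensitivity is detectable; the screen applies a Kruskal–Wallis
rank test per adaptation state to per-individual sensitivities in each
receptor's peak region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2, rankdata

from .calibration import SpectralSensitivity
from .errors import ValidationError

#: Screen wavelengths (nm) per default adaptation label: the LW peak region
#: under dark/dim adaptation, the UV peak region under bright-green adaptation.
DEFAULT_SCREEN_WAVELENGTHS: dict[str, tuple[float, ...]] = {
    "dark": (529.0,),
    "dim_green": (529.0,),
    "bright_green": (352.0, 358.0),
}


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; chi-square reference, df = k−1.

    H = [12/(N(N+1))]·Σ n_j·r̄_j² − 3(N+1), divided by the tie-correction
    factor 1 − Σ(t³−t)/(N³−N).  When every observation is tied the statistic
    is defined as 0 and p as 1.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("empty group in Kruskal–Wallis test")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start:start + a.size]
        h += a.size * r.mean() ** 2
        start += a.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if correction == 0:         # every observation tied
        return 0.0, 1.0
    h /= correction
    df = len(groups) - 1
    return float(h), float(chi2.sf(h, df))


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the sex-difference screen for one adaptation state."""

    adaptation_label: str
    statistic: float              # Kruskal–Wallis H
    p_value: float
    screen_wavelengths: tuple[float, ...]
    n_by_sex: dict[str, int]

    def permits_pooling(self, alpha: float) -> bool:
        return self.p_value > alpha


def sex_difference_screen(
    curves_by_sex: Mapping[str, Sequence[SpectralSensitivity]],
    adaptation_label: str,
    screen_wavelengths: Sequence[float],
) -> ScreenResult:
    """Kruskal–Wallis screen on per-individual peak-region sensitivities.

    Each individual contributes its mean S over ``screen_wavelengths``
    (nearest grid wavelengths are used).
    """
    groups, n_by_sex = [], {}
    for sex, curves in curves_by_sex.items():
        vals = []
        for c in curves:
            wl = np.asarray(c.wavelengths)
            idx = [int(np.argmin(np.abs(wl - w))) for w in screen_wavelengths]
            vals.append(float(np.mean(np.asarray(c.values)[idx])))
        if not vals:
            raise ValidationError(f"no individuals for sex {sex!r}")
        groups.append(vals)
        n_by_sex[sex] = len(vals)
    h, p = kruskal_wallis(*groups)
    return ScreenResult(adaptation_label=adaptation_label, statistic=h,
                        p_value=p,
                        screen_wavelengths=tuple(float(w) for w
                                                 in screen_wavelengths),
                        n_by_sex=n_by_sex)
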