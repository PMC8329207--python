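"""Least-squares λ_max estimation, study orchestration, third-receptor scan.

``fit_single_receptor`` fits amplitude·R(λ; λ_max) to an averaged sensitivity
curve by Levenberg–Marquardt least squares with a multistart over λ_max
initial values (the template objective is mildly multimodal).  The standard
error comes from the local curvature of the solution, the residual standard
error is sqrt(SSR/(n−2)), and the parameter p-value is the conventional
t = estimate/SE significance of λ_max.

``fit_study`` runs the full analysis: quality-control exclusion, per-session
V-log(I) calibration and sensitivity transform, the male/female screen,
pooling (only when every screen passes), template fits on the adaptations
isolating each receptor (UV on bright-green-adapted data, LW on
dark-adapted data), adaptation scaling factors, and the summed model curve
for every adaptation.

``third_receptor_scan`` asks whether the data need a third (blue) receptor:
an extra fixed-shape template with one shared amplitude is profiled over a
candidate λ_max range, amplitudes refit by linear least squares against the
pooled residuals from all adaptations, and compared to the two-receptor
model with an extra-sum-of-squares F test (Bonferroni-corrected over the
profiled candidates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import lmfit
import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from .calibration import (SpectralSensitivity, average_sensitivities,
                          fit_vlogi, sensitivity_spectrum)
from .errors import (FitError, MissingAdaptationError, ValidationError)
from .protocol import StimulusProtocol
from .sessions import ERGSession, qc_exclude
from .stats import (DEFAULT_SCREEN_WAVELENGTHS, ScreenResult,
                    sex_difference_screen)
from .templates import (AdaptationScaling, ModelCurve, OpsinTemplate,
                        compute_ki, sum_model, template_sensitivity)


@dataclass
class ReceptorFit:
    """One fitted opsin template: peak estimate and diagnostics."""

    lambda_max_hat: float
    lambda_max_se: float               # nm, from the LS curvature; nan at bounds
    amplitude_hat: float
    amplitude_se: float
    residual_standard_error: float     # sqrt(SSR/(n-2)), on the S scale
    p_value: float                     # t = lambda_max_hat / SE convention
    converged: bool
    n_obs: int
    init_used: float                   # nm, winning multistart initial value
    at_bounds: bool
    bounds: tuple[float, float]
    data_window: tuple[float, float]
    backend: str
    meta: dict = field(default_factory=dict)


def fit_single_receptor(sens: SpectralSensitivity,
                        lambda_bounds: tuple[float, float],
                        backend: str = "stavenga",
                        beta_band: bool = False,
                        init_step: float = 10.0,
                        data_window: tuple[float, float] | None = None,
                        ) -> ReceptorFit:
    """Fit amplitude·R(λ; λ_max) to a sensitivity curve.

    Only wavelengths inside ``data_window`` (default: the λ_max bounds) enter
    the fit — receptors are fitted on the adaptation state that isolates
    them, and the window drops wavelengths dominated by the other receptor.
    """
    lo, hi = float(lambda_bounds[0]), float(lambda_bounds[1])
    if not lo < hi:
        raise ValidationError("lambda_bounds must be increasing")
    window = (lo, hi) if data_window is None else (float(data_window[0]),
                                                  float(data_window[1]))
    wl = np.asarray(sens.wavelengths, dtype=float)
    s = np.asarray(sens.values, dtype=float)
    order = np.argsort(wl)
    wl, s = wl[order], s[order]
    mask = (wl >= window[0]) & (wl <= window[1]) & np.isfinite(s)
    wl, s = wl[mask], s[mask]
    n = wl.size
    if n < 4:
        raise FitError(f"need >= 4 wavelengths in the window, got {n}")

    def residual(params):
        template = OpsinTemplate(
            lambda_max=params["lambda_max"].value, amplitude=1.0,
            backend=backend, beta_band=beta_band)
        return (params["amplitude"].value * template_sensitivity(template, wl)
                - s)

    inits = np.arange(lo, hi + 1e-9, float(init_step))
    inits = np.clip(inits, lo + 1e-6, hi - 1e-6)
    best = None
    best_init = None
    failures = []
    for init in inits:
        params = lmfit.Parameters()
        params.add("lambda_max", value=float(init), min=lo, max=hi)
        params.add("amplitude", value=float(s.max()), min=0.0)
        try:
            result = lmfit.minimize(residual, params, method="leastsq",
                                    xtol=1e-13, ftol=1e-13)
        except Exception as exc:          # pragma: no cover - lmfit internals
            failures.append((float(init), repr(exc)))
            continue
        if not result.success:
            failures.append((float(init), result.message))
            continue
        if best is None or result.chisqr < best.chisqr:
            best, best_init = result, float(init)
    if best is None:
        raise FitError(f"no multistart converged; failures: {failures}")

    lam = best.params["lambda_max"]
    amp = best.params["amplitude"]
    at_bounds = bool(min(lam.value - lo, hi - lam.value) < 1e-6)
    if at_bounds:
        warnings.warn(f"lambda_max hit the fitting bounds "
                      f"[{lo}, {hi}] nm", stacklevel=2)
    lam_se = float(lam.stderr) if lam.stderr is not None else float("nan")
    amp_se = float(amp.stderr) if amp.stderr is not None else float("nan")
    rse = float(np.sqrt(best.chisqr / (n - 2)))
    if np.isfinite(lam_se) and lam_se > 0:
        tval = lam.value / lam_se
        p_value = float(2.0 * t_dist.sf(abs(tval), df=n - 2))
    else:
        p_value = float("nan")
    return ReceptorFit(
        lambda_max_hat=float(lam.value), lambda_max_se=lam_se,
        amplitude_hat=float(amp.value), amplitude_se=amp_se,
        residual_standard_error=rse, p_value=p_value,
        converged=bool(best.success), n_obs=n, init_used=best_init,
        at_bounds=at_bounds, bounds=(lo, hi), data_window=window,
        backend=backend, meta={"beta_band": beta_band,
                               "n_starts": len(inits)})


@dataclass(frozen=True)
class ThirdReceptorScan:
    """Extra-sum-of-squares evidence for an unmodelled third receptor.

    ``rse_two_receptor``/``rse_three_receptor`` are RMS residuals with a
    common denominator n (monotone for the nested pair); the F statistic
    uses the proper residual degrees of freedom.
    """

    best_extra_lambda_max: float
    extra_amplitude: float
    rse_two_receptor: float
    rse_three_receptor: float
    f_statistic: float
    p_value: float                  # Bonferroni-corrected over candidates
    detected: bool
    alpha: float
    n_candidates: int
    meta: dict = field(default_factory=dict)


def third_receptor_scan(averaged_by_adaptation: Mapping[str, SpectralSensitivity],
                        templates: Mapping[str, OpsinTemplate],
                        candidate_range: tuple[float, float] = (400.0, 500.0),
                        step: float = 5.0,
                        alpha: float = 0.05,
                        backend: str = "stavenga",
                        bonferroni: bool = True) -> ThirdReceptorScan:
    """Profile a third fixed-shape template over a candidate λ_max range.

    The two-receptor baseline refits the two template amplitudes freely per
    adaptation state (the fitted λ_max values stay fixed); the three-receptor
    alternative adds one blue template with a single non-negative amplitude
    tied across adaptations.  Both are linear least-squares problems, so the
    profile is exact.
    """
    lo, hi = float(candidate_range[0]), float(candidate_range[1])
    candidates = np.arange(lo, hi + 1e-9, float(step))
    if candidates.size == 0 or not lo <= hi:
        raise ValidationError("empty candidate range")
    labels = list(averaged_by_adaptation)
    if not labels:
        raise ValidationError("no averaged sensitivities supplied")
    rec_labels = list(templates)

    blocks, ys, wls = [], [], []
    for a_idx, label in enumerate(labels):
        sens = averaged_by_adaptation[label]
        wl = np.asarray(sens.wavelengths, dtype=float)
        base = np.column_stack([
            template_sensitivity(
                OpsinTemplate(lambda_max=templates[r].lambda_max,
                              amplitude=1.0, backend=templates[r].backend,
                              beta_band=templates[r].beta_band), wl)
            for r in rec_labels])
        blocks.append(base)
        ys.append(np.asarray(sens.values, dtype=float))
        wls.append(wl)
    n_total = sum(y.size for y in ys)
    p2 = len(labels) * len(rec_labels)
    x2 = np.zeros((n_total, p2))
    y = np.concatenate(ys)
    row = 0
    for a_idx, base in enumerate(blocks):
        nrows = base.shape[0]
        x2[row:row + nrows,
           a_idx * len(rec_labels):(a_idx + 1) * len(rec_labels)] = base
        row += nrows
    coef2, _, _, _ = np.linalg.lstsq(x2, y, rcond=None)
    ssr2 = float(np.sum((y - x2 @ coef2) ** 2))

    best = None   # (ssr3, lambda, d)
    for lam in candidates:
        blue = np.concatenate([
            template_sensitivity(OpsinTemplate(lambda_max=float(lam),
                                               amplitude=1.0,
                                               backend=backend), wl)
            for wl in wls])
        x3 = np.column_stack([x2, blue])
        coef3, _, _, _ = np.linalg.lstsq(x3, y, rcond=None)
        d = float(coef3[-1])
        if d < 0:
            ssr3, d = ssr2, 0.0   # constrained optimum reverts to baseline
        else:
            ssr3 = float(np.sum((y - x3 @ coef3) ** 2))
        if best is None or ssr3 < best[0]:
            best = (ssr3, float(lam), d)
    ssr3, best_lam, best_d = best

    df3 = n_total - (p2 + 1)
    if ssr3 <= 0:
        f_stat = float("inf")
        p_raw = 0.0
    else:
        f_stat = (ssr2 - ssr3) / (ssr3 / df3)
        p_raw = float(f_dist.sf(f_stat, 1, df3))
    p_value = min(1.0, p_raw * candidates.size) if bonferroni else p_raw
    return ThirdReceptorScan(
        best_extra_lambda_max=best_lam, extra_amplitude=best_d,
        rse_two_receptor=float(np.sqrt(ssr2 / n_total)),
        rse_three_receptor=float(np.sqrt(ssr3 / n_total)),
        f_statistic=float(f_stat), p_value=float(p_value),
        detected=bool(p_value < alpha), alpha=alpha,
        n_candidates=int(candidates.size),
        meta={"candidate_range": (lo, hi), "step": float(step),
              "bonferroni": bonferroni, "adaptations": labels,
              "ssr_two": ssr2, "ssr_three": ssr3})


@dataclass
class StudyConfig:
    """Tunable choices of the end-to-end analysis."""

    alpha: float = 0.05
    min_response: float = 0.0                 # mV, QC exclusion threshold
    #: "screen": pool iff every sex screen passes (default);
    #: "always"/"never": override the screen's pooling decision.
    pooling: str = "screen"
    uv_adaptation: str = "bright_green"
    lw_adaptation: str = "dark"
    uv_bounds: tuple[float, float] = (300.0, 450.0)
    lw_bounds: tuple[float, float] = (450.0, 650.0)
    template_backend: str = "stavenga"
    beta_band: bool = False
    init_step: float = 10.0
    screen_wavelengths: dict[str, tuple[float, ...]] | None = None
    ki_interpolate: bool = False
    scan_third_receptor: bool = False
    scan_range: tuple[float, float] = (400.0, 500.0)
    scan_step: float = 5.0


@dataclass
class GroupFitResult:
    """Fits, scaling factors and model curves for one pooling group."""

    group: str                                 # "pooled" | "male" | "female"
    averages: dict[str, SpectralSensitivity]   # per adaptation label
    fits: dict[str, ReceptorFit]               # "UV", "LW"
    templates: dict[str, OpsinTemplate]        # fitted λ_max + amplitude
    scaling: AdaptationScaling
    model_curves: dict[str, ModelCurve]
    scan: ThirdReceptorScan | None = None


@dataclass
class StudyResult:
    """Structured output of the full pipeline with provenance."""

    kept_individuals: list[str]
    excluded_individuals: list[str]
    screens: dict[str, ScreenResult]
    pooled: bool
    groups: dict[str, GroupFitResult]
    warnings: list[str]
    provenance: dict


def _fit_group(group: str,
               curves_by_adaptation: Mapping[str, list[SpectralSensitivity]],
               config: StudyConfig) -> GroupFitResult:
    averages = {label: average_sensitivities(curves, grouping=group)
                for label, curves in curves_by_adaptation.items() if curves}
    uv_fit = fit_single_receptor(
        averages[config.uv_adaptation], config.uv_bounds,
        backend=config.template_backend, beta_band=False,
        init_step=config.init_step)
    lw_fit = fit_single_receptor(
        averages[config.lw_adaptation], config.lw_bounds,
        backend=config.template_backend, beta_band=config.beta_band,
        init_step=config.init_step)
    fits = {"UV": uv_fit, "LW": lw_fit}
    fitted_templates = {
        name: OpsinTemplate(lambda_max=fit.lambda_max_hat,
                            amplitude=fit.amplitude_hat,
                            backend=config.template_backend,
                            beta_band=(config.beta_band if name == "LW"
                                       else False))
        for name, fit in fits.items()}
    scaling = compute_ki(
        averages,
        peak_wavelengths={"UV": uv_fit.lambda_max_hat,
                          "LW": lw_fit.lambda_max_hat},
        reference_map={"UV": config.uv_adaptation,
                       "LW": config.lw_adaptation},
        interpolate=config.ki_interpolate)
    curves = {label: sum_model(fitted_templates, scaling, label,
                               averages[label].wavelengths)
              for label in averages}
    scan = None
    if config.scan_third_receptor:
        scan = third_receptor_scan(
            averages, fitted_templates,
            candidate_range=config.scan_range, step=config.scan_step,
            alpha=config.alpha, backend=config.template_backend)
    return GroupFitResult(group=group, averages=averages, fits=fits,
                          templates=fitted_templates, scaling=scaling,
                          model_curves=curves, scan=scan)


def fit_study(sessions: Sequence[ERGSession],
              protocol: StimulusProtocol,
              config: StudyConfig | None = None) -> StudyResult:
    """Run the complete analysis on a set of validated sessions."""
    config = config or StudyConfig()
    present = {s.adaptation_label for s in sessions}
    for needed in (config.uv_adaptation, config.lw_adaptation):
        if needed not in present:
            raise MissingAdaptationError(
                f"required adaptation state {needed!r} absent from sessions")
    kept, excluded = qc_exclude(sessions, min_response=config.min_response)
    notes: list[str] = []
    if excluded:
        notes.append(f"excluded {len(excluded)} unresponsive individuals: "
                     f"{excluded}")

    per_adapt_sex: dict[str, dict[str, list[SpectralSensitivity]]] = {}
    n_extrapolated = 0
    for session in kept:
        curve = fit_vlogi(session)
        spectrum = sensitivity_spectrum(session, curve)
        if spectrum.extrapolated is not None:
            n_extrapolated += int(np.sum(spectrum.extrapolated))
        per_adapt_sex.setdefault(session.adaptation_label, {}) \
            .setdefault(session.sex, []).append(spectrum)

    screen_wl = (config.screen_wavelengths
                 if config.screen_wavelengths is not None
                 else DEFAULT_SCREEN_WAVELENGTHS)
    screens: dict[str, ScreenResult] = {}
    for label, by_sex in per_adapt_sex.items():
        if label not in screen_wl:
            raise ValidationError(
                f"no screen wavelengths configured for {label!r}")
        screens[label] = sex_difference_screen(by_sex, label,
                                               screen_wl[label])
    if config.pooling == "screen":
        pooled = all(r.permits_pooling(config.alpha)
                     for r in screens.values())
    elif config.pooling in ("always", "never"):
        pooled = config.pooling == "always"
    else:
        raise ValidationError(f"unknown pooling policy {config.pooling!r}")

    groups: dict[str, GroupFitResult] = {}
    if pooled:
        merged = {label: [c for curves in by_sex.values() for c in curves]
                  for label, by_sex in per_adapt_sex.items()}
        groups["pooled"] = _fit_group("pooled", merged, config)
    else:
        notes.append("sex screen failed for at least one adaptation; "
                     "pooling refused, emitting per-sex fits")
        warnings.warn(notes[-1], stacklevel=2)
        sexes = sorted({sex for by_sex in per_adapt_sex.values()
                        for sex in by_sex})
        for sex in sexes:
            per_sex = {label: by_sex.get(sex, [])
                       for label, by_sex in per_adapt_sex.items()}
            groups[sex] = _fit_group(sex, per_sex, config)

    return StudyResult(
        kept_individuals=sorted({s.individual_id for s in kept}),
        excluded_individuals=excluded,
        screens=screens, pooled=pooled, groups=groups, warnings=notes,
        provenance={
            "config": asdict(config),
            "n_sessions": len(sessions),
            "n_kept_sessions": len(kept),
            "n_extrapolated_points": n_extrapolated,
            "screen_wavelengths": {k: list(v) for k, v in screen_wl.items()
                                   if k in per_adapt_sex},
        })
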