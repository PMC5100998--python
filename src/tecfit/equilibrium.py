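"""Depletion-corrected equilibrium binding: titration model and Kd fitting.

At 100 nM receptor the ligand (tagetitoxin, TGT) is consumed appreciably by
complex formation, so the hyperbolic isotherm is wrong; the bound complex
concentration b is instead the physical root of the mass-balance quadratic

    b^2 - (R + L + Kd) * b + R * L = 0,

where R and L are the *total* receptor and ligand concentrations.  A
titration curve is modeled as a linear interpolation between the free- and
bound-state signal endpoints weighted by the bound fraction b/R; the shared
Kd is fit jointly across curves (per-curve endpoints are profiled by linear
least squares), with Kd kept positive by optimizing log10 Kd.  The 95%
confidence interval comes from the profile of the joint sum of squares at
the F-distribution threshold appropriate for one profiled parameter; a Wald
interval from the local curvature is reported alongside.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import f as f_dist

__all__ = [
    "TitrationError",
    "TitrationCurve",
    "TitrationFitResult",
    "bound_fraction",
    "titration_model",
    "fit_titration",
]


class TitrationError(ValueError):
    """A titration input violates its contract."""


def bound_fraction(kd: float, receptor_total: float, ligand_total: float) -> float:
    """Fraction of receptor bound at equilibrium under ligand depletion.

    Uses the cancellation-free form of the quadratic root,
    b = 2 R L / (S + sqrt(S^2 - 4 R L)) with S = R + L + Kd, which is exact
    for L = 0 and monotone nondecreasing in the total ligand.
    """
    if kd < 0 or receptor_total <= 0 or ligand_total < 0:
        raise TitrationError(
            "bound_fraction needs kd >= 0, receptor_total > 0, ligand_total >= 0"
        )
    r, l = receptor_total, ligand_total
    s = r + l + kd
    disc = s * s - 4.0 * r * l
    b = 2.0 * r * l / (s + math.sqrt(max(disc, 0.0)))
    return min(b / r, 1.0)


@dataclass
class TitrationCurve:
    """Total-ligand series vs equilibrium signal at fixed receptor total.

    ``volumes`` optionally holds the cumulative cuvette volume after each
    addition; when present the receptor total is diluted by v0/v_i at each
    point (the provided ligand totals are taken as actual post-dilution
    totals).
    """

    ligand_totals: np.ndarray  # molar, nondecreasing
    signals: np.ndarray
    receptor_total: float  # molar
    volumes: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ligand_totals = np.asarray(self.ligand_totals, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.ligand_totals.shape != self.signals.shape:
            raise TitrationError("ligand_totals and signals must have equal length")
        if np.any(self.ligand_totals < 0):
            raise TitrationError("ligand totals must be >= 0")
        if np.any(np.diff(self.ligand_totals) < 0):
            raise TitrationError("ligand totals must be nondecreasing")
        if self.receptor_total <= 0:
            raise TitrationError("receptor_total must be positive")
        if self.volumes is not None:
            self.volumes = np.asarray(self.volumes, dtype=float)
            if self.volumes.shape != self.signals.shape:
                raise TitrationError("volumes must match the number of points")

    def receptor_series(self) -> np.ndarray:
        if self.volumes is None:
            return np.full_like(self.ligand_totals, self.receptor_total)
        return self.receptor_total * self.volumes[0] / self.volumes

    def bound_fractions(self, kd: float) -> np.ndarray:
        r_series = self.receptor_series()
        return np.array(
            [
                bound_fraction(kd, r, l)
                for r, l in zip(r_series, self.ligand_totals)
            ]
        )


def titration_model(
    curve: TitrationCurve, kd: float, signal_free: float, signal_bound: float
) -> np.ndarray:
    """Predicted signals: free-state endpoint moving to the bound endpoint."""
    f = curve.bound_fractions(kd)
    return signal_free + (signal_bound - signal_free) * f


def _profiled_ssr(curves: list[TitrationCurve], kd: float):
    """SSR at fixed Kd with per-curve endpoints solved by linear lstsq."""
    ssr = 0.0
    endpoints = []
    for curve in curves:
        f = curve.bound_fractions(kd)
        design = np.column_stack([1.0 - f, f])  # columns: signal_free, signal_bound
        coef, *_ = np.linalg.lstsq(design, curve.signals, rcond=None)
        resid = design @ coef - curve.signals
        ssr += float(resid @ resid)
        endpoints.append((float(coef[0]), float(coef[1])))
    return ssr, endpoints


@dataclass
class TitrationFitResult:
    kd: float  # molar
    ci_lower: float
    ci_upper: float
    wald_lower: float
    wald_upper: float
    endpoints: tuple[tuple[float, float], ...]  # per curve (free, bound)
    ssr: float
    confidence: float
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "Kd_M": self.kd,
            "ci_lower_M": self.ci_lower,
            "ci_upper_M": self.ci_upper,
            "wald_lower_M": self.wald_lower,
            "wald_upper_M": self.wald_upper,
            "confidence": self.confidence,
            "endpoints": [list(e) for e in self.endpoints],
            "ssr": self.ssr,
            "flags": list(self.flags),
        }


def fit_titration(
    curves, confidence: float = 0.95, log_kd_bracket: tuple[float, float] = (-12.0, -3.0)
) -> TitrationFitResult:
    """Joint nonlinear fit of a shared Kd over one or more titration curves.

    Each curve needs at least 5 ligand levels.  The confidence interval is
    the profile of the joint SSR at the threshold
    ``SSR_min * (1 + F(1, dof; confidence) / dof)``; a curve set whose best
    fit never reaches half-occupancy is flagged ``transition_not_spanned``
    (the CI is then expected to be wide or one-sided).
    """
    curves = list(curves)
    if not curves:
        raise TitrationError("need at least one titration curve")
    for c in curves:
        if len(c.signals) < 5:
            raise TitrationError("each titration curve needs >= 5 ligand levels")

    def objective(log_kd: float) -> float:
        return _profiled_ssr(curves, 10.0 ** log_kd)[0]

    res = minimize_scalar(
        objective, bounds=log_kd_bracket, method="bounded",
        options={"xatol": 1e-6},
    )
    log_kd = float(res.x)
    ssr_min, endpoints = _profiled_ssr(curves, 10.0 ** log_kd)

    n_points = sum(len(c.signals) for c in curves)
    n_params = 1 + 2 * len(curves)
    dof = max(n_points - n_params, 1)
    f_crit = float(f_dist.ppf(confidence, 1, dof))
    threshold = ssr_min * (1.0 + f_crit / dof)

    def walk(direction: int) -> float:
        v_in = log_kd
        h = 0.02
        limit = log_kd_bracket[1] if direction > 0 else log_kd_bracket[0]
        while True:
            v = v_in + direction * h
            at_limit = v >= limit if direction > 0 else v <= limit
            if at_limit:
                v = limit
            if objective(v) >= threshold:
                break
            v_in = v
            if at_limit:
                return limit
            h *= 1.6
        v_out = v
        for _ in range(60):
            mid = 0.5 * (v_in + v_out)
            if objective(mid) >= threshold:
                v_out = mid
            else:
                v_in = mid
            if abs(v_out - v_in) < 1e-4:
                break
        return 0.5 * (v_in + v_out)

    flags: list[str] = []
    if ssr_min <= 0 or threshold <= ssr_min * (1 + 1e-12):
        ci_lo = ci_hi = 10.0 ** log_kd
    else:
        ci_lo = 10.0 ** walk(-1)
        ci_hi = 10.0 ** walk(+1)

    # Wald interval from the local curvature of SSR in log10 Kd. With
    # sigma^2 estimated as SSR_min/dof, var(log Kd) = 2 sigma^2 / d2SSR.
    h = 0.01
    d2 = (objective(log_kd + h) - 2.0 * ssr_min + objective(log_kd - h)) / h**2
    if d2 > 0 and ssr_min > 0:
        se = math.sqrt(2.0 * (ssr_min / dof) / d2)
        from scipy.stats import t as t_dist

        tcrit = float(t_dist.ppf(0.5 + confidence / 2.0, dof))
        # a nearly flat profile gives an enormous se; clamp the exponents to
        # a little outside the search bracket instead of overflowing
        lo_exp = max(log_kd - tcrit * se, log_kd_bracket[0] - 3.0)
        hi_exp = min(log_kd + tcrit * se, log_kd_bracket[1] + 3.0)
        wald_lo = 10.0 ** lo_exp
        wald_hi = 10.0 ** hi_exp
    else:
        wald_lo = wald_hi = 10.0 ** log_kd

    max_bound = max(float(c.bound_fractions(10.0 ** log_kd).max()) for c in curves)
    if max_bound < 0.5:
        flags.append("transition_not_spanned")

    return TitrationFitResult(
        kd=10.0 ** log_kd,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        wald_lower=wald_lo,
        wald_upper=wald_hi,
        endpoints=tuple(endpoints),
        ssr=ssr_min,
        confidence=confidence,
        flags=tuple(flags),
    )
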