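"""Stretched-exponential fits, median reaction times, replicate summaries.

Relaxations that are not strictly single-exponential (pyrophosphorolysis,
backtracking, RNA cleavage, dinucleotide release) are summarized by fitting

    signal(t) = baseline + amplitude * (1 - exp(-(t / tau)**beta))

with a signed amplitude (negative for decays such as a 6-MI fluorescence
decrease) and reporting the *median reaction time*

    t_med = tau * (ln 2)**(1 / beta),

the time at which the fitted curve crosses half of its total amplitude.  For
beta = 1 this reduces to the ordinary half-life ln 2 / k.  Stretched
exponentials are multimodal in (tau, beta), so the fit is started from a
small documented grid of beta values with tau seeded from the observed
half-crossing, and the best sum of squares wins; a fit that lands on a beta
bound is flagged rather than silently accepted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from .ode_engine import Trace

__all__ = [
    "LN2",
    "ConstantTraceError",
    "FitDataError",
    "StretchedExpFit",
    "ReplicateSummary",
    "stretched_exponential",
    "fit_stretched_exponential",
    "median_reaction_time",
    "summarize_replicates",
    "fold_change",
]

LN2 = math.log(2.0)
BETA_BOUNDS = (0.1, 2.0)
BETA_STARTS = (0.5, 0.75, 1.0)


class ConstantTraceError(ValueError):
    """The trace carries no resolvable amplitude to fit."""


class FitDataError(ValueError):
    """The trace violates the fitting preconditions (too few points, ...)."""


def stretched_exponential(t, baseline, amplitude, tau, beta):
    """baseline + amplitude * (1 - exp(-(t/tau)**beta))."""
    t = np.asarray(t, dtype=float)
    return baseline + amplitude * (1.0 - np.exp(-np.power(t / tau, beta)))


@dataclass
class StretchedExpFit:
    """Best-fit stretched-exponential parameters plus the median-time statistic."""

    baseline: float
    amplitude: float
    tau: float
    beta: float
    rss: float
    median_time: float = field(init=False)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not BETA_BOUNDS[0] < self.beta <= BETA_BOUNDS[1] + 1e-12:
            raise ValueError(f"beta {self.beta} outside ({BETA_BOUNDS[0]}, {BETA_BOUNDS[1]}]")
        self.median_time = self.tau * LN2 ** (1.0 / self.beta)

    def predict(self, t) -> np.ndarray:
        return stretched_exponential(t, self.baseline, self.amplitude, self.tau, self.beta)

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline,
            "amplitude": self.amplitude,
            "tau_s": self.tau,
            "beta": self.beta,
            "rss": self.rss,
            "median_time_s": self.median_time,
            "flags": list(self.flags),
        }


def median_reaction_time(fit: StretchedExpFit) -> float:
    """tau * (ln 2)**(1/beta): the half-amplitude crossing of the fitted curve."""
    return fit.tau * LN2 ** (1.0 / fit.beta)


def _smooth(signal: np.ndarray) -> np.ndarray:
    w = max(3, signal.size // 20)
    kernel = np.ones(w) / w
    pad = np.r_[np.full(w - 1, signal[0]), signal, np.full(w - 1, signal[-1])]
    sm = np.convolve(pad, kernel, mode="same")
    return sm[w - 1 : w - 1 + signal.size]


def _half_crossing_guess(times: np.ndarray, signal: np.ndarray) -> float:
    sm = _smooth(signal)
    s0, s1 = sm[0], sm[-1]
    half = 0.5 * (s0 + s1)
    rising = s1 >= s0
    crossed = sm >= half if rising else sm <= half
    idx = np.argmax(crossed)
    if crossed.any() and idx > 0:
        # linear interpolation between the bracketing samples
        t0, t1 = times[idx - 1], times[idx]
        y0, y1 = sm[idx - 1], sm[idx]
        if y1 != y0:
            return float(t0 + (half - y0) * (t1 - t0) / (y1 - y0))
        return float(t1)
    return float(np.median(times))


def fit_stretched_exponential(
    trace: Trace,
    beta_starts: tuple[float, ...] = BETA_STARTS,
) -> StretchedExpFit:
    """Unweighted least-squares stretched-exponential fit of one trace.

    Requires at least 8 time points and a non-constant signal.  The fit is
    deterministic: a fixed multi-start grid over ``beta_starts`` with tau
    seeded from the observed half-crossing time.
    """
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.signal, dtype=float)
    if t.size < 8:
        raise FitDataError(f"need at least 8 time points, got {t.size}")

    ptp = float(np.ptp(y))
    if ptp == 0.0:
        raise ConstantTraceError("signal is exactly constant")
    # Noise scale from first differences; a trace whose smoothed variation is
    # indistinguishable from smoothed noise carries no amplitude to fit.
    noise = float(np.std(np.diff(y))) / math.sqrt(2.0) if t.size > 2 else 0.0
    w = max(5, t.size // 8)
    kernel = np.ones(w) / w
    heavy = np.convolve(y, kernel, mode="valid")
    if noise > 0 and float(np.std(heavy)) < 3.0 * noise / math.sqrt(w):
        raise ConstantTraceError("signal excursion is indistinguishable from noise")
    sm = _smooth(y)

    tau0 = _half_crossing_guess(t, y)
    tau0 = min(max(tau0, t[t > 0].min() if (t > 0).any() else 1e-6), t[-1])
    base0 = float(sm[0])
    amp0 = float(sm[-1] - sm[0])
    if amp0 == 0.0:
        amp0 = ptp if y[-1] >= y[0] else -ptp

    model = Model(stretched_exponential)
    flags: list[str] = []
    best = None
    for beta0 in beta_starts:
        pars = model.make_params(
            baseline={"value": base0},
            amplitude={"value": amp0},
            tau={"value": tau0 * LN2 ** (-1.0 / beta0), "min": 1e-9 * tau0},
            beta={"value": beta0, "min": BETA_BOUNDS[0], "max": BETA_BOUNDS[1]},
        )
        try:
            res = model.fit(y, pars, t=t)
        except Exception:
            continue
        rss = float(np.sum(res.residual**2))
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        raise FitDataError("stretched-exponential fit failed from every start")

    rss, res = best
    p = res.params
    if p["beta"].value <= BETA_BOUNDS[0] + 1e-3 or p["beta"].value >= BETA_BOUNDS[1] - 1e-3:
        flags.append("beta_at_bound")
    fit = StretchedExpFit(
        baseline=float(p["baseline"].value),
        amplitude=float(p["amplitude"].value),
        tau=float(p["tau"].value),
        beta=float(min(p["beta"].value, BETA_BOUNDS[1])),
        rss=rss,
        flags=tuple(flags),
    )
    if t[-1] < 2.0 * fit.median_time:
        fit.flags = fit.flags + ("short_span",)
    return fit


# ---------------------------------------------------------------------------
# Replicate summaries and fold changes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicateSummary:
    """Mean of replicate values with the field's error convention.

    The spread is the range (max - min) for duplicates, the sample SD for
    n > 2, and zero for a singleton.
    """

    values: tuple[float, ...]
    center: float
    spread: float

    def to_dict(self) -> dict:
        return {"values": list(self.values), "center": self.center, "spread": self.spread}


def summarize_replicates(values) -> ReplicateSummary:
    vals = tuple(float(v) for v in values)
    if not vals:
        raise FitDataError("cannot summarize an empty replicate list")
    center = float(np.mean(vals))
    if len(vals) == 1:
        spread = 0.0
    elif len(vals) == 2:
        spread = float(max(vals) - min(vals))
    else:
        spread = float(np.std(vals, ddof=1))
    return ReplicateSummary(vals, center, spread)


def fold_change(numerator: ReplicateSummary, denominator: ReplicateSummary) -> ReplicateSummary:
    """Ratio of centers with first-order propagation of relative spreads."""
    if denominator.center <= 0:
        raise FitDataError(
            f"fold change needs a positive denominator, got {denominator.center}"
        )
    ratio = numerator.center / denominator.center
    rel = 0.0
    if numerator.center != 0:
        rel = math.hypot(
            numerator.spread / numerator.center,
            denominator.spread / denominator.center,
        )
    return ReplicateSummary((ratio,), ratio, abs(ratio) * rel)
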