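"""Simultaneous least-squares fitting of heterogeneous kinetic datasets.

A :class:`Dataset` collects observations of different kinds — discrete
quench-flow product fractions and continuous stopped-flow fluorescence
traces — that share one kinetic scheme and one set of rate constants.  The
joint objective is

    chi2(theta) = sum_obs sum_i ((model_i - data_i) / sigma_obs)^2

with per-observation noise levels sigma.  Rate constants are optimized in
log10 space (they are positive and span orders of magnitude); the
per-trace fluorescence scale and offset nuisances are profiled analytically
inside the residual (a 2x2 linear solve per trace), which is equivalent to
optimizing them jointly but keeps the nonlinear parameter vector small.

Parameter confidence bounds follow the chi-square-threshold convention of
pre-steady-state kinetics software: the reported interval for a parameter is
the region where the *re-optimized* chi2 (all other parameters refit at each
fixed value) stays within a fractional increase — 10% by default — of its
minimum.  Endpoints are located by an outward walk plus bisection; profiles
that never reach the threshold are flagged as unbounded.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .ode_engine import Conditions, Trace, fluorescence_base, project, simulate
from .schemes import (
    KineticScheme,
    ObservableMap,
    RateParameterSet,
    build_bimolecular_binding_scheme,
)

__all__ = [
    "DatasetError",
    "GlobalFitError",
    "Observation",
    "Dataset",
    "GlobalFitResult",
    "ProfileBound",
    "chi_squared",
    "fit_global",
    "profile_bounds",
    "profile_parameter",
    "fit_binding_series",
]

DEFAULT_CHI2_INCREASE = 0.10
_LOG_SPAN = 6.0  # profile walk limit: 10^6-fold away from the best fit


class DatasetError(ValueError):
    """The dataset violates a structural precondition."""


class GlobalFitError(RuntimeError):
    """Global fitting or profiling was called outside its contract."""


@dataclass
class Observation:
    """One trace (or discrete point series) with its observable and conditions."""

    trace: Trace
    observable: ObservableMap
    conditions: Conditions | None = None
    sigma: float | None = None
    label: str = ""


@dataclass
class Dataset:
    observations: tuple[Observation, ...]

    def __post_init__(self) -> None:
        self.observations = tuple(self.observations)
        if not self.observations:
            raise DatasetError("a dataset needs at least one observation")
        for i, obs in enumerate(self.observations):
            if not obs.label:
                obs.label = f"obs{i}"
            cond = obs.conditions
            if cond is not None:
                if cond.receptor_total < 0 or any(
                    v < 0 for v in cond.species_totals.values()
                ):
                    raise DatasetError(f"negative concentration in {obs.label!r}")

    def __iter__(self):
        return iter(self.observations)

    def __len__(self) -> int:
        return len(self.observations)


@dataclass
class ProfileBound:
    lower: float
    upper: float
    lower_unbounded: bool = False
    upper_unbounded: bool = False


@dataclass
class GlobalFitResult:
    """Best-fit parameters, per-trace nuisances, chi2 and (after profiling) bounds."""

    params: RateParameterSet
    free: tuple[str, ...]
    chi2: float
    nuisances: dict[str, tuple[float, float]]  # label -> (scale, offset)
    sigmas: dict[str, float]
    converged: bool
    n_iter: int
    bounds: dict[str, tuple[float | None, float, float | None]] = field(default_factory=dict)
    flags: tuple[str, ...] = ()
    insensitive: tuple[str, ...] = ()
    derived: dict[str, float] = field(default_factory=dict)
    chi2_increase: float | None = None
    slow_fraction_derived: bool = False

    def to_dict(self) -> dict:
        return {
            "parameters": {
                name: {
                    "lower_bound": self.bounds.get(name, (None, None, None))[0],
                    "best_fit": self.params.get(name),
                    "upper_bound": self.bounds.get(name, (None, None, None))[2],
                }
                for name in self.free
            },
            "all_rates": dict(self.params.rates),
            "slow_fraction": self.params.slow_fraction,
            "chi2": self.chi2,
            "chi2_increase": self.chi2_increase,
            "nuisances": {k: list(v) for k, v in self.nuisances.items()},
            "sigmas": dict(self.sigmas),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "flags": list(self.flags),
            "insensitive": list(self.insensitive),
            "derived": dict(self.derived),
        }


# ---------------------------------------------------------------------------
# Prediction and chi2
# ---------------------------------------------------------------------------

def _predict_observation(
    obs: Observation, scheme: KineticScheme, params: RateParameterSet
) -> tuple[np.ndarray, tuple[float, float]]:
    """Model signal for one observation, with profiled (scale, offset)."""
    traj = simulate(scheme, params, obs.trace.times, obs.conditions)
    if obs.observable.kind == "state_sum":
        return project(traj, obs.observable), (1.0, 0.0)
    base = fluorescence_base(traj, obs.observable)
    design = np.column_stack([base, np.ones_like(base)])
    coef, *_ = np.linalg.lstsq(design, obs.trace.signal, rcond=None)
    scale, offset = float(coef[0]), float(coef[1])
    return offset + scale * base, (scale, offset)


def _sigma_of(obs: Observation) -> float:
    sigma = 1.0 if obs.sigma is None else float(obs.sigma)
    if sigma <= 0:
        raise DatasetError(f"observation {obs.label!r} has variance <= 0")
    return sigma


def chi_squared(
    params: RateParameterSet, dataset: Dataset, scheme: KineticScheme
) -> float:
    """Joint chi2 over all observations with profiled per-trace nuisances."""
    total = 0.0
    for obs in dataset:
        sigma = _sigma_of(obs)
        pred, _ = _predict_observation(obs, scheme, params)
        r = (pred - obs.trace.signal) / sigma
        total += float(r @ r)
    return total


# ---------------------------------------------------------------------------
# Internal parameterization: log10 for rates, linear for slow_fraction
# ---------------------------------------------------------------------------

class _Problem:
    def __init__(
        self,
        dataset: Dataset,
        scheme: KineticScheme,
        base: RateParameterSet,
        free: tuple[str, ...],
        sigmas: dict[str, float],
        derive_slow_fraction: bool = False,
    ):
        rate_names = set(scheme.rate_names())
        allowed = rate_names | set(scheme.initial_parameter_names()) | {"slow_fraction"}
        for name in free:
            if name not in allowed:
                raise DatasetError(f"free parameter {name!r} is not in the scheme")
        if derive_slow_fraction and "slow_fraction" in free:
            raise DatasetError(
                "slow_fraction cannot be free when derived from the pre-equilibrium"
            )
        self.dataset = dataset
        # canonical observation order: chi2 and fits are invariant under
        # permutation of the observations
        self.ordered = tuple(sorted(dataset, key=lambda o: o.label))
        self.scheme = scheme
        self.base = base
        self.free = tuple(free)
        self.sigmas = sigmas
        self.derive_slow_fraction = derive_slow_fraction
        self.is_log = tuple(name != "slow_fraction" for name in self.free)
        self.lower = np.array(
            [-12.0 if lg else 0.0 for lg in self.is_log]
        )
        self.upper = np.array([12.0 if lg else 1.0 for lg in self.is_log])

    def to_internal(self, params: RateParameterSet) -> np.ndarray:
        vals = []
        for name, lg in zip(self.free, self.is_log):
            v = params.get(name)
            vals.append(math.log10(max(v, 1e-300)) if lg else v)
        return np.array(vals)

    def from_internal(self, x: np.ndarray) -> RateParameterSet:
        changes = {
            name: (10.0 ** v if lg else float(np.clip(v, 0.0, 1.0)))
            for name, lg, v in zip(self.free, self.is_log, x)
        }
        params = self.base.updated(**changes)
        if self.derive_slow_fraction:
            # initial inactive fraction from the slow pre-equilibrium
            k_rec, k_inact = params.get("k_rec"), params.get("k_inact")
            total = k_rec + k_inact
            params = params.updated(
                slow_fraction=k_inact / total if total > 0 else 0.0
            )
        return params

    def residual(self, x: np.ndarray) -> np.ndarray:
        params = self.from_internal(x)
        parts = []
        for obs in self.ordered:
            sigma = self.sigmas[obs.label]
            pred, _ = _predict_observation(obs, self.scheme, params)
            parts.append((pred - obs.trace.signal) / sigma)
        return np.concatenate(parts)

    def chi2(self, x: np.ndarray) -> float:
        r = self.residual(x)
        return float(r @ r)


def _minimize(problem: _Problem, x0: np.ndarray, **kwargs):
    return least_squares(
        problem.residual,
        np.clip(x0, problem.lower, problem.upper),
        bounds=(problem.lower, problem.upper),
        method="trf",
        x_scale="jac",
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Global fit
# ---------------------------------------------------------------------------

def fit_global(
    dataset: Dataset,
    scheme: KineticScheme,
    initial: RateParameterSet,
    free: tuple[str, ...],
    *,
    reweight: bool = True,
    starts: tuple[float, ...] = (1.0,),
    late_fraction: float = 0.2,
    derive_slow_fraction: bool = False,
) -> GlobalFitResult:
    """Joint local least-squares fit of ``free`` parameters to ``dataset``.

    ``starts`` is a truth-agnostic multi-start grid of multiplicative factors
    applied to the initial rate values (slow_fraction is never scaled); the
    start with the lowest chi2 wins.  When ``reweight`` is set and an
    observation carries no explicit sigma, a pilot unit-weight fit is run and
    each observation's sigma is estimated from the sample SD of its late-time
    residuals (the final ``late_fraction`` of points, at least 4), after
    which the weighted fit is rerun.

    With ``derive_slow_fraction`` the initial inactive fraction is not a free
    parameter but the pre-equilibrium value k_inact / (k_rec + k_inact) —
    the assembled complexes interconvert slowly before the reaction starts,
    so their initial split reflects that equilibrium.  This couples the
    otherwise barely-identifiable inactivation rate to the slow-phase
    amplitude.
    """
    if not free:
        raise DatasetError("free parameter list is empty")
    unit_sigmas = {obs.label: _sigma_of(obs) for obs in dataset}
    problem = _Problem(
        dataset, scheme, initial, tuple(free), unit_sigmas,
        derive_slow_fraction=derive_slow_fraction,
    )

    def run(prob: _Problem, x0: np.ndarray):
        best = None
        for factor in starts:
            shift = np.array(
                [math.log10(factor) if lg else 0.0 for lg in prob.is_log]
            )
            res = _minimize(prob, x0 + shift)
            if best is None or res.cost < best.cost:
                best = res
        return best

    x0 = problem.to_internal(initial)
    res = run(problem, x0)

    needs_estimate = reweight and any(obs.sigma is None for obs in dataset)
    if needs_estimate:
        params_pilot = problem.from_internal(res.x)
        sigmas = {}
        for obs in dataset:
            if obs.sigma is not None:
                sigmas[obs.label] = float(obs.sigma)
                continue
            pred, _ = _predict_observation(obs, scheme, params_pilot)
            r = pred - obs.trace.signal
            n_late = max(4, int(math.ceil(late_fraction * r.size)))
            tail = r[-n_late:]
            est = float(np.std(tail, ddof=1))
            sigmas[obs.label] = est if est > 0 else 1.0
        problem = _Problem(
            dataset, scheme, initial, tuple(free), sigmas,
            derive_slow_fraction=derive_slow_fraction,
        )
        res = run(problem, res.x)
    else:
        sigmas = unit_sigmas

    params = problem.from_internal(res.x)
    chi2 = 2.0 * float(res.cost)

    nuisances = {}
    for obs in dataset:
        _, nu = _predict_observation(obs, scheme, params)
        nuisances[obs.label] = nu

    # Structural identifiability: a parameter whose jacobian column is
    # (numerically) zero has no sensitivity in this design.
    jac = np.asarray(res.jac)
    col_norms = np.linalg.norm(jac, axis=0)
    ref = max(col_norms.max(), 1.0)
    insensitive = tuple(
        name for name, cn in zip(problem.free, col_norms) if cn < 1e-10 * ref
    )

    converged = bool(res.success)
    flags = () if converged else ("not_converged: " + str(res.message),)
    result = GlobalFitResult(
        params=params,
        free=problem.free,
        chi2=chi2,
        nuisances=nuisances,
        sigmas=sigmas,
        converged=converged,
        n_iter=int(res.nfev),
        bounds={name: (None, params.get(name), None) for name in problem.free},
        flags=flags,
        insensitive=insensitive,
        slow_fraction_derived=derive_slow_fraction,
    )
    return result


# ---------------------------------------------------------------------------
# Profile bounds at a fractional chi2 increase
# ---------------------------------------------------------------------------

def profile_parameter(
    residual,
    x_best: np.ndarray,
    index: int,
    threshold: float,
    *,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
    step: float = 0.1,
    span: float = _LOG_SPAN,
    rel_tol: float = 0.01,
) -> ProfileBound:
    """Profile one coordinate of a least-squares problem.

    ``residual`` maps the full internal parameter vector to a residual array;
    the profile chi2 at a fixed coordinate value re-optimizes all the other
    coordinates (warm-started while walking outward).  Returns the interval
    where the profile chi2 stays <= ``threshold``; endpoints are refined by
    bisection to ``rel_tol`` relative precision in the coordinate, and a side
    that never crosses the threshold within ``span`` of the optimum is
    flagged as unbounded.
    """
    x_best = np.asarray(x_best, dtype=float)
    m = x_best.size
    others = [j for j in range(m) if j != index]
    lo_all = np.full(m, -np.inf) if lower is None else np.asarray(lower, float)
    hi_all = np.full(m, np.inf) if upper is None else np.asarray(upper, float)

    def chi2_fixed(v: float, x_other0: np.ndarray) -> tuple[float, np.ndarray]:
        if not others:
            full = np.array([v])
            r = residual(full)
            return float(r @ r), x_other0
        def red(xo):
            full = np.empty(m)
            full[index] = v
            full[others] = xo
            return residual(full)
        res = least_squares(
            red,
            np.clip(x_other0, lo_all[others], hi_all[others]),
            bounds=(lo_all[others], hi_all[others]),
            method="trf",
            x_scale="jac",
        )
        return 2.0 * float(res.cost), res.x

    r0 = residual(x_best)
    chi2_min = float(r0 @ r0)
    if threshold <= chi2_min * (1 + 1e-12) + 1e-300:
        # Degenerate (e.g. noiseless data): the allowed region collapses.
        v = float(x_best[index])
        return ProfileBound(v, v)

    hard_lo = max(lo_all[index], x_best[index] - span)
    hard_hi = min(hi_all[index], x_best[index] + span)

    def walk(direction: int) -> tuple[float, bool]:
        limit = hard_hi if direction > 0 else hard_lo
        v_in, chi2_in = float(x_best[index]), chi2_min
        x_other = x_best[others].copy() if others else np.empty(0)
        h = step
        while True:
            v = v_in + direction * h
            at_limit = (v >= limit) if direction > 0 else (v <= limit)
            if at_limit:
                v = limit
            c, x_other = chi2_fixed(v, x_other)
            if c >= threshold:
                break
            v_in, chi2_in = v, c
            if at_limit:
                return limit, True  # never crossed within the allowed span
            h *= 1.7
        # bisect between v_in (inside) and v (outside)
        v_out = v
        for _ in range(60):
            mid = 0.5 * (v_in + v_out)
            c, x_other = chi2_fixed(mid, x_other)
            if c >= threshold:
                v_out = mid
            else:
                v_in = mid
            close = abs(c - threshold) <= rel_tol * threshold
            narrow = abs(v_out - v_in) <= rel_tol * max(abs(v_in), 1e-3)
            if close or narrow:
                break
        return 0.5 * (v_in + v_out), False

    up_v, up_unb = walk(+1)
    lo_v, lo_unb = walk(-1)
    return ProfileBound(lo_v, up_v, lower_unbounded=lo_unb, upper_unbounded=up_unb)


def profile_bounds(
    fit: GlobalFitResult,
    dataset: Dataset,
    scheme: KineticScheme,
    chi2_increase: float = DEFAULT_CHI2_INCREASE,
    rel_tol: float = 0.01,
) -> dict[str, ProfileBound]:
    """Per-parameter (lower, upper) interval at a fractional chi2 increase.

    For each free parameter the interval is the region where the chi2,
    re-optimized over all other parameters, stays within
    ``(1 + chi2_increase) * chi2_min``.  Bounds are returned on the natural
    parameter scale and also written into ``fit.bounds``.
    """
    if not fit.converged:
        raise GlobalFitError("profile_bounds requires a converged fit")
    problem = _Problem(
        dataset, scheme, fit.params, fit.free, fit.sigmas,
        derive_slow_fraction=fit.slow_fraction_derived,
    )
    x_best = problem.to_internal(fit.params)
    chi2_min = problem.chi2(x_best)
    threshold = (1.0 + chi2_increase) * chi2_min

    out: dict[str, ProfileBound] = {}
    for i, (name, lg) in enumerate(zip(problem.free, problem.is_log)):
        pb = profile_parameter(
            problem.residual,
            x_best,
            i,
            threshold,
            lower=problem.lower,
            upper=problem.upper,
            step=0.1 if lg else 0.02,
            span=_LOG_SPAN if lg else 1.0,
            rel_tol=rel_tol if lg else max(rel_tol * 0.5, 0.005),
        )
        if lg:
            pb = ProfileBound(
                10.0 ** pb.lower,
                10.0 ** pb.upper,
                pb.lower_unbounded,
                pb.upper_unbounded,
            )
        if name in fit.insensitive:
            pb.lower_unbounded = pb.upper_unbounded = True
        out[name] = pb
        fit.bounds[name] = (pb.lower, fit.params.get(name), pb.upper)
    fit.chi2_increase = chi2_increase
    return out


# ---------------------------------------------------------------------------
# Binding-kinetics series
# ---------------------------------------------------------------------------

def fit_binding_series(
    traces,
    initial: RateParameterSet | None = None,
    ligand: str = "NusG",
    *,
    starts: tuple[float, ...] = (0.1, 1.0, 10.0),
) -> GlobalFitResult:
    """Joint fit of k_on and k_off across a ligand-concentration series.

    Each trace's metadata must carry the molar post-mix totals
    ``ligand_total_M`` and ``receptor_total_M``.  At least three distinct
    ligand concentrations are required — with a single concentration the
    association and dissociation rates are not separable.  The derived
    equilibrium constant Kd = k_off / k_on is reported in ``result.derived``.
    """
    traces = list(traces)
    totals = []
    for tr in traces:
        try:
            totals.append(float(tr.meta["ligand_total_M"]))
        except KeyError:
            raise DatasetError(
                "every binding trace needs meta['ligand_total_M'] (molar, post-mix)"
            ) from None
    if len(set(np.round(totals, 15))) < 3:
        raise DatasetError(
            "binding-series fit needs >= 3 distinct ligand concentrations; "
            "k_on and k_off are not separable from fewer"
        )
    scheme = build_bimolecular_binding_scheme(ligand)
    obs_map = ObservableMap(kind="fluorescence", coefficients={"TEC_bound": 1.0})
    observations = []
    for i, tr in enumerate(traces):
        cond = Conditions(
            receptor_total=float(tr.meta["receptor_total_M"]),
            species_totals={ligand: float(tr.meta["ligand_total_M"])},
        )
        observations.append(
            Observation(tr, obs_map, cond, label=tr.meta.get("label", f"conc{i}"))
        )
    dataset = Dataset(tuple(observations))
    if initial is None:
        initial = RateParameterSet({"k_on": 1e6, "k_off": 1.0})
    result = fit_global(
        dataset, scheme, initial, ("k_on", "k_off"), starts=starts
    )
    k_on = result.params.get("k_on")
    k_off = result.params.get("k_off")
    if k_on > 0:
        result.derived["Kd_M"] = k_off / k_on
    return result
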