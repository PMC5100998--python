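"""Numerical integration of mass-action schemes and observable projection.

The engine integrates state *fractions* with a stiff-capable solver (LSODA).
Rate constants within one scheme can span several orders of magnitude
(0.02–93 s^-1 in the fits this package targets), hence the tight tolerances.
Bimolecular transitions couple to tracked species through the free
concentration ``total - receptor_total * sum(stoich_s * fraction_s)``, which
makes the system nonlinear but keeps ligand conservation exact by
construction.

Solver noise is controlled, not ignored: fractions in [-1e-10, 0) are clamped
to zero, anything more negative raises, and each output row is renormalized
(the raw deviation from unit sum is checked against 1e-8 first).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .schemes import KineticScheme, ObservableMap, RateParameterSet, SchemeError

__all__ = [
    "Conditions",
    "Trace",
    "Trajectory",
    "IntegrationError",
    "ObservableError",
    "simulate",
    "project",
]

_NEG_TOL = 1e-10
_SUM_TOL = 1e-8
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12  # kept well below the -1e-10 clamp threshold


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the time at which it gave up."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class ObservableError(ValueError):
    """An observable references states absent from the trajectory."""


@dataclass(frozen=True)
class Conditions:
    """Per-experiment conditions bound at simulation time.

    ``receptor_total`` and ``species_totals`` are molar; ``dead_time`` is the
    stopped-flow dead time in seconds (bookkeeping only — generators and
    readers truncate, the integrator itself starts at t = 0, the instant of
    mixing).
    """

    receptor_total: float = 0.0
    species_totals: dict[str, float] = field(default_factory=dict)
    dead_time: float = 0.0


@dataclass
class Trace:
    """One time-resolved observable: times (s), signal, condition metadata."""

    times: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class Trajectory:
    """State fractions over time plus free concentrations of tracked species."""

    times: np.ndarray
    states: tuple[str, ...]
    state_fractions: np.ndarray  # time x state
    species_free: dict[str, np.ndarray] = field(default_factory=dict)
    species_totals: dict[str, float] = field(default_factory=dict)
    receptor_total: float = 0.0

    def fraction(self, state: str) -> np.ndarray:
        try:
            return self.state_fractions[:, self.states.index(state)]
        except ValueError:
            raise ObservableError(f"unknown state {state!r}") from None

    def species_bound(self, species: str) -> np.ndarray:
        """Molar concentration of a species sequestered by the receptor."""
        return self.species_totals[species] - self.species_free[species]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, state, fraction) table."""
        n_t, n_s = self.state_fractions.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.times, n_s),
                "state": list(self.states) * n_t,
                "fraction": self.state_fractions.ravel(),
            }
        )


def _resolve_rates(scheme: KineticScheme, params: RateParameterSet) -> np.ndarray:
    rates = np.empty(len(scheme.transitions))
    for i, tr in enumerate(scheme.transitions):
        k = params.get(tr.rate)  # raises SchemeError when missing
        if k < 0:
            raise SchemeError(f"rate {tr.rate!r} is negative: {k}")
        rates[i] = k
    return rates


def simulate(
    scheme: KineticScheme,
    params: RateParameterSet,
    times,
    conditions: Conditions | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate ``scheme`` under ``params`` and report fractions at ``times``.

    ``times`` must be strictly increasing with ``times[0] >= 0``.  Conditions
    must supply a molar total for every species-multiplied transition, plus
    ``receptor_total`` so depletion can be computed.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if times[0] < 0 or (times.size > 1 and np.any(np.diff(times) <= 0)):
        raise ValueError("times must be strictly increasing and start at t >= 0")

    conditions = conditions or Conditions()
    rates = _resolve_rates(scheme, params)
    y0 = np.asarray(scheme.initial_fractions(params), dtype=float)

    state_index = {s: i for i, s in enumerate(scheme.states)}
    src = np.array([state_index[tr.source] for tr in scheme.transitions])
    tgt = np.array([state_index[tr.target] for tr in scheme.transitions])

    species = scheme.species_names()
    for sp in species:
        if sp not in conditions.species_totals:
            raise SchemeError(f"conditions missing total concentration for species {sp!r}")
    if species and conditions.receptor_total <= 0:
        raise SchemeError("receptor_total must be positive when species are tracked")

    # Per-species stoichiometry vector over states (molecules bound per receptor).
    stoich = {
        sp: np.array(
            [scheme.species_stoichiometry.get(sp, {}).get(s, 0.0) for s in scheme.states]
        )
        for sp in species
    }
    tr_species = [tr.species for tr in scheme.transitions]
    r_tot = conditions.receptor_total

    def free_conc(sp: str, y: np.ndarray) -> float:
        return max(conditions.species_totals[sp] - r_tot * float(stoich[sp] @ y), 0.0)

    n_tr = len(scheme.transitions)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        for i in range(n_tr):
            flux = rates[i] * y[src[i]]
            sp = tr_species[i]
            if sp is not None:
                flux *= free_conc(sp, y)
            dy[src[i]] -= flux
            dy[tgt[i]] += flux
        return dy

    t_end = float(times[-1])
    if t_end == 0.0:
        frac = np.tile(y0, (times.size, 1))
    else:
        sol = solve_ivp(
            rhs,
            (0.0, t_end),
            y0,
            method="LSODA",
            t_eval=times,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            t_fail = float(sol.t[-1]) if sol.t.size else 0.0
            raise IntegrationError(
                f"ODE solver failed at t = {t_fail:g} s: {sol.message}", time=t_fail
            )
        frac = sol.y.T.copy()

    low = frac.min()
    if low < -_NEG_TOL:
        raise IntegrationError(
            f"state fraction dropped to {low:.3e}, below the -1e-10 tolerance"
        )
    np.clip(frac, 0.0, None, out=frac)

    row_sums = frac.sum(axis=1)
    worst = np.abs(row_sums - 1.0).max()
    if worst > _SUM_TOL:
        raise IntegrationError(
            f"mass conservation violated by {worst:.3e} (> 1e-8)"
        )
    frac /= row_sums[:, None]

    species_free = {
        sp: np.maximum(
            conditions.species_totals[sp] - r_tot * frac @ stoich[sp], 0.0
        )
        for sp in species
    }
    return Trajectory(
        times=times,
        states=scheme.states,
        state_fractions=frac,
        species_free=species_free,
        species_totals={sp: conditions.species_totals[sp] for sp in species},
        receptor_total=r_tot,
    )


def project(traj: Trajectory, obs: ObservableMap) -> np.ndarray:
    """Project a trajectory onto an observable signal series."""
    unknown = obs.referenced_states() - set(traj.states)
    if unknown:
        raise ObservableError(f"observable references unknown states {sorted(unknown)}")
    if obs.kind == "state_sum":
        idx = [traj.states.index(s) for s in obs.product_states]
        return traj.state_fractions[:, idx].sum(axis=1)
    base = fluorescence_base(traj, obs)
    return obs.offset + obs.scale * base


def fluorescence_base(traj: Trajectory, obs: ObservableMap) -> np.ndarray:
    """Coefficient-weighted state sum, before the scale/offset nuisances."""
    unknown = set(obs.coefficients) - set(traj.states)
    if unknown:
        raise ObservableError(f"observable references unknown states {sorted(unknown)}")
    coeff = np.array([obs.coefficients.get(s, 0.0) for s in traj.states])
    return traj.state_fractions @ coeff
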