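"""Seeded generators for every input class the analysis pipeline consumes.

The study's raw instrument traces are not deposited, so each assay class is
emulated with its design parameters: quench-flow product fractions at
log-spaced times in the instrument's 0.004–10 s window, stopped-flow
fluorescence relaxations sampled uniformly after a 1.5 ms dead time,
depletion-regime equilibrium titrations at 100 nM receptor, and bimolecular
binding transients at 0.1–10 µM post-mix ligand (half the syringe values —
equal volumes of the TEC and additive solutions are mixed).  Noise is
additive, homoscedastic Gaussian per trace, with SD specified as a fraction
of the full signal amplitude (defaults: 1% stopped flow, 2% quench flow; the
source figures do not quantify instrument noise, so these are declared
assumptions).  All generators are bit-reproducible per (spec, seed).

``CONDITION_PRESETS`` mirrors the study's per-condition median reaction
times (wild type, cleft-loop deletions, upstream-DNA mismatches, with and
without NusG) as single-exponential targets: the backtracking-limited
cleavage chain is given an entry rate such that the noiseless trace crosses
half-amplitude exactly at the target median.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .equilibrium import TitrationCurve, titration_model
from .ode_engine import Conditions, Trace, project, simulate
from .schemes import ObservableMap, RateParameterSet, scheme_by_name

__all__ = [
    "GeneratorSpec",
    "ConditionPreset",
    "CONDITION_PRESETS",
    "resolve_preset",
    "generate_quench_flow",
    "generate_stopped_flow_trace",
    "generate_binding_series",
    "generate_titration",
    "preset_generator_spec",
    "replicate",
    "TABLE1_MINUS_NUSG",
]

#: Best-fit rate constants of the three-step mechanism without NusG
#: (nucleotide addition 28 s^-1, translocation 65 s^-1, recovery 1.1 s^-1,
#: inactivation 0.09 s^-1, slow fraction 8%).
TABLE1_MINUS_NUSG = RateParameterSet(
    {"k_add": 28.0, "k_tr": 65.0, "k_rec": 1.1, "k_inact": 0.09},
    slow_fraction=0.08,
)

QUENCH_FLOW_WINDOW = (0.004, 10.0)  # instrument sampling window, seconds
DEFAULT_DEAD_TIME = 0.0015  # stopped-flow dead time, seconds
DEFAULT_NOISE_STOPPED_FLOW = 0.01
DEFAULT_NOISE_QUENCH_FLOW = 0.02
CLEAVAGE_RATE_RATIO = 100.0  # k_cleave / k_bt in backtracking-limited presets


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic experiment.

    ``noise`` is the Gaussian SD as a fraction of the full (noiseless) signal
    amplitude; ``seed`` feeds ``numpy.random.default_rng`` and is recorded in
    every output's metadata.
    """

    scheme: str
    params: RateParameterSet | None
    assay: str  # quench_flow | stopped_flow | titration | binding_series
    seed: int
    noise: float = 0.01
    n_points: int = 400
    duration: float | None = None
    window: tuple[float, float] = QUENCH_FLOW_WINDOW
    dead_time: float = DEFAULT_DEAD_TIME
    conditions: Conditions | None = None
    observable: ObservableMap | None = None
    # Equilibrium-titration fields
    kd: float | None = None
    receptor_total: float = 1e-7  # 100 nM design
    signal_free: float = 1.0
    signal_bound: float = 2.0

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class ConditionPreset:
    """A study condition expressed as target median reaction times (seconds)."""

    label: str
    median_minus_nusg: float
    median_plus_nusg: float
    direction: int = +1  # +1 rising signal (2-AP), -1 falling (6-MI)
    beta: float = 1.0

    def target(self, plus_nusg: bool) -> float:
        return self.median_plus_nusg if plus_nusg else self.median_minus_nusg


CONDITION_PRESETS: dict[str, ConditionPreset] = {
    # RNA cleavage / dinucleotide release, matched and perturbed TECs (2-AP rise)
    "WT": ConditionPreset("WT", 12.4, 30.3),
    "dRL": ConditionPreset("dRL", 11.1, 25.7),
    "dLL": ConditionPreset("dLL", 11.4, 20.6),
    "dGL": ConditionPreset("dGL", 24.0, 54.1),
    "mm1": ConditionPreset("mm1", 19.9, 42.9),
    "mm1-2": ConditionPreset("mm1-2", 2.30, 3.11),
    "3pmm": ConditionPreset("3pmm", 0.34, 0.36),
    # Method cross-checks on the wild-type TEC
    "WT-2AP": ConditionPreset("WT-2AP", 12.4, 30.3),
    "WT-6MI": ConditionPreset("WT-6MI", 13.2, 28.0, direction=-1),
    "WT-RNA18": ConditionPreset("WT-RNA18", 11.7, 30.4),
    "WT-RNA16": ConditionPreset("WT-RNA16", 11.6, 30.1),
    # Pyrophosphorolysis-driven backward translocation (6-MI decrease)
    "pyrophosphorolysis": ConditionPreset("pyrophosphorolysis", 0.49, 0.51, direction=-1),
}

_PRESET_ALIASES = {
    "ΔRL": "dRL",
    "ΔLL": "dLL",
    "ΔGL": "dGL",
    "3'mm": "3pmm",
    "3'-mm": "3pmm",
}


def resolve_preset(label: str) -> ConditionPreset:
    key = _PRESET_ALIASES.get(label, label)
    try:
        return CONDITION_PRESETS[key]
    except KeyError:
        raise KeyError(
            f"unknown condition preset {label!r}; known: {sorted(CONDITION_PRESETS)}"
        ) from None


def _chain_entry_rate(median: float, ratio: float = CLEAVAGE_RATE_RATIO) -> float:
    """Entry rate k_bt such that the two-step chain median equals ``median``.

    For the irreversible chain k_bt -> k_cleave with k_cleave = ratio * k_bt,
    the uncleaved fraction is (ratio e^{-z} - e^{-ratio z}) / (ratio - 1) in
    the scaled time z = k_bt t; solve for the z at half-completion.
    """
    def uncleaved(z: float) -> float:
        return (ratio * math.exp(-z) - math.exp(-ratio * z)) / (ratio - 1.0)

    z_half = brentq(lambda z: uncleaved(z) - 0.5, 1e-9, 60.0)
    return z_half / median


def preset_generator_spec(
    label: str,
    plus_nusg: bool = False,
    seed: int = 0,
    noise: float = DEFAULT_NOISE_STOPPED_FLOW,
    n_points: int = 400,
) -> GeneratorSpec:
    """Stopped-flow generator spec reproducing a condition's median time.

    The condition is emulated with the backtracking-limited cleavage chain:
    k_cleave is 100x the backtracking entry rate, so the observed relaxation
    is governed by k_bt and the noiseless half-amplitude crossing lands
    exactly on the preset median.
    """
    preset = resolve_preset(label)
    median = preset.target(plus_nusg)
    k_bt = _chain_entry_rate(median)
    params = RateParameterSet(
        {"k_bt": k_bt, "k_fwd": 0.0, "k_cleave": CLEAVAGE_RATE_RATIO * k_bt}
    )
    coeff = 1.0 if preset.direction > 0 else -1.0
    observable = ObservableMap(
        kind="fluorescence",
        coefficients={"TEC_cleaved": coeff},
        scale=1.0,
        offset=0.1 if preset.direction > 0 else 1.1,
    )
    return GeneratorSpec(
        scheme="backtrack_cleavage",
        params=params,
        assay="stopped_flow",
        seed=seed,
        noise=noise,
        n_points=n_points,
        duration=8.0 * median,
        observable=observable,
    )


def _amplitude(noiseless: np.ndarray, obs: ObservableMap | None) -> float:
    ptp = float(np.ptp(noiseless))
    if ptp > 1e-300:
        return ptp
    # Degenerate (flat) signal: fall back to the observable scale so that a
    # requested noise fraction still produces a noisy flat trace.
    return abs(obs.scale) if obs is not None else 1.0


def generate_quench_flow(spec: GeneratorSpec) -> Trace:
    """Discrete product-fraction points at log-spaced times with seeded noise."""
    if spec.assay != "quench_flow":
        raise ValueError(f"spec assay is {spec.assay!r}, expected 'quench_flow'")
    scheme = scheme_by_name(spec.scheme)
    obs = spec.observable or ObservableMap(
        kind="state_sum", product_states=frozenset({"TEC17_pre", "TEC17_post"})
    )
    n = spec.n_points if spec.n_points else 12
    times = np.geomspace(spec.window[0], spec.window[1], n)
    traj = simulate(scheme, spec.params, times, spec.conditions)
    clean = project(traj, obs)
    rng = np.random.default_rng(spec.seed)
    noisy = clean + rng.normal(0.0, spec.noise * _amplitude(clean, obs), clean.shape)
    return Trace(
        times,
        noisy,
        meta={
            "assay": "quench_flow",
            "scheme": spec.scheme,
            "seed": spec.seed,
            "noise": spec.noise,
            "window_s": list(spec.window),
        },
    )


def generate_stopped_flow_trace(spec: GeneratorSpec) -> Trace:
    """Uniformly sampled fluorescence trace starting after the dead time."""
    if spec.assay != "stopped_flow":
        raise ValueError(f"spec assay is {spec.assay!r}, expected 'stopped_flow'")
    if spec.duration is None:
        raise ValueError("stopped-flow spec needs a duration")
    if spec.observable is None:
        raise ValueError("stopped-flow spec needs a fluorescence observable")
    scheme = scheme_by_name(spec.scheme)
    times = np.linspace(spec.dead_time, spec.duration, spec.n_points)
    traj = simulate(scheme, spec.params, times, spec.conditions)
    clean = project(traj, spec.observable)
    rng = np.random.default_rng(spec.seed)
    noisy = clean + rng.normal(
        0.0, spec.noise * _amplitude(clean, spec.observable), clean.shape
    )
    return Trace(
        times,
        noisy,
        meta={
            "assay": "stopped_flow",
            "scheme": spec.scheme,
            "seed": spec.seed,
            "noise": spec.noise,
            "dead_time_s": spec.dead_time,
        },
    )


def generate_binding_series(
    spec: GeneratorSpec,
    syringe_ligand_M,
    receptor_syringe_M: float = 4e-7,
    ligand: str = "NusG",
) -> list[Trace]:
    """Bimolecular binding transients over a ligand concentration series.

    ``syringe_ligand_M`` holds the pre-mix syringe molarities; equal-volume
    mixing halves both the ligand and the receptor, and the post-mix totals
    are recorded in each trace's metadata.  Trace durations adapt to the
    expected relaxation rate k_on * L + k_off (about five relaxation times).
    """
    if spec.assay != "binding_series":
        raise ValueError(f"spec assay is {spec.assay!r}, expected 'binding_series'")
    syringe = list(syringe_ligand_M)
    if not syringe:
        raise ValueError("need at least one ligand concentration")
    scheme = scheme_by_name(spec.scheme)
    obs = spec.observable or ObservableMap(
        kind="fluorescence", coefficients={"TEC_bound": 1.0}, scale=1.0, offset=1.0
    )
    k_on = spec.params.get("k_on")
    k_off = spec.params.get("k_off")
    receptor_total = receptor_syringe_M / 2.0
    traces: list[Trace] = []
    for i, syr in enumerate(syringe):
        ligand_total = syr / 2.0
        rate_guess = k_on * ligand_total + k_off
        duration = spec.duration or 5.0 / rate_guess
        times = np.linspace(spec.dead_time, duration, spec.n_points)
        cond = Conditions(
            receptor_total=receptor_total, species_totals={ligand: ligand_total}
        )
        traj = simulate(scheme, spec.params, times, cond)
        clean = project(traj, obs)
        rng = np.random.default_rng(spec.seed + i)
        noisy = clean + rng.normal(0.0, spec.noise * _amplitude(clean, obs), clean.shape)
        traces.append(
            Trace(
                times,
                noisy,
                meta={
                    "assay": "binding_series",
                    "scheme": spec.scheme,
                    "seed": spec.seed + i,
                    "noise": spec.noise,
                    "dead_time_s": spec.dead_time,
                    "ligand": ligand,
                    "syringe_ligand_M": syr,
                    "ligand_total_M": ligand_total,
                    "receptor_syringe_M": receptor_syringe_M,
                    "receptor_total_M": receptor_total,
                    "label": f"L{syr * 1e6:g}uM",
                },
            )
        )
    return traces


def generate_titration(spec: GeneratorSpec, ligand_levels) -> TitrationCurve:
    """Equilibrium titration signals at the given nondecreasing ligand totals."""
    if spec.assay != "titration":
        raise ValueError(f"spec assay is {spec.assay!r}, expected 'titration'")
    if spec.kd is None:
        raise ValueError("titration spec needs a kd")
    levels = np.asarray(list(ligand_levels), dtype=float)
    curve = TitrationCurve(
        ligand_totals=levels,
        signals=np.zeros_like(levels),
        receptor_total=spec.receptor_total,
    )
    clean = titration_model(curve, spec.kd, spec.signal_free, spec.signal_bound)
    rng = np.random.default_rng(spec.seed)
    sd = spec.noise * abs(spec.signal_bound - spec.signal_free)
    noisy = clean + rng.normal(0.0, sd, clean.shape)
    return TitrationCurve(
        ligand_totals=levels,
        signals=noisy,
        receptor_total=spec.receptor_total,
        meta={
            "assay": "titration",
            "seed": spec.seed,
            "noise": spec.noise,
            "kd_M": spec.kd,
            "signal_free": spec.signal_free,
            "signal_bound": spec.signal_bound,
        },
    )


def replicate(spec: GeneratorSpec, seed: int) -> GeneratorSpec:
    """Same design, new seed — convenience for replicate simulations."""
    return replace(spec, seed=seed)
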