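"""Declarative mass-action kinetic schemes for transcription elongation complexes.

A :class:`KineticScheme` is a small state graph: named states, mass-action
transitions (each carrying the *name* of a rate parameter, bound to a value
only at simulation or fit time), and an initial distribution over states.
Transitions may optionally be multiplied by the free concentration of a
tracked species (e.g. NusG in the bimolecular binding scheme), with explicit
depletion bookkeeping: the free concentration is the total minus whatever is
sequestered by receptor states, as declared in ``species_stoichiometry``.

Three schemes used throughout the package are provided as constructors:

* :func:`build_three_step_scheme` — single-round nucleotide addition and
  forward translocation by a TEC16, with a slow inactive fraction that
  recovers reversibly (rates ``k_rec``/``k_inact``) before the irreversible
  nucleotide addition (``k_add``) and translocation (``k_tr``) steps.
* :func:`build_bimolecular_binding_scheme` — one-step reversible binding of a
  ligand (NusG) to the TEC with ligand depletion (``k_on``, ``k_off``).
* :func:`build_backtrack_cleavage_scheme` — backtracking followed by
  factor-assisted RNA cleavage (``k_bt``, ``k_fwd``, ``k_cleave``); in the
  backtracking-limited regime (``k_cleave >> k_bt``) the cleaved fraction
  relaxes as a near single exponential with rate ``k_bt``.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

__all__ = [
    "SchemeError",
    "Transition",
    "KineticScheme",
    "RateParameterSet",
    "ObservableMap",
    "build_three_step_scheme",
    "build_bimolecular_binding_scheme",
    "build_backtrack_cleavage_scheme",
    "validate_scheme",
    "scheme_by_name",
    "SCHEME_REGISTRY",
]

_SUM_TOL = 1e-12


class SchemeError(ValueError):
    """A kinetic scheme, parameter set or observable violates its contract."""


@dataclass(frozen=True)
class Transition:
    """One mass-action transition ``source -> target`` at rate ``rate``.

    If ``species`` is set, the unimolecular rate constant is multiplied by
    the free molar concentration of that species at each instant (the rate
    parameter is then a bimolecular constant in M^-1 s^-1).
    """

    source: str
    target: str
    rate: str
    species: str | None = None

    def to_dict(self) -> dict:
        d = {"source": self.source, "target": self.target, "rate": self.rate}
        if self.species is not None:
            d["species"] = self.species
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Transition":
        return cls(d["source"], d["target"], d["rate"], d.get("species"))


@dataclass(frozen=True)
class KineticScheme:
    """Named states plus mass-action transitions.

    ``initial_distribution`` maps each state to either a float fraction or a
    parameter expression: the bare name of a parameter (e.g.
    ``"slow_fraction"``) or its complement (``"1 - slow_fraction"``), resolved
    against a :class:`RateParameterSet` at simulation time.

    ``species_stoichiometry`` maps a tracked species name to
    ``{state: molecules sequestered per receptor in that state}``; the ODE
    engine uses it to compute the free concentration under depletion.
    """

    name: str
    states: tuple[str, ...]
    transitions: tuple[Transition, ...]
    initial_distribution: dict[str, float | str]
    species_stoichiometry: dict[str, dict[str, float]] = field(default_factory=dict)

    # -- parameter bookkeeping -------------------------------------------------
    def rate_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for tr in self.transitions:
            if tr.rate not in seen:
                seen.append(tr.rate)
        return tuple(seen)

    def initial_parameter_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for expr in self.initial_distribution.values():
            if isinstance(expr, str):
                name = _parse_initial_expr(expr)[1]
                if name not in names:
                    names.append(name)
        return tuple(names)

    def species_names(self) -> tuple[str, ...]:
        names = [tr.species for tr in self.transitions if tr.species is not None]
        for sp in self.species_stoichiometry:
            if sp not in names:
                names.append(sp)
        return tuple(dict.fromkeys(names))

    def initial_fractions(self, params: "RateParameterSet | None" = None) -> list[float]:
        """Resolve the initial distribution to one fraction per state."""
        out = []
        for st in self.states:
            expr = self.initial_distribution.get(st, 0.0)
            if isinstance(expr, str):
                if params is None:
                    raise SchemeError(
                        f"initial fraction of state {st!r} needs parameter {expr!r}"
                    )
                sign, name = _parse_initial_expr(expr)
                value = params.get(name)
                out.append(1.0 - value if sign else value)
            else:
                out.append(float(expr))
        return out

    # -- serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "states": list(self.states),
            "transitions": [tr.to_dict() for tr in self.transitions],
            "initial_distribution": dict(self.initial_distribution),
            "species_stoichiometry": {
                sp: dict(m) for sp, m in self.species_stoichiometry.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticScheme":
        return cls(
            name=d["name"],
            states=tuple(d["states"]),
            transitions=tuple(Transition.from_dict(t) for t in d["transitions"]),
            initial_distribution=dict(d["initial_distribution"]),
            species_stoichiometry={
                sp: dict(m) for sp, m in d.get("species_stoichiometry", {}).items()
            },
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "KineticScheme":
        return cls.from_dict(json.loads(text))


def _parse_initial_expr(expr: str) -> tuple[bool, str]:
    """Parse ``"p"`` or ``"1 - p"``; return (complement?, parameter name)."""
    s = expr.strip()
    if s.startswith("1"):
        rest = s[1:].strip()
        if not rest.startswith("-"):
            raise SchemeError(f"cannot parse initial-fraction expression {expr!r}")
        return True, rest[1:].strip()
    return False, s


@dataclass
class RateParameterSet:
    """Values for a scheme's rate parameters.

    Unimolecular rates are in s^-1, bimolecular (species-multiplied) rates in
    M^-1 s^-1.  ``slow_fraction`` is the dimensionless initial inactive
    fraction used by the three-step scheme.
    """

    rates: dict[str, float]
    slow_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name, v in self.rates.items():
            if not math.isfinite(v) or v < 0:
                raise SchemeError(f"rate {name!r} must be finite and >= 0, got {v}")
        if not 0.0 <= self.slow_fraction <= 1.0:
            raise SchemeError(
                f"slow_fraction must lie in [0, 1], got {self.slow_fraction}"
            )

    def get(self, name: str) -> float:
        if name == "slow_fraction":
            return self.slow_fraction
        try:
            return self.rates[name]
        except KeyError:
            raise SchemeError(f"missing rate parameter {name!r}") from None

    def __getitem__(self, name: str) -> float:
        return self.get(name)

    def __contains__(self, name: str) -> bool:
        return name == "slow_fraction" or name in self.rates

    def updated(self, **changes: float) -> "RateParameterSet":
        rates = dict(self.rates)
        slow = self.slow_fraction
        for name, v in changes.items():
            if name == "slow_fraction":
                slow = v
            else:
                rates[name] = v
        return RateParameterSet(rates, slow)

    def to_dict(self) -> dict:
        return {"rates": dict(self.rates), "slow_fraction": self.slow_fraction}

    @classmethod
    def from_dict(cls, d: dict) -> "RateParameterSet":
        return cls(dict(d["rates"]), float(d.get("slow_fraction", 0.0)))


@dataclass(frozen=True)
class ObservableMap:
    """Projection from state fractions onto an experimental read-out.

    ``state_sum`` sums the fractions of ``product_states`` (gel product
    fraction).  ``fluorescence`` returns ``offset + scale * sum(coeff_s *
    fraction_s)``; the direction of a signal change (6-MI decrease vs 2-AP
    increase) is carried by the sign of the coefficients, ``scale`` stays
    strictly positive.
    """

    kind: str  # "state_sum" | "fluorescence"
    product_states: frozenset[str] = frozenset()
    coefficients: dict[str, float] = field(default_factory=dict)
    scale: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("state_sum", "fluorescence"):
            raise SchemeError(f"unknown observable kind {self.kind!r}")
        if self.kind == "fluorescence" and self.scale <= 0:
            raise SchemeError("fluorescence scale must be strictly positive")

    def referenced_states(self) -> frozenset[str]:
        if self.kind == "state_sum":
            return self.product_states
        return frozenset(self.coefficients)


# ---------------------------------------------------------------------------
# Scheme constructors
# ---------------------------------------------------------------------------

def build_three_step_scheme() -> KineticScheme:
    """Nucleotide addition / translocation scheme with a slow inactive fraction.

    TEC16_inactive <-> TEC16_active (k_rec / k_inact), then the irreversible
    nucleotide addition TEC16_active -> TEC17_pre (k_add) and irreversible
    forward translocation TEC17_pre -> TEC17_post (k_tr).  The initial mass
    splits between the inactive state (``slow_fraction``) and the active one.
    NTP dependence is folded into the pseudo-first-order k_add because the
    assays use saturating substrate (200 uM after mixing).
    """
    return KineticScheme(
        name="three_step",
        states=("TEC16_inactive", "TEC16_active", "TEC17_pre", "TEC17_post"),
        transitions=(
            Transition("TEC16_inactive", "TEC16_active", "k_rec"),
            Transition("TEC16_active", "TEC16_inactive", "k_inact"),
            Transition("TEC16_active", "TEC17_pre", "k_add"),
            Transition("TEC17_pre", "TEC17_post", "k_tr"),
        ),
        initial_distribution={
            "TEC16_inactive": "slow_fraction",
            "TEC16_active": "1 - slow_fraction",
            "TEC17_pre": 0.0,
            "TEC17_post": 0.0,
        },
    )


def build_bimolecular_binding_scheme(ligand: str = "NusG") -> KineticScheme:
    """One-step reversible ligand binding with explicit ligand depletion.

    TEC_free -> TEC_bound at ``k_on`` times the free ligand molarity
    (total minus receptor-bound), TEC_bound -> TEC_free at ``k_off``.
    Depletion is mandatory: the lowest post-mix ligand concentration in the
    study design (0.1 uM) is comparable to the 0.2 uM receptor.
    """
    return KineticScheme(
        name="bimolecular_binding",
        states=("TEC_free", "TEC_bound"),
        transitions=(
            Transition("TEC_free", "TEC_bound", "k_on", species=ligand),
            Transition("TEC_bound", "TEC_free", "k_off"),
        ),
        initial_distribution={"TEC_free": 1.0, "TEC_bound": 0.0},
        species_stoichiometry={ligand: {"TEC_bound": 1.0}},
    )


def build_backtrack_cleavage_scheme() -> KineticScheme:
    """Backtracking captured by cleavage: TEC_pre <-> TEC_backtracked -> TEC_cleaved.

    ``k_bt`` enters the backtracked state, ``k_fwd`` returns (no value is
    asserted for it here; it is exposed and defaults to zero in generators),
    ``k_cleave`` irreversibly cleaves.  With ``k_cleave >> k_bt`` the cleaved
    fraction is backtracking-limited and nearly single-exponential in k_bt.
    Cleavage-factor concentration is not a species: inhibition in the study
    system is independent of it, so cleavage enters as an effective
    unimolecular rate.
    """
    return KineticScheme(
        name="backtrack_cleavage",
        states=("TEC_pre", "TEC_backtracked", "TEC_cleaved"),
        transitions=(
            Transition("TEC_pre", "TEC_backtracked", "k_bt"),
            Transition("TEC_backtracked", "TEC_pre", "k_fwd"),
            Transition("TEC_backtracked", "TEC_cleaved", "k_cleave"),
        ),
        initial_distribution={
            "TEC_pre": 1.0,
            "TEC_backtracked": 0.0,
            "TEC_cleaved": 0.0,
        },
    )


SCHEME_REGISTRY = {
    "three_step": build_three_step_scheme,
    "bimolecular_binding": build_bimolecular_binding_scheme,
    "backtrack_cleavage": build_backtrack_cleavage_scheme,
}


def scheme_by_name(name: str) -> KineticScheme:
    try:
        return SCHEME_REGISTRY[name]()
    except KeyError:
        raise SchemeError(
            f"unknown scheme {name!r}; known: {sorted(SCHEME_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_scheme(scheme: KineticScheme) -> list[str]:
    """Check the scheme invariants; return one finding per violation.

    An empty list means the scheme is well formed.  Findings name the state
    or transition at fault; no exception is raised.
    """
    findings: list[str] = []
    seen: set[str] = set()
    for st in scheme.states:
        if st in seen:
            findings.append(f"duplicate state name {st!r}")
        seen.add(st)

    for tr in scheme.transitions:
        for endpoint in (tr.source, tr.target):
            if endpoint not in seen:
                findings.append(
                    f"transition {tr.source!r}->{tr.target!r} references "
                    f"undeclared state {endpoint!r}"
                )

    for st in scheme.initial_distribution:
        if st not in seen:
            findings.append(f"initial distribution references undeclared state {st!r}")

    # Normalization: resolve parameterized entries at two arbitrary test values;
    # a valid parameterization (p paired with 1-p) sums to 1 for any value.
    try:
        for probe in (0.37, 0.61):
            names = scheme.initial_parameter_names()
            params = RateParameterSet(
                {n: probe for n in names if n != "slow_fraction"},
                slow_fraction=probe,
            )
            total = sum(scheme.initial_fractions(params))
            if abs(total - 1.0) > _SUM_TOL:
                findings.append(
                    f"initial fractions sum to {total!r}, not 1 (normalization)"
                )
                break
    except SchemeError as exc:
        findings.append(f"initial distribution is malformed: {exc}")

    for sp, stoich in scheme.species_stoichiometry.items():
        for st in stoich:
            if st not in seen:
                findings.append(
                    f"species {sp!r} stoichiometry references undeclared state {st!r}"
                )

    if scheme.transitions and not scheme.rate_names():
        findings.append("no rate parameter is referenced by any transition")
    return findings
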