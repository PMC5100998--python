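"""Integrator correctness: matrix-exponential oracle, conservation, projection."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from tecfit import (
    Conditions,
    KineticScheme,
    ObservableMap,
    RateParameterSet,
    SchemeError,
    Transition,
    build_bimolecular_binding_scheme,
    build_three_step_scheme,
    project,
    simulate,
)
from tecfit.ode_engine import ObservableError
from tecfit.synthetic_data import TABLE1_MINUS_NUSG


def rate_matrix(scheme, params):
    """Generator matrix A with dp/dt = A p — the oracle's own construction."""
    idx = {s: i for i, s in enumerate(scheme.states)}
    a = np.zeros((len(scheme.states),) * 2)
    for tr in scheme.transitions:
        k = params.get(tr.rate)
        i, j = idx[tr.source], idx[tr.target]
        a[j, i] += k
        a[i, i] -= k
    return a


def test_two_state_closed_form():
    s = KineticScheme(
        "ab", ("A", "B"), (Transition("A", "B", "k"),), {"A": 1.0, "B": 0.0}
    )
    traj = simulate(s, RateParameterSet({"k": 2.0}), np.array([0.34657]))
    assert traj.fraction("A")[0] == pytest.approx(0.500, abs=1e-4)


def test_zero_rates_keep_initial_distribution():
    s = build_three_step_scheme()
    p = RateParameterSet({k: 0.0 for k in s.rate_names()}, slow_fraction=0.3)
    traj = simulate(s, p, np.linspace(0.1, 5.0, 10))
    assert np.allclose(traj.state_fractions, traj.state_fractions[0], atol=1e-12)
    assert traj.fraction("TEC16_inactive")[0] == pytest.approx(0.3)


def test_three_step_matches_matrix_exponential_and_completes():
    s = build_three_step_scheme()
    times = np.geomspace(1e-3, 10.0, 25)
    traj = simulate(s, TABLE1_MINUS_NUSG, times)
    a = rate_matrix(s, TABLE1_MINUS_NUSG)
    p0 = np.array(s.initial_fractions(TABLE1_MINUS_NUSG))
    oracle = np.stack([expm(a * t) @ p0 for t in times])
    assert np.max(np.abs(traj.state_fractions - oracle)) < 1e-6
    product = traj.fraction("TEC17_pre") + traj.fraction("TEC17_post")
    assert product[-1] > 0.99  # slow-state drain completes within 10 s


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_random_unimolecular_schemes_match_matrix_exponential(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 5))
    states = tuple(f"S{i}" for i in range(n))
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    rng.shuffle(pairs)
    n_edges = int(rng.integers(1, len(pairs) + 1))
    transitions = tuple(
        Transition(states[i], states[j], f"k{m}") for m, (i, j) in enumerate(pairs[:n_edges])
    )
    p0 = rng.dirichlet(np.ones(n))
    scheme = KineticScheme(
        "rand", states, transitions, dict(zip(states, p0.tolist()))
    )
    params = RateParameterSet(
        {f"k{m}": float(10.0 ** rng.uniform(-2, 2)) for m in range(n_edges)}
    )
    times = np.array([0.01, 0.1, 1.0])
    traj = simulate(scheme, params, times)
    a = rate_matrix(scheme, params)
    oracle = np.stack([expm(a * t) @ p0 for t in times])
    assert np.max(np.abs(traj.state_fractions - oracle)) < 1e-6
    assert np.max(np.abs(traj.state_fractions.sum(axis=1) - 1.0)) < 1e-8
    assert traj.state_fractions.min() >= 0.0


def test_ligand_conservation_under_depletion():
    s = build_bimolecular_binding_scheme()
    params = RateParameterSet({"k_on": 9.2e6, "k_off": 1.1})
    r_tot, l_tot = 2e-7, 1e-7
    cond = Conditions(receptor_total=r_tot, species_totals={"NusG": l_tot})
    traj = simulate(s, params, np.linspace(0.001, 3.0, 100), cond)
    bound_ligand = r_tot * traj.fraction("TEC_bound")
    assert np.max(np.abs(traj.species_free["NusG"] + bound_ligand - l_tot)) < 1e-8
    assert np.max(np.abs(traj.state_fractions.sum(axis=1) - 1.0)) < 1e-8


def test_simulate_errors_are_named():
    s = build_three_step_scheme()
    with pytest.raises(SchemeError, match="k_tr"):
        simulate(
            s,
            RateParameterSet({"k_add": 1.0, "k_rec": 1.0, "k_inact": 1.0}),
            np.array([1.0]),
        )
    with pytest.raises(ValueError, match="strictly increasing"):
        simulate(s, TABLE1_MINUS_NUSG, np.array([1.0, 0.5]))
    b = build_bimolecular_binding_scheme()
    with pytest.raises(SchemeError, match="NusG"):
        simulate(b, RateParameterSet({"k_on": 1e6, "k_off": 1.0}), np.array([1.0]))


def test_project_state_sum_and_degenerate_fluorescence():
    s = build_three_step_scheme()
    traj = simulate(s, TABLE1_MINUS_NUSG, np.geomspace(1e-3, 5.0, 20))
    everything = ObservableMap(kind="state_sum", product_states=frozenset(s.states))
    assert np.allclose(project(traj, everything), 1.0, atol=1e-10)
    flat = ObservableMap(
        kind="fluorescence",
        coefficients={st_: 0.7 for st_ in s.states},
        scale=2.0,
        offset=0.5,
    )
    assert np.allclose(project(traj, flat), 0.5 + 2.0 * 0.7, atol=1e-9)
    with pytest.raises(ObservableError, match="nope"):
        project(traj, ObservableMap(kind="state_sum", product_states=frozenset({"nope"})))


def test_product_plateau_reflects_slow_fraction():
    # before the slow states recover, the product amplitude is 1 - slow_fraction
    s = build_three_step_scheme()
    params = RateParameterSet(
        {"k_add": 28.0, "k_tr": 65.0, "k_rec": 0.01, "k_inact": 0.0}, slow_fraction=0.2
    )
    traj = simulate(s, params, np.array([0.5]))  # fast phase done, recovery not started
    product = traj.fraction("TEC17_pre") + traj.fraction("TEC17_post")
    assert product[0] == pytest.approx(0.8, abs=0.01)


def test_trajectory_tidy_export():
    s = build_three_step_scheme()
    traj = simulate(s, TABLE1_MINUS_NUSG, np.array([0.1, 1.0]))
    frame = traj.to_frame()
    assert list(frame.columns) == ["time_s", "state", "fraction"]
    assert len(frame) == 2 * 4
    total = frame.groupby("time_s")["fraction"].sum()
    assert np.allclose(total, 1.0, atol=1e-8)
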