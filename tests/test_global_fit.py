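"""Joint chi2, global fitting, profile bounds, binding-series kinetics."""
import numpy as np
import pytest

from tecfit import (
    Conditions,
    Dataset,
    KineticScheme,
    Observation,
    ObservableMap,
    RateParameterSet,
    Trace,
    Transition,
    chi_squared,
    fit_binding_series,
    fit_global,
    fit_stretched_exponential,
    profile_bounds,
    profile_parameter,
    simulate,
)
from tecfit.global_fit import DatasetError, GlobalFitError
from tecfit.schemes import build_three_step_scheme
from tecfit.synthetic_data import (
    TABLE1_MINUS_NUSG,
    GeneratorSpec,
    generate_binding_series,
)
from conftest import GENERIC_INITIAL, THREE_STEP_FREE, make_three_step_dataset

AB = KineticScheme("ab", ("A", "B"), (Transition("A", "B", "k"),), {"A": 1.0, "B": 0.0})
SUM_ALL = ObservableMap(kind="state_sum", product_states=frozenset({"A", "B"}))


def _point_obs(value, sigma=1.0):
    # the all-states sum predicts exactly 1.0, so the residual is 1 - value
    return Observation(Trace(np.array([1.0]), np.array([value])), SUM_ALL, sigma=sigma)


def test_chi_squared_definition_and_homogeneity():
    params = RateParameterSet({"k": 1.0})
    ds = Dataset((_point_obs(-1.0),))  # residual 2, variance 1
    assert chi_squared(params, ds, AB) == pytest.approx(4.0)
    ds2 = Dataset((_point_obs(-3.0),))  # doubled residual
    assert chi_squared(params, ds2, AB) == pytest.approx(16.0)
    perfect = Dataset((_point_obs(1.0),))
    assert chi_squared(params, perfect, AB) < 1e-12
    with pytest.raises(DatasetError, match="variance"):
        chi_squared(params, Dataset((_point_obs(1.0, sigma=0.0),)), AB)


def test_noiseless_fit_is_a_fixed_point():
    scheme = build_three_step_scheme()
    times = np.geomspace(0.004, 10.0, 12)
    traj = simulate(scheme, TABLE1_MINUS_NUSG, times)
    obs_map = ObservableMap(
        kind="state_sum", product_states=frozenset({"TEC17_pre", "TEC17_post"})
    )
    product = traj.fraction("TEC17_pre") + traj.fraction("TEC17_post")
    ds = Dataset((Observation(Trace(times, product), obs_map, sigma=1.0),))
    res = fit_global(ds, scheme, TABLE1_MINUS_NUSG, THREE_STEP_FREE, reweight=False)
    assert res.converged
    assert res.chi2 < 1e-10
    for name in ("k_add", "k_tr"):
        assert res.params.get(name) == pytest.approx(TABLE1_MINUS_NUSG.get(name), rel=1e-4)
    # refitting from the optimum stays put
    res2 = fit_global(ds, scheme, res.params, THREE_STEP_FREE, reweight=False)
    assert res2.chi2 <= res.chi2 + 1e-10


def test_permutation_invariance(three_step_dataset):
    scheme = build_three_step_scheme()
    reversed_ds = Dataset(tuple(reversed(three_step_dataset.observations)))
    c1 = chi_squared(TABLE1_MINUS_NUSG, three_step_dataset, scheme)
    c2 = chi_squared(TABLE1_MINUS_NUSG, reversed_ds, scheme)
    assert c1 == pytest.approx(c2, rel=1e-12)
    r1 = fit_global(three_step_dataset, scheme, GENERIC_INITIAL, ("k_add", "k_tr"))
    r2 = fit_global(reversed_ds, scheme, GENERIC_INITIAL, ("k_add", "k_tr"))
    assert r1.params.get("k_add") == pytest.approx(r2.params.get("k_add"), rel=1e-6)


def test_three_step_recovery_from_generic_start(three_step_dataset):
    scheme = build_three_step_scheme()
    res = fit_global(three_step_dataset, scheme, GENERIC_INITIAL, THREE_STEP_FREE)
    assert res.converged
    assert 27.0 <= res.params.get("k_add") <= 30.0
    assert 60.0 <= res.params.get("k_tr") <= 73.0
    assert res.params.slow_fraction == pytest.approx(0.08, abs=0.02)


def test_parameter_recovery_medians_lie_in_published_intervals():
    """Medians over 20 replicate experiments fall inside the reported
    lower/upper intervals for every rate of the three-step mechanism.

    The initial inactive fraction is tied to the k_inact/k_rec
    pre-equilibrium here (the assembled complexes interconvert slowly before
    mixing), which is what makes the tiny inactivation rate identifiable
    from the slow-phase amplitude."""
    scheme = build_three_step_scheme()
    free = ("k_add", "k_tr", "k_rec", "k_inact")
    estimates = {name: [] for name in THREE_STEP_FREE}
    for i in range(20):
        ds = make_three_step_dataset(seed=3000 + i)
        res = fit_global(
            ds, scheme, GENERIC_INITIAL, free, derive_slow_fraction=True
        )
        for name in free:
            estimates[name].append(res.params.get(name))
        estimates["slow_fraction"].append(res.params.slow_fraction)
    med = {name: float(np.median(v)) for name, v in estimates.items()}
    assert 27.0 <= med["k_add"] <= 30.0
    assert 60.0 <= med["k_tr"] <= 73.0
    assert 0.4 <= med["k_rec"] <= 2.7
    assert 0.03 <= med["k_inact"] <= 0.3
    assert med["slow_fraction"] == pytest.approx(0.08, abs=0.02)


def test_profile_bounds_match_linear_chi2_parabola():
    """For y = a t with known noise the profile chi2 is an exact parabola:
    the 10%-increase endpoints are a_hat +/- sqrt(0.1 chi2_min / sum(t^2/s^2))."""
    rng = np.random.default_rng(7)
    t = np.linspace(0.1, 5.0, 40)
    sigma = 0.2
    a_true = 1.7
    y = a_true * t + rng.normal(0, sigma, t.size)

    def residual(x):
        return (x[0] * t - y) / sigma

    a_hat = float(np.sum(t * y) / np.sum(t * t))
    chi2_min = float(np.sum(((a_hat * t - y) / sigma) ** 2))
    threshold = 1.1 * chi2_min
    half_width = np.sqrt(0.1 * chi2_min / np.sum(t * t / sigma**2))

    pb = profile_parameter(
        residual, np.array([a_hat]), 0, threshold, step=0.01, span=5.0, rel_tol=0.002
    )
    assert pb.lower == pytest.approx(a_hat - half_width, rel=0.02)
    assert pb.upper == pytest.approx(a_hat + half_width, rel=0.02)
    assert not pb.lower_unbounded and not pb.upper_unbounded
    # endpoint chi2 sits on the threshold
    for endpoint in (pb.lower, pb.upper):
        c = float(np.sum(residual(np.array([endpoint])) ** 2))
        assert c == pytest.approx(threshold, rel=0.01)


def test_zero_sensitivity_parameter_is_flagged_unbounded():
    # state C starts empty, so its exit rate has no effect on the observable
    scheme = KineticScheme(
        "dead-branch",
        ("A", "B", "C"),
        (Transition("A", "B", "k1"), Transition("C", "B", "k2")),
        {"A": 1.0, "B": 0.0, "C": 0.0},
    )
    times = np.linspace(0.05, 3.0, 30)
    traj = simulate(scheme, RateParameterSet({"k1": 1.5, "k2": 1.0}), times)
    y = traj.fraction("B") + np.random.default_rng(0).normal(0, 0.01, times.size)
    obs = Observation(
        Trace(times, y),
        ObservableMap(kind="state_sum", product_states=frozenset({"B"})),
        sigma=0.01,
    )
    ds = Dataset((obs,))
    res = fit_global(ds, scheme, RateParameterSet({"k1": 1.0, "k2": 1.0}), ("k1", "k2"))
    assert "k2" in res.insensitive
    pb = profile_bounds(res, ds, scheme)
    assert pb["k2"].lower_unbounded and pb["k2"].upper_unbounded
    assert not pb["k1"].lower_unbounded and not pb["k1"].upper_unbounded
    assert pb["k1"].lower <= res.params.get("k1") <= pb["k1"].upper


def test_profile_requires_convergence(three_step_dataset):
    scheme = build_three_step_scheme()
    res = fit_global(three_step_dataset, scheme, GENERIC_INITIAL, ("k_add",))
    res.converged = False
    with pytest.raises(GlobalFitError):
        profile_bounds(res, three_step_dataset, scheme)


# ---------------------------------------------------------------------------
# Binding kinetics
# ---------------------------------------------------------------------------

BINDING_TRUTH = RateParameterSet({"k_on": 9.2e6, "k_off": 1.1})


def _binding_traces(seed=5, syringe=(0.2, 0.4, 1, 2, 4, 10, 20)):
    spec = GeneratorSpec(
        scheme="bimolecular_binding",
        params=BINDING_TRUTH,
        assay="binding_series",
        seed=seed,
        noise=0.01,
        n_points=200,
    )
    return generate_binding_series(spec, [c * 1e-6 for c in syringe])


def test_binding_series_recovers_rate_constants_within_10_percent():
    res = fit_binding_series(_binding_traces())
    assert res.converged
    assert res.params.get("k_on") == pytest.approx(9.2e6, rel=0.10)
    assert res.params.get("k_off") == pytest.approx(1.1, rel=0.10)
    assert res.derived["Kd_M"] == pytest.approx(0.12e-6, rel=0.15)


def test_binding_series_needs_multiple_concentrations():
    traces = _binding_traces(syringe=(2.0,))
    with pytest.raises(DatasetError, match="separable|distinct"):
        fit_binding_series(traces)


def test_high_ligand_relaxation_approaches_pseudo_first_order_rate():
    # at 10 uM post-mix ligand, k_obs ~ k_on*L + k_off = 93.1 s^-1
    spec = GeneratorSpec(
        scheme="bimolecular_binding",
        params=BINDING_TRUTH,
        assay="binding_series",
        seed=0,
        noise=0.0,
        n_points=300,
    )
    (trace,) = generate_binding_series(spec, [20e-6])
    fit = fit_stretched_exponential(trace)
    k_obs = 1.0 / fit.tau  # beta ~ 1 for this relaxation
    assert fit.beta == pytest.approx(1.0, abs=0.02)
    assert k_obs == pytest.approx(93.1, rel=0.05)
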