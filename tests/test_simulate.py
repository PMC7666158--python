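"""Pre-equilibration, protocol simulation and observable derivation."""

import numpy as np
import pytest

from phosphoswitch import (
    ModelParameters,
    Protocol,
    ReactionNetwork,
    compute_observables,
)
from phosphoswitch.simulate import Trajectory, pre_equilibrate, run_protocol
from phosphoswitch.species import ATF2_FREE, ATF2_JNK, ComplexSpecies

ZERO_MOD = {n: 0.0 for n in ("k1", "k2", "k3", "k4", "k_eq6", "k_eq7",
                             "dp1", "dp2", "dp3", "dp4")}


def binding_only_params(kon=1.0, koff=1.0):
    """One JNK-ATF2 binding pair; every modification rate off."""
    return ModelParameters().updated(
        kon1=kon, koff1=koff, kon2=0.0, koff2=0.0, kon3=0.0, koff3=0.0,
        **ZERO_MOD,
    )


def test_binding_equilibrium_matches_quadratic_closed_form():
    """A + B <-> AB with A_tot = B_tot = 1 µM, K_D = 1 µM.

    Closed form: AB solves AB² − (A+B+K_D)·AB + A·B = 0,
    AB = (3 − √5)/2 ≈ 0.3820 µM.
    """
    params = binding_only_params(kon=1.0, koff=1.0)
    net = ReactionNetwork.build(params)
    steady = pre_equilibrate(net, params)
    bound = sum(
        steady[net.index[s]] for s in net.species if s.kind == ATF2_JNK
    )
    expected = (3.0 - np.sqrt(5.0)) / 2.0
    assert bound == pytest.approx(expected, rel=1e-6)


def test_two_state_mapk_equilibrium_closed_form():
    """Binding disabled, k_eq = 1e-4, dp = 1e-3: pp fraction = 1/11."""
    params = ModelParameters().updated(
        kon1=0.0, koff1=0.0, kon2=0.0, koff2=0.0, kon3=0.0, koff3=0.0,
        k1=0.0, k2=0.0, k3=0.0, k4=0.0, dp3=0.0, dp4=0.0,
        k_eq6=1e-4, k_eq7=1e-4, dp1=1e-3, dp2=1e-3,
    )
    net = ReactionNetwork.build(params)
    steady = pre_equilibrate(net, params)
    traj = Trajectory(np.array([0.0]), steady[None, :], net, params)
    for obs in ("pp_jnk_fraction", "pp_p38_fraction"):
        assert traj.observables[obs][0] == pytest.approx(1.0 / 11.0, rel=1e-6)


def test_zero_basal_rates_give_unphosphorylated_equilibrated_state():
    params = ModelParameters().updated(k_eq6=0.0, k_eq7=0.0)
    net = ReactionNetwork.build(params)
    steady = pre_equilibrate(net, params)
    traj = Trajectory(np.array([0.0]), steady[None, :], net, params)
    assert traj.observables["pp_jnk_fraction"][0] == pytest.approx(0.0, abs=1e-12)
    assert traj.observables["pp_p38_fraction"][0] == pytest.approx(0.0, abs=1e-12)
    assert traj.observables["pp_atf2_fraction"][0] == pytest.approx(0.0, abs=1e-12)
    # binding still equilibrates
    bound = sum(steady[net.index[s]] for s in net.species if s.kind == ATF2_JNK)
    assert bound > 0.05


def test_pre_equilibration_is_idempotent(wt_network, wt_params, wt_steady_state):
    again = pre_equilibrate(wt_network, wt_params)
    assert np.allclose(again, wt_steady_state, rtol=0, atol=1e-13)


def test_stimulation_at_basal_rates_stays_flat(wt_network, wt_params, wt_steady_state):
    traj = run_protocol(
        wt_network,
        wt_params,
        Protocol(sampling_times=(0.0, 1200.0, 2400.0),
                 overrides={"k6": wt_params.k_eq6, "k7": wt_params.k_eq7}),
        initial_state=wt_steady_state.copy(),
    )
    for series in traj.observables.values():
        assert np.all(np.abs(series - series[0]) < 1e-7)


def test_relaxation_matches_analytic_two_state_solution():
    """Binding disabled: pp-JNK(t) relaxes exponentially toward
    k_stim7/(k_stim7 + dp1) with rate (k_stim7 + dp1)."""
    params = ModelParameters().updated(
        kon1=0.0, koff1=0.0, kon2=0.0, koff2=0.0, kon3=0.0, koff3=0.0,
        k1=0.0, k2=0.0, k3=0.0, k4=0.0, dp3=0.0, dp4=0.0,
    )
    net = ReactionNetwork.build(params)
    steady = pre_equilibrate(net, params)
    times = (0.0, 120.0, 600.0, 1800.0, 2400.0)
    traj = run_protocol(net, params, Protocol(sampling_times=times),
                        initial_state=steady)
    ks, dp = params.k_stim7, params.dp1
    p0 = traj.observables["pp_jnk_fraction"][0]
    p_inf = ks / (ks + dp)
    expected = p_inf + (p0 - p_inf) * np.exp(-(ks + dp) * np.asarray(times))
    assert np.allclose(traj.observables["pp_jnk_fraction"], expected, atol=1e-6)


def test_conservation_along_trajectory(anisomycin_trajectory, wt_params):
    net = anisomycin_trajectory.network
    for row in anisomycin_trajectory.concentrations:
        totals = net.totals(row)
        assert abs(totals["atf2"] - wt_params.atf2_total) < 1e-6 * wt_params.atf2_total
        assert abs(totals["jnk"] - wt_params.jnk_total) < 1e-6 * wt_params.jnk_total
        assert abs(totals["p38"] - wt_params.p38_total) < 1e-6 * wt_params.p38_total


def test_observables_stay_in_range(anisomycin_trajectory, wt_params):
    obs = anisomycin_trajectory.observables
    for name in ("pp_jnk_fraction", "pp_p38_fraction", "pp_atf2_fraction",
                 "ps90_fraction"):
        assert np.all(obs[name] >= -1e-12)
        assert np.all(obs[name] <= 1.0 + 1e-12)
    assert np.all(obs["p38_atf2_complex_total"] >= -1e-12)
    assert np.all(
        obs["p38_atf2_complex_total"]
        <= min(wt_params.atf2_total, wt_params.p38_total) + 1e-12
    )


def test_observables_hand_sum():
    """0.3 µM pp-free + 0.2 µM pp-JNK-bound + 0.5 µM other → fraction 0.5."""
    params = ModelParameters()
    net = ReactionNetwork.build(params)
    state = np.zeros(net.n_species)
    state[net.index[ComplexSpecies(ATF2_FREE, "P", "P", "U")]] = 0.3
    state[net.index[ComplexSpecies(ATF2_JNK, "P", "P", "U", "pp")]] = 0.2
    state[net.index[ComplexSpecies(ATF2_FREE, "P", "U", "U")]] = 0.5
    traj = Trajectory(np.array([0.0]), state[None, :], net, params)
    assert traj.observables["pp_atf2_fraction"][0] == pytest.approx(0.5)


def test_fully_phosphorylated_free_atf2_fraction_is_one():
    params = ModelParameters()
    net = ReactionNetwork.build(params)
    state = np.zeros(net.n_species)
    state[net.index[ComplexSpecies(ATF2_FREE, "P", "P", "U")]] = params.atf2_total
    traj = Trajectory(np.array([0.0]), state[None, :], net, params)
    assert traj.observables["pp_atf2_fraction"][0] == pytest.approx(1.0)


def test_solver_tolerance_halving_leaves_observables_stable(
    wt_network, wt_params, wt_steady_state
):
    def run(rtol, atol):
        return run_protocol(
            wt_network, wt_params, Protocol(sampling_times=(2400.0,)),
            initial_state=wt_steady_state.copy(), rtol=rtol, atol=atol,
        ).observables

    a = run(1e-8, 1e-12)
    b = run(5e-9, 5e-13)
    for name in a:
        assert np.allclose(a[name], b[name], atol=1e-5)


def test_s90n_terminal_response_nondecreasing_in_stimulation():
    params = ModelParameters().with_variant("S90N")
    net = ReactionNetwork.build(params)
    steady = pre_equilibrate(net, params)

    def terminal(k6, k7):
        traj = run_protocol(
            net, params,
            Protocol(sampling_times=(2400.0,), overrides={"k6": k6, "k7": k7}),
            initial_state=steady.copy(),
        )
        return traj.observables["pp_atf2_fraction"][-1]

    k6_grid = [1e-5, 1e-4, 1e-3]
    k7_grid = [1e-5, 1e-4, 1e-3]
    vals6 = [terminal(k6, 2e-4) for k6 in k6_grid]
    vals7 = [terminal(2e-4, k7) for k7 in k7_grid]
    assert np.all(np.diff(vals6) > -1e-9)
    assert np.all(np.diff(vals7) > -1e-9)


def test_compute_observables_requires_matching_dimensions(wt_network):
    params = ModelParameters()
    bad = Trajectory.__new__(Trajectory)
    bad.times = np.array([0.0])
    bad.concentrations = np.zeros((1, 3))
    bad.network = wt_network
    bad.params = params
    with pytest.raises(ValueError):
        compute_observables(bad)
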