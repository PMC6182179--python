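"""Kinetics, reaction networks and default parameters."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import srnafb as sf
from srnafb.circuits import free_repressor, nominal_params, params_from_yaml, params_to_yaml
from srnafb.dynamics import simulate_timecourse, steady_state

from conftest import random_params

TOPOLOGIES = [sf.AUTOREPRESSOR, sf.SRNA_TUNED_AUTOREPRESSOR,
              sf.CLOSED_LOOP_CONSTITUTIVE, sf.CLOSED_LOOP_INDUCIBLE]


# ---------------------------------------------------------------------------
# Hill forms and inducer coupling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x, K, n, expected", [
    (7.0, 7.0, 3.0, 0.5),       # half-saturation at the threshold
    (0.0, 5.0, 2.0, 0.0),
    (30.0, 10.0, 2.0, 0.9),     # 9/(1+9)
])
def test_hill_activation_examples(x, K, n, expected):
    assert sf.hill_activation(x, K, n) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("x, K, n, expected", [
    (7.0, 7.0, 3.0, 0.5),
    (0.0, 5.0, 2.0, 1.0),
    (30.0, 10.0, 2.0, 0.1),
])
def test_hill_repression_examples(x, K, n, expected):
    assert sf.hill_repression(x, K, n) == pytest.approx(expected, rel=1e-12)


@given(x1=st.floats(0, 1e6), x2=st.floats(0, 1e6),
       K=st.floats(1e-3, 1e3), n=st.floats(1, 6))
def test_hill_monotone_and_bounded(x1, x2, K, n):
    lo, hi = sorted((x1, x2))
    act_lo, act_hi = sf.hill_activation(lo, K, n), sf.hill_activation(hi, K, n)
    rep_lo, rep_hi = sf.hill_repression(lo, K, n), sf.hill_repression(hi, K, n)
    assert 0.0 <= act_lo <= act_hi <= 1.0
    assert 1.0 >= rep_lo >= rep_hi >= 0.0


@pytest.mark.parametrize("bad", [-1.0, float("nan"), float("inf")])
def test_hill_rejects_invalid_argument(bad):
    with pytest.raises(ValueError):
        sf.hill_activation(bad, 1.0, 2.0)
    with pytest.raises(ValueError):
        sf.hill_repression(bad, 1.0, 2.0)


def test_free_repressor_sequestration():
    # no aTc: all repressor active; at theta1 with n1=1: half active
    assert free_repressor(50.0, 0.0, 10.0, 2.0) == 50.0
    assert free_repressor(50.0, 10.0, 10.0, 1.0) == pytest.approx(25.0)
    assert free_repressor(0.0, 3.0, 10.0, 2.0) == 0.0
    with pytest.raises(ValueError):
        free_repressor(-1.0, 0.0, 10.0, 2.0)


# ---------------------------------------------------------------------------
# ODE right-hand side
# ---------------------------------------------------------------------------

def test_rhs_empty_cell_autorepressor():
    # zero repressor: promoter fully active, so dm/dt = a0 + a1
    d = sf.rhs(sf.AUTOREPRESSOR, sf.CircuitState(), nominal_params(),
               sf.InducerInput())
    assert d[0] == pytest.approx(0.02 + 2.0, rel=1e-12)
    assert d[1] == 0.0


def test_rhs_rejects_negative_state():
    with pytest.raises(ValueError):
        sf.CircuitState(m=-1.0)
    with pytest.raises(ValueError):
        sf.CircuitTopology.from_name("NOT_A_CIRCUIT")


@pytest.mark.parametrize("topology", TOPOLOGIES)
def test_rhs_vanishes_at_steady_state(topology, cal_params):
    inputs = sf.InducerInput(u1=5.0, u2=1e-4, u3=0.3)
    st_ = steady_state(topology, cal_params, inputs)
    d = sf.rhs(topology, st_, cal_params, inputs)
    scale = max(1.0, float(np.max(np.abs(st_.as_array(topology)))))
    assert np.max(np.abs(d)) < 1e-9 * scale


def test_autorepressor_state_forbids_srna():
    with pytest.raises(ValueError):
        sf.CircuitState(m=1.0, p=1.0, s=2.0).as_array(sf.AUTOREPRESSOR)


# ---------------------------------------------------------------------------
# Reaction networks
# ---------------------------------------------------------------------------

def test_reaction_counts():
    pr = nominal_params()
    assert sf.build_reaction_network(sf.AUTOREPRESSOR, pr,
                                     sf.InducerInput()).n_reactions == 4
    assert sf.build_reaction_network(sf.SRNA_TUNED_AUTOREPRESSOR, pr,
                                     sf.InducerInput()).n_reactions == 8


def test_network_rejects_time_varying_inputs():
    with pytest.raises(ValueError):
        sf.build_reaction_network(sf.AUTOREPRESSOR, nominal_params(),
                                  sf.InducerInput(u1=lambda t: 1.0 + t))


@pytest.mark.parametrize("topology", TOPOLOGIES)
def test_network_mean_field_matches_rhs(topology):
    """Sum of stoichiometry x propensity at omega-scaled counts must equal
    the omega-scaled macroscopic derivatives (mass-action consistency)."""
    rng = np.random.default_rng(7)
    for trial in range(20):
        pr = random_params(rng)
        inputs = sf.InducerInput(u1=rng.uniform(0, 50),
                                 u2=10 ** rng.uniform(-5, -3),
                                 u3=rng.uniform(0, 1))
        net = sf.build_reaction_network(topology, pr, inputs)
        x = rng.uniform(0, 100, size=topology.n_states)
        state = sf.CircuitState.from_array(x, topology)
        expected = sf.rhs(topology, state, pr, inputs)
        got = net.stoichiometry.T @ net.propensity(pr.omega * x) / pr.omega
        np.testing.assert_allclose(got, expected, atol=1e-10, rtol=0)


@given(y=st.lists(st.floats(0, 1e4), min_size=4, max_size=4))
def test_propensities_nonnegative(y):
    net = sf.build_reaction_network(sf.SRNA_TUNED_AUTOREPRESSOR,
                                    nominal_params(),
                                    sf.InducerInput(u1=3.0, u2=1e-4))
    assert np.all(net.propensity(np.array(y)) >= 0)


# ---------------------------------------------------------------------------
# Defaults, invariants, serialization
# ---------------------------------------------------------------------------

def test_default_params_pure_and_valid():
    a = sf.default_params(sf.SRNA_TUNED_AUTOREPRESSOR)
    b = sf.default_params(sf.SRNA_TUNED_AUTOREPRESSOR)
    assert a == b
    assert a.b1 > a.a1  # strong silencing needs sRNA production > mRNA production


def test_default_params_give_92_percent_knockdown(cal_params):
    tuned = sf.SRNA_TUNED_AUTOREPRESSOR
    p0 = steady_state(tuned, cal_params, sf.InducerInput(u1=0, u2=0)).p
    ps = steady_state(tuned, cal_params, sf.InducerInput(u1=0, u2=1e-3)).p
    assert 100 * (1 - ps / p0) == pytest.approx(92.0, abs=0.01)


@pytest.mark.parametrize("bad_kwargs", [
    {"delta_p": 0.0}, {"omega": 0.0}, {"n_R": 0.5}, {"a1": -1.0},
    {"K_R": 0.0}, {"kappa": float("nan")},
])
def test_params_invariants_enforced(bad_kwargs):
    with pytest.raises(ValueError):
        sf.CircuitParams(**bad_kwargs)


def test_params_yaml_round_trip(tmp_path, cal_params):
    path = tmp_path / "params.yaml"
    params_to_yaml(cal_params, str(path))
    assert params_from_yaml(str(path)) == cal_params


def test_copy_number_scaling_scales_all_transcription():
    pr = nominal_params().scaled({"copy_number": 2.0, "kappa": 0.5})
    assert pr.a0 == pytest.approx(0.04)
    assert pr.a1 == pytest.approx(4.0)
    assert pr.b1 == pytest.approx(30.0)
    assert pr.kappa == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# Dynamic invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("topology", TOPOLOGIES)
def test_trajectories_stay_nonnegative(topology):
    rng = np.random.default_rng(21)
    for trial in range(3):
        pr = random_params(rng)
        inputs = sf.InducerInput(u1=rng.uniform(0, 50),
                                 u2=10 ** rng.uniform(-5, -3),
                                 u3=rng.uniform(0, 1))
        state0 = sf.CircuitState.from_array(
            rng.uniform(0, 50, topology.n_states), topology)
        traj = simulate_timecourse(topology, pr, inputs, state0=state0,
                                   t_end=200.0)
        assert np.all(traj.states >= 0)


def test_linear_limit_steady_state_closed_form(linear_params):
    """With repression disabled and no sRNA binding the fixed point is
    m* = (a0+a1)/delta_m, p* = kappa m*/delta_p exactly."""
    pr = linear_params
    st_ = steady_state(sf.AUTOREPRESSOR, pr, sf.InducerInput())
    m_star = (pr.a0 + pr.a1) / pr.delta_m
    assert st_.m == pytest.approx(m_star, rel=1e-6)
    assert st_.p == pytest.approx(pr.kappa * m_star / pr.delta_p, rel=1e-6)


def test_monotone_statics_on_grids(cal_params, closed_params):
    """Steady-state output: non-increasing in u2 (sRNA), non-decreasing in
    u1 (aTc) and u3 (output inducer)."""
    tuned = sf.SRNA_TUNED_AUTOREPRESSOR
    p_u2 = [steady_state(tuned, cal_params, sf.InducerInput(u1=20, u2=v)).p
            for v in [0, 1e-5, 1e-4, 1e-3]]
    assert all(a >= b - 1e-9 for a, b in zip(p_u2, p_u2[1:]))
    p_u1 = [steady_state(sf.AUTOREPRESSOR, cal_params, sf.InducerInput(u1=v)).p
            for v in [0, 5, 20, 100]]
    assert all(a <= b + 1e-9 for a, b in zip(p_u1, p_u1[1:]))
    cl = sf.CLOSED_LOOP_INDUCIBLE
    p_u3 = [steady_state(cl, closed_params, sf.InducerInput(u2=2.0, u3=v)).p
            for v in [0.05, 0.25, 0.5, 1.0]]
    assert all(a <= b + 1e-9 for a, b in zip(p_u3, p_u3[1:]))
    p_cl_u2 = [steady_state(cl, closed_params, sf.InducerInput(u2=v, u3=0.5)).p
               for v in [0, 1e-4, 2.0]]
    assert all(a >= b - 1e-9 for a, b in zip(p_cl_u2, p_cl_u2[1:]))
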