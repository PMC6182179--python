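"""Time courses, steady states, response times, disturbance rejection."""

import math

import numpy as np
import pytest

import srnafb as sf
from srnafb.circuits import nominal_params
from srnafb.dynamics import (
    SteadyStateError,
    Trajectory,
    disturbance_response,
    dose_response,
    log_sensitivity,
    response_time_t90,
    simulate_timecourse,
    square_wave,
    steady_state,
    steady_state_protein_batch,
)


def test_linear_mrna_rise_matches_closed_form(linear_params):
    """Decoupled linear mRNA: m(t) = (a0+a1)/dm (1 - exp(-dm t))."""
    pr = linear_params
    traj = simulate_timecourse(sf.AUTOREPRESSOR, pr, sf.InducerInput(),
                               t_end=30.0, reltol=1e-10, abstol=1e-12)
    m_inf = (pr.a0 + pr.a1) / pr.delta_m
    expected = m_inf * (1.0 - np.exp(-pr.delta_m * traj.times))
    np.testing.assert_allclose(traj.observable("m")[1:], expected[1:],
                               rtol=1e-6)


def test_zero_production_stays_at_zero(cal_params):
    pr = cal_params.with_updates(a0=0.0, a1=0.0, b0=0.0, b1=0.0)
    traj = simulate_timecourse(sf.SRNA_TUNED_AUTOREPRESSOR, pr,
                               sf.InducerInput(u2=1e-3), t_end=100.0)
    assert np.all(traj.states == 0.0)


def test_long_integration_converges_to_steady_state(cal_params):
    inputs = sf.InducerInput(u1=10.0, u2=1e-4)
    traj = simulate_timecourse(sf.SRNA_TUNED_AUTOREPRESSOR, cal_params, inputs,
                               t_end=50.0 / cal_params.delta_p)
    st = steady_state(sf.SRNA_TUNED_AUTOREPRESSOR, cal_params, inputs)
    assert traj.observable("p")[-1] == pytest.approx(st.p, rel=1e-3)


def test_independent_integrators_agree(cal_params):
    """LSODA result cross-checked against Radau at halved tolerance."""
    from scipy.integrate import solve_ivp

    from srnafb.circuits import _rhs_array

    inputs = sf.InducerInput(u1=10.0, u2=1e-4)
    topo = sf.SRNA_TUNED_AUTOREPRESSOR
    reltol = 1e-7
    traj = simulate_timecourse(topo, cal_params, inputs, t_end=500.0,
                               reltol=reltol, abstol=1e-9)
    ref = solve_ivp(lambda t, y: _rhs_array(topo, y, cal_params,
                                            inputs.constants()),
                    (0.0, 500.0), np.zeros(4), method="Radau",
                    rtol=reltol / 2, atol=5e-10)
    np.testing.assert_allclose(traj.states[-1], np.clip(ref.y[:, -1], 0, None),
                               rtol=10 * reltol, atol=1e-8)


def test_timecourse_input_validation(cal_params):
    with pytest.raises(ValueError):
        simulate_timecourse(sf.AUTOREPRESSOR, cal_params, sf.InducerInput(),
                            t_end=-1.0)
    with pytest.raises(ValueError):
        simulate_timecourse(sf.AUTOREPRESSOR, cal_params, sf.InducerInput(),
                            t_end=10.0, reltol=0.5)


def test_steady_state_matches_brute_force_integration(cal_params):
    """Independent oracle: very long, very tight integration from zero."""
    inputs = sf.InducerInput(u1=0.0, u2=1e-3)  # saturating sRNA induction
    st = steady_state(sf.SRNA_TUNED_AUTOREPRESSOR, cal_params, inputs)
    traj = simulate_timecourse(sf.SRNA_TUNED_AUTOREPRESSOR, cal_params, inputs,
                               t_end=100.0 / cal_params.delta_p,
                               reltol=1e-11, abstol=1e-13)
    np.testing.assert_allclose(st.as_array(sf.SRNA_TUNED_AUTOREPRESSOR),
                               traj.states[-1], rtol=1e-6)


def test_steady_state_zero_production():
    pr = nominal_params().with_updates(a0=0.0, a1=0.0, b0=0.0, b1=0.0)
    st = steady_state(sf.SRNA_TUNED_AUTOREPRESSOR, pr, sf.InducerInput())
    assert st.m == st.p == st.s == st.c == 0.0


def test_batch_solver_agrees_with_scalar_solver(cal_params):
    rng = np.random.default_rng(3)
    inputs = sf.InducerInput(u1=15.0, u2=1e-4)
    scales = {"kappa": rng.lognormal(0, 0.25, 8),
              "copy_number": rng.lognormal(0, 0.25, 8)}
    batch = steady_state_protein_batch(sf.SRNA_TUNED_AUTOREPRESSOR,
                                       cal_params, inputs, scales)
    for i in range(8):
        pr = cal_params.scaled({"kappa": scales["kappa"][i],
                                "copy_number": scales["copy_number"][i]})
        st = steady_state(sf.SRNA_TUNED_AUTOREPRESSOR, pr, inputs)
        assert batch[i] == pytest.approx(st.p, rel=1e-9)


# ---------------------------------------------------------------------------
# Dose response
# ---------------------------------------------------------------------------

def test_single_point_grid_reduces_to_steady_state(cal_params):
    surf = dose_response(sf.AUTOREPRESSOR, cal_params, ("u1", [5.0]))
    st = steady_state(sf.AUTOREPRESSOR, cal_params, sf.InducerInput(u1=5.0))
    assert surf.output[0, 0] == pytest.approx(st.p, rel=1e-12)


def test_autorepressor_dose_response_is_sigmoidal(cal_params):
    """Log-log slope of p*(u1) exceeds 1 somewhere: the steep switch-like
    response that motivates sRNA tuning."""
    u1 = np.logspace(0, 2, 15)
    surf = dose_response(sf.AUTOREPRESSOR, cal_params, ("u1", u1))
    slopes = np.diff(np.log(surf.output[:, 0])) / np.diff(np.log(u1))
    assert slopes.max() > 1.0


def test_srna_suppresses_output_at_every_atc_level(cal_params):
    u1 = [0.0, 5.0, 20.0, 100.0]
    surf = dose_response(sf.SRNA_TUNED_AUTOREPRESSOR, cal_params,
                         ("u1", u1), ("u2", [0.0, 1e-3]))
    assert np.all(surf.output[:, 1] < surf.output[:, 0])


def test_surface_csv_round_trip(tmp_path, cal_params):
    import pandas as pd

    surf = dose_response(sf.AUTOREPRESSOR, cal_params, ("u1", [0.0, 10.0]))
    path = tmp_path / "surface.csv"
    surf.to_csv(str(path))
    back = pd.read_csv(path)
    np.testing.assert_allclose(back["p_star"].to_numpy(), surf.output[:, 0],
                               rtol=1e-14)


# ---------------------------------------------------------------------------
# Response time
# ---------------------------------------------------------------------------

def test_t90_first_order_closed_form(cal_params):
    """p(t) = p*(1-exp(-d t)) crosses 90% at ln(10)/d; d = 0.02 -> 115.13."""
    delta = 0.02
    times = np.linspace(0.0, 2500.0, 25001)
    states = np.column_stack([np.zeros_like(times),
                              1000.0 * (1 - np.exp(-delta * times))])
    traj = Trajectory(times=times, states=states, topology=sf.AUTOREPRESSOR,
                      params=cal_params, inputs=sf.InducerInput())
    assert response_time_t90(traj) == pytest.approx(math.log(10) / delta,
                                                    rel=1e-4)
    assert response_time_t90(traj) == pytest.approx(115.13, abs=0.05)


def test_t90_error_cases(cal_params):
    times = np.linspace(0, 10, 300)
    flat = Trajectory(times=times, states=np.zeros((300, 2)),
                      topology=sf.AUTOREPRESSOR, params=cal_params,
                      inputs=sf.InducerInput())
    with pytest.raises(ValueError):
        response_time_t90(flat)
    high = Trajectory(times=times,
                      states=np.column_stack([np.zeros(300),
                                              np.full(300, 5.0)]),
                      topology=sf.AUTOREPRESSOR, params=cal_params,
                      inputs=sf.InducerInput())
    with pytest.raises(ValueError):
        response_time_t90(high)


def test_autorepressor_t90_increases_with_atc(cal_params):
    """Higher aTc weakens the feedback, so the response slows as the
    output rises -- the coupling the sRNA dial removes."""
    t90 = []
    for u1 in (5.0, 20.0, 80.0):
        traj = simulate_timecourse(sf.AUTOREPRESSOR, cal_params,
                                   sf.InducerInput(u1=u1),
                                   t_end=50.0 / cal_params.delta_p)
        t90.append(response_time_t90(traj))
    assert t90[0] < t90[1] < t90[2]


# ---------------------------------------------------------------------------
# Disturbance rejection
# ---------------------------------------------------------------------------

def test_constant_modulation_gives_zero_attenuation(closed_params):
    traj, att = disturbance_response(
        sf.CLOSED_LOOP_INDUCIBLE, closed_params,
        sf.InducerInput(u2=2.0, u3=0.5), "u3", modulation=lambda t: 1.0)
    p = traj.observable("p")
    assert att == 0.0
    assert np.ptp(p) / np.mean(p) < 1e-6


def test_nonpositive_modulation_rejected(closed_params):
    with pytest.raises(ValueError):
        disturbance_response(sf.CLOSED_LOOP_INDUCIBLE, closed_params,
                             sf.InducerInput(u2=2.0, u3=0.5), "u3",
                             modulation=lambda t: math.sin(t / 20.0))


def test_feedback_dampens_u3_disturbance(closed_params):
    """Closed-loop property: engaging the sRNA feedback (u2 > 0) reduces
    the transmitted amplitude of a u3 disturbance."""
    _, att_open = disturbance_response(sf.CLOSED_LOOP_INDUCIBLE,
                                       closed_params,
                                       sf.InducerInput(u2=0.0, u3=0.5), "u3")
    _, att_fb = disturbance_response(sf.CLOSED_LOOP_INDUCIBLE, closed_params,
                                     sf.InducerInput(u2=2.0, u3=0.5), "u3")
    assert att_fb < att_open


def test_srna_dial_improves_disturbance_rejection_at_matched_output(cal_params):
    """At matched mean output, the sRNA-tuned circuit attenuates an aTc
    disturbance at least as well as aTc-tuning alone."""
    from scipy.optimize import brentq

    tuned = sf.SRNA_TUNED_AUTOREPRESSOR
    target = steady_state(tuned, cal_params,
                          sf.InducerInput(u1=100.0, u2=2e-5)).p
    u1_match = brentq(
        lambda u1: steady_state(sf.AUTOREPRESSOR, cal_params,
                                sf.InducerInput(u1=u1)).p - target, 0.1, 100.0)
    _, att_tuned = disturbance_response(tuned, cal_params,
                                        sf.InducerInput(u1=100.0, u2=2e-5),
                                        "u1")
    _, att_plain = disturbance_response(sf.AUTOREPRESSOR, cal_params,
                                        sf.InducerInput(u1=u1_match), "u1")
    assert att_tuned <= att_plain


def test_square_wave_validation():
    with pytest.raises(ValueError):
        square_wave(amplitude=1.5)
    wave = square_wave(period=100.0, amplitude=0.3)
    assert wave(10.0) == pytest.approx(1.3)
    assert wave(60.0) == pytest.approx(0.7)


# ---------------------------------------------------------------------------
# Log sensitivity
# ---------------------------------------------------------------------------

def test_sensitivity_linear_limit_is_unity(cal_params):
    """Negligible leak, G(u3) << theta3, n3 = 1: p* proportional to u3."""
    pr = cal_params.with_updates(a0=1e-6, K_R=1e12, k=0.0, b1=0.0, n3=1.0)
    s = log_sensitivity(sf.CLOSED_LOOP_INDUCIBLE, pr,
                        sf.InducerInput(u3=1e-3), "u3")
    assert s == pytest.approx(1.0, abs=0.02)


def test_sensitivity_saturated_srna_channel_is_flat(cal_params):
    s = log_sensitivity(sf.SRNA_TUNED_AUTOREPRESSOR, cal_params,
                        sf.InducerInput(u1=0.0, u2=0.05), "u2")
    assert abs(s) < 1e-3


def test_sensitivity_peaks_at_interior_atc_level(cal_params):
    """The u1 response is switch-like: log-gain rises from ~0, peaks above
    the aTc threshold, and falls again toward saturation."""
    grid = [2.0, 5.0, 10.0, 20.0, 40.0, 80.0]
    sens = [log_sensitivity(sf.AUTOREPRESSOR, cal_params,
                            sf.InducerInput(u1=u), "u1") for u in grid]
    peak = int(np.argmax(sens))
    assert 0 < peak < len(grid) - 1
    assert grid[peak] > cal_params.theta1
    with pytest.raises(ValueError):
        log_sensitivity(sf.AUTOREPRESSOR, cal_params, sf.InducerInput(), "u1")


def test_trajectory_csv_round_trip(tmp_path, cal_params):
    import pandas as pd

    traj = simulate_timecourse(sf.AUTOREPRESSOR, cal_params,
                               sf.InducerInput(u1=10.0), t_end=100.0)
    path = tmp_path / "traj.csv"
    traj.to_csv(str(path))
    back = pd.read_csv(path)
    np.testing.assert_allclose(back[["m", "p"]].to_numpy(), traj.states,
                               rtol=1e-14)
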