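"""Deterministic analysis: time courses, steady states, dose-response
surfaces, response times and disturbance rejection.

Steady states exploit the structure of the models: at constant induction
the protein, sRNA and duplex are explicit functions of the mRNA level, so
the fixed point reduces to a scalar root problem in ``m`` whose left-hand
side is monotone for these negative-feedback topologies.  The root is
bracketed on ``[0, production_max / delta_m]`` and solved with Brent's
method to machine precision; the result is verified against the full
right-hand side and a long-integration fallback guards pathological
parameter sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .circuits import (
    CircuitParams,
    CircuitState,
    CircuitTopology,
    InducerInput,
    PromoterMode,
    TopologyKind,
    _mrna_production,
    _rhs_array,
    _srna_production,
    hill_activation,
)

__all__ = [
    "Trajectory",
    "DoseResponseSurface",
    "SteadyStateError",
    "IntegrationError",
    "simulate_timecourse",
    "steady_state",
    "steady_state_protein_batch",
    "dose_response",
    "response_time_t90",
    "disturbance_response",
    "square_wave",
    "log_sensitivity",
]


class SteadyStateError(RuntimeError):
    """Raised when no verified steady state can be produced."""


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails; carries the failure time."""


@dataclass(frozen=True)
class Trajectory:
    """A simulated time course: ``states[i]`` is the state at ``times[i]``."""

    times: np.ndarray
    states: np.ndarray
    topology: CircuitTopology
    params: CircuitParams
    inputs: InducerInput

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states) or len(self.times) < 2:
            raise ValueError("trajectory needs >= 2 aligned samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.states < 0):
            raise ValueError("states must be non-negative")

    def observable(self, name: str = "p") -> np.ndarray:
        idx = self.topology.species.index(name)
        return self.states[:, idx]

    def final_state(self) -> CircuitState:
        return CircuitState.from_array(self.states[-1], self.topology)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times})
        for j, name in enumerate(self.topology.species):
            df[name] = self.states[:, j]
        return df

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.15g")


@dataclass(frozen=True)
class DoseResponseSurface:
    """Steady-state output over a one- or two-dimensional inducer grid."""

    axis1_name: str
    axis1: np.ndarray
    axis2_name: str | None
    axis2: np.ndarray | None
    output: np.ndarray  # shape (len(axis1), len(axis2) or 1)
    topology: CircuitTopology
    params: CircuitParams
    base: InducerInput

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.output)) or np.any(self.output < 0):
            raise ValueError("surface output must be finite and >= 0")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, v1 in enumerate(self.axis1):
            if self.axis2 is None:
                rows.append({self.axis1_name: v1, "p_star": self.output[i, 0]})
            else:
                for j, v2 in enumerate(self.axis2):
                    rows.append({self.axis1_name: v1, self.axis2_name: v2,
                                 "p_star": self.output[i, j]})
        return pd.DataFrame(rows)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.15g")


# ---------------------------------------------------------------------------
# Time integration
# ---------------------------------------------------------------------------

def simulate_timecourse(topology: CircuitTopology, params: CircuitParams,
                        inputs: InducerInput,
                        state0: CircuitState | None = None,
                        t_end: float = 600.0,
                        reltol: float = 1e-7, abstol: float = 1e-9,
                        n_points: int = 400,
                        max_step: float = np.inf) -> Trajectory:
    """Integrate the circuit ODEs from ``state0`` (default: empty cell).

    Uses a stiff-capable integrator (LSODA) with dense output sampled at
    ``n_points`` >= 200 uniformly spaced times.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    for tol in (reltol, abstol):
        if not (0 < tol <= 1e-2):
            raise ValueError("tolerances must lie in (0, 1e-2]")
    if n_points < 200:
        raise ValueError("at least 200 output points required")
    y0 = (state0 or CircuitState()).as_array(topology)

    def fun(t: float, y: np.ndarray) -> np.ndarray:
        return _rhs_array(topology, y, params, inputs.at(t))

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(fun, (0.0, t_end), y0, method="LSODA", rtol=reltol,
                    atol=abstol, t_eval=t_eval, max_step=max_step)
    if not sol.success:
        t_fail = sol.t[-1] if len(sol.t) else 0.0
        raise IntegrationError(f"integration failed at t = {t_fail:.3f} min: {sol.message}")
    states = np.clip(sol.y.T, 0.0, None)
    return Trajectory(times=sol.t, states=states, topology=topology,
                      params=params, inputs=inputs)


# ---------------------------------------------------------------------------
# Steady states
# ---------------------------------------------------------------------------

def _mrna_balance(topology: CircuitTopology, pr: CircuitParams,
                  u: tuple[float, float, float]) -> tuple[Callable[[float], float], float]:
    """The scalar mRNA balance ``f(m)`` and its bracket upper bound.

    ``f(m) = production(m) - delta_m*m - k*s(m)*m`` with protein and sRNA
    eliminated via their own balances; ``f(0) >= 0`` and ``f(m_hi) <= 0``.
    """
    u1, u2, u3 = u
    if topology.kind is TopologyKind.CLOSED_LOOP_SRNA:
        prod_max = _mrna_production(topology, pr, 0.0, u1, u3)  # p-independent
    else:
        prod_max = pr.a0 + pr.a1
    m_hi = prod_max / pr.delta_m

    def f(m: float) -> float:
        p = pr.kappa * m / pr.delta_p
        prod = _mrna_production(topology, pr, p, u1, u3)
        loss = pr.delta_m * m
        if topology.n_states == 4:
            b = _srna_production(topology, pr, p, u2)
            loss += pr.k * m * b / (pr.delta_s + pr.k * m)
        return prod - loss

    return f, m_hi


def _assemble_state(topology: CircuitTopology, pr: CircuitParams, m: float,
                    u: tuple[float, float, float]) -> CircuitState:
    p = pr.kappa * m / pr.delta_p
    if topology.n_states == 2:
        return CircuitState(m=m, p=p)
    b = _srna_production(topology, pr, p, u[1])
    s = b / (pr.delta_s + pr.k * m)
    c = pr.k * s * m / pr.delta_c
    return CircuitState(m=m, p=p, s=s, c=c)


def _verify(topology: CircuitTopology, state: CircuitState, pr: CircuitParams,
            u: tuple[float, float, float]) -> bool:
    y = state.as_array(topology)
    resid = np.max(np.abs(_rhs_array(topology, y, pr, u)))
    return resid < 1e-9 * max(1.0, float(np.max(np.abs(y))))


def steady_state(topology: CircuitTopology, params: CircuitParams,
                 inputs: InducerInput) -> CircuitState:
    """Unique attracting fixed point at constant induction.

    The returned state satisfies ``||rhs||_inf < 1e-9 * max(1, ||state||_inf)``.
    Raises :class:`SteadyStateError` if no verified fixed point is found.
    """
    u = inputs.constants()
    f, m_hi = _mrna_balance(topology, params, u)
    if m_hi == 0.0 or f(0.0) <= 0.0:
        m_star = 0.0
    else:
        hi = m_hi * (1.0 + 1e-12) + 1e-300
        m_star = brentq(f, 0.0, hi, xtol=1e-14 * max(1.0, m_hi),
                        rtol=4.0 * np.finfo(float).eps, maxiter=300)
    state = _assemble_state(topology, params, m_star, u)
    if _verify(topology, state, params, u):
        return state

    # Fallback: relax by long integration, then Newton-refine the full system.
    traj = simulate_timecourse(topology, params, inputs,
                               t_end=50.0 / params.delta_p,
                               reltol=1e-10, abstol=1e-12)
    y0 = traj.states[-1]
    sol = root(lambda y: _rhs_array(topology, y, params, u), y0, method="hybr",
               tol=1e-13)
    cand = CircuitState.from_array(np.clip(sol.x, 0.0, None), topology)
    if _verify(topology, cand, params, u):
        return cand
    raise SteadyStateError(
        f"no verified steady state for {topology.name} at u={u}")


def steady_state_protein_batch(topology: CircuitTopology, params: CircuitParams,
                               inputs: InducerInput,
                               scales: Mapping[str, np.ndarray] | None = None,
                               n_iter: int = 90) -> np.ndarray:
    """Vectorized steady-state protein for many cells at once.

    ``scales`` maps a multiplicative parameter name (``a0, a1, b0, b1,
    kappa`` or the joint ``copy_number``) to a per-cell factor array; this
    is the fast path for extrinsic-variability sampling, solved by
    bisection of the scalar mRNA balance for all cells simultaneously.
    """
    u1, u2, u3 = inputs.constants()
    pr = params
    scales = dict(scales or {})
    n = 1
    for v in scales.values():
        n = max(n, np.size(v))

    def per_cell(name: str) -> np.ndarray:
        base = np.full(n, getattr(pr, name), dtype=float)
        if name in scales:
            base = base * np.asarray(scales.pop(name), dtype=float)
        return base

    a0 = per_cell("a0")
    a1 = per_cell("a1")
    b0 = per_cell("b0")
    b1 = per_cell("b1")
    kappa = per_cell("kappa")
    if "copy_number" in scales:
        cn = np.asarray(scales.pop("copy_number"), dtype=float)
        a0, a1, b0, b1 = a0 * cn, a1 * cn, b0 * cn, b1 * cn
    if scales:
        raise ValueError(f"unsupported scaled parameters: {sorted(scales)}")
    if np.any(a0 < 0) or np.any(a1 < 0) or np.any(b0 < 0) or np.any(b1 < 0) \
            or np.any(kappa < 0):
        raise ValueError("scaled parameters must remain non-negative")

    closed = topology.kind is TopologyKind.CLOSED_LOOP_SRNA
    if closed:
        if topology.output_promoter_mode is PromoterMode.INDUCIBLE:
            g3 = hill_activation(u3, pr.theta3, pr.n3)
        else:
            g3 = 1.0
        prod_max = a0 + a1 * g3
    else:
        f1 = 1.0 if u1 == 0 else 1.0 / (1.0 + (u1 / pr.theta1) ** pr.n1)
        prod_max = a0 + a1
    f2 = hill_activation(u2, pr.theta2, pr.n2)

    def balance(m: np.ndarray) -> np.ndarray:
        p = kappa * m / pr.delta_p
        if closed:
            prod = a0 + a1 * g3
            act_arg = p * f2
            act = np.where(act_arg > 0,
                           act_arg ** pr.n_A / (pr.K_A ** pr.n_A + act_arg ** pr.n_A),
                           0.0)
            b = b0 + b1 * act
        else:
            rep_arg = p * f1
            prod = a0 + a1 / (1.0 + (rep_arg / pr.K_R) ** pr.n_R)
            b = b0 + b1 * f2
        loss = pr.delta_m * m
        if topology.n_states == 4:
            loss = loss + pr.k * m * b / (pr.delta_s + pr.k * m)
        return prod - loss

    lo = np.zeros(n)
    hi = prod_max / pr.delta_m
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        pos = balance(mid) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    m = 0.5 * (lo + hi)
    return kappa * m / pr.delta_p


# ---------------------------------------------------------------------------
# Dose response and dynamic metrics
# ---------------------------------------------------------------------------

def dose_response(topology: CircuitTopology, params: CircuitParams,
                  grid1: tuple[str, Sequence[float]],
                  grid2: tuple[str, Sequence[float]] | None = None,
                  base: InducerInput = InducerInput()) -> DoseResponseSurface:
    """Steady-state output over a cartesian grid of one or two inducers."""
    name1, vals1 = grid1[0], np.asarray(grid1[1], dtype=float)
    if grid2 is not None:
        name2, vals2 = grid2[0], np.asarray(grid2[1], dtype=float)
    else:
        name2, vals2 = None, np.array([np.nan])
    for nm in filter(None, (name1, name2)):
        if nm not in ("u1", "u2", "u3"):
            raise ValueError(f"unknown inducer axis {nm!r}")
    out = np.empty((len(vals1), len(vals2)))
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            kw = dict(u1=base.u1, u2=base.u2, u3=base.u3)
            kw[name1] = v1
            if name2 is not None:
                kw[name2] = v2
            try:
                st = steady_state(topology, params, InducerInput(**kw))
            except SteadyStateError as exc:
                raise SteadyStateError(
                    f"steady state failed at grid point {name1}={v1}"
                    + (f", {name2}={v2}" if name2 else "")) from exc
            out[i, j] = st.p
    return DoseResponseSurface(axis1_name=name1, axis1=vals1, axis2_name=name2,
                               axis2=(vals2 if grid2 is not None else None),
                               output=out, topology=topology, params=params,
                               base=base)


def response_time_t90(traj: Trajectory, observable: str = "p") -> float:
    """First time the observable crosses 90% of its final value.

    The trajectory's final value proxies the steady state, so the run
    must span several protein half-lives.  Linear interpolation between
    the bracketing samples.
    """
    v = traj.observable(observable)
    final = float(v[-1])
    if final <= 0:
        raise ValueError("flat or zero trajectory: response time undefined")
    target = 0.9 * final
    if v[0] >= target:
        raise ValueError("trajectory starts at or above 90% of its final value")
    above = np.nonzero(v >= target)[0]
    if len(above) == 0:
        raise ValueError("observable never crosses 90% of its final value")
    i = int(above[0])
    t0, t1 = traj.times[i - 1], traj.times[i]
    v0, v1 = v[i - 1], v[i]
    return float(t0 + (target - v0) / (v1 - v0) * (t1 - t0))


def square_wave(period: float = 240.0, amplitude: float = 0.3) -> Callable[[float], float]:
    """Unit-mean square wave: ``1 + a`` for the first half period,
    ``1 - a`` for the second."""
    if not (0 <= amplitude < 1):
        raise ValueError("amplitude must lie in [0, 1)")
    if period <= 0:
        raise ValueError("period must be > 0")

    def wave(t: float) -> float:
        return 1.0 + amplitude if (t % period) < period / 2.0 else 1.0 - amplitude

    return wave


def disturbance_response(topology: CircuitTopology, params: CircuitParams,
                         u_baseline: InducerInput, disturbed: str,
                         modulation: Callable[[float], float] | None = None,
                         period: float = 240.0, n_settle: int = 1,
                         n_measure: int = 2,
                         reltol: float = 1e-7, abstol: float = 1e-9,
                         ) -> tuple[Trajectory, float]:
    """Response to a multiplicative disturbance ``u(t) = u0 * u*(t)``.

    The system is pre-equilibrated at the baseline, then simulated with
    the named input modulated by the strictly positive, unit-mean profile
    ``u*(t)`` (default: +/-30% square wave, 240 min period).  The
    attenuation is the relative output peak-to-peak divided by the
    relative input peak-to-peak, measured after ``n_settle`` periods.
    """
    if disturbed not in ("u1", "u2", "u3"):
        raise ValueError(f"unknown input {disturbed!r}")
    if modulation is None:
        modulation = square_wave(period=period)
    t_end = (n_settle + n_measure) * period
    probe = np.linspace(0.0, t_end, 512)
    mvals = np.array([modulation(t) for t in probe])
    if np.any(mvals <= 0):
        raise ValueError("modulation must be strictly positive")

    u0 = getattr(u_baseline, disturbed)
    if callable(u0):
        raise ValueError("baseline input must be constant")
    state0 = steady_state(topology, params, u_baseline)
    kw = dict(u1=u_baseline.u1, u2=u_baseline.u2, u3=u_baseline.u3)
    kw[disturbed] = (lambda t: u0 * modulation(t))
    traj = simulate_timecourse(topology, params, InducerInput(**kw),
                               state0=state0, t_end=t_end, reltol=reltol,
                               abstol=abstol,
                               n_points=max(400, 100 * (n_settle + n_measure)),
                               max_step=period / 50.0)
    window = traj.times >= n_settle * period
    out = traj.observable("p")[window]
    out_rel = float(np.ptp(out) / np.mean(out)) if np.mean(out) > 0 else 0.0
    mwin = np.array([modulation(t) for t in traj.times[window]])
    in_rel = float(np.ptp(mwin) / np.mean(mwin))
    attenuation = out_rel / in_rel if in_rel > 0 else 0.0
    return traj, attenuation


def log_sensitivity(topology: CircuitTopology, params: CircuitParams,
                    inputs: InducerInput, input_name: str,
                    rel_step: float = 0.01) -> float:
    """Central-difference logarithmic gain ``d ln p* / d ln u`` at the
    operating point (default step: 1% in log space)."""
    if input_name not in ("u1", "u2", "u3"):
        raise ValueError(f"unknown input {input_name!r}")
    u0 = getattr(inputs, input_name)
    if callable(u0) or u0 <= 0:
        raise ValueError("input value must be a positive constant")
    h = math.log1p(rel_step)
    ps = []
    for sign in (+1.0, -1.0):
        kw = dict(u1=inputs.u1, u2=inputs.u2, u3=inputs.u3)
        kw[input_name] = u0 * math.exp(sign * h)
        ps.append(steady_state(topology, params, InducerInput(**kw)).p)
    if min(ps) <= 0:
        raise ValueError("steady-state output vanished; sensitivity undefined")
    return (math.log(ps[0]) - math.log(ps[1])) / (2.0 * h)
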