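"""Compiled Gillespie direct-method kernel for the circuit networks.

Specialized to the three topologies so the inner event loop is free of
Python overhead; the generic :class:`~srnafb.circuits.ReactionNetwork`
path in :mod:`srnafb.noise` computes identical propensities and serves as
the cross-check.  Parameters arrive as a flat float vector (see
:func:`pack_params`); input-coupling Hill factors are pre-evaluated since
induction is constant during a run.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .circuits import (
    CircuitParams,
    CircuitTopology,
    InducerInput,
    PromoterMode,
    TopologyKind,
    hill_activation,
    hill_repression,
)

# pv layout
_A0, _A1, _KR, _NR, _KA, _NA, _B0, _B1, _KAP, _K, _DM, _DS, _DC, _DP, \
    _OM, _F1, _F2, _G3, _CODE = range(19)

_CODES = {
    TopologyKind.AUTOREPRESSOR: 0.0,
    TopologyKind.SRNA_TUNED_AUTOREPRESSOR: 1.0,
    TopologyKind.CLOSED_LOOP_SRNA: 2.0,
}


def pack_params(topology: CircuitTopology, params: CircuitParams,
                inputs: InducerInput, omega: float | None = None) -> np.ndarray:
    u1, u2, u3 = inputs.constants()
    pr = params
    om = pr.omega if omega is None else float(omega)
    f1 = hill_repression(u1, pr.theta1, pr.n1)
    f2 = hill_activation(u2, pr.theta2, pr.n2)
    if topology.kind is TopologyKind.CLOSED_LOOP_SRNA and \
            topology.output_promoter_mode is PromoterMode.INDUCIBLE:
        g3 = hill_activation(u3, pr.theta3, pr.n3)
    else:
        g3 = 1.0
    return np.array([pr.a0, pr.a1, pr.K_R, pr.n_R, pr.K_A, pr.n_A, pr.b0,
                     pr.b1, pr.kappa, pr.k, pr.delta_m, pr.delta_s, pr.delta_c,
                     pr.delta_p, om, f1, f2, g3, _CODES[topology.kind]],
                    dtype=np.float64)


@njit(cache=True)
def ssa_endpoint(pv, y0, t_end, seed):  # pragma: no cover - compiled
    """Final molecule counts of one SSA run; returns (state4, absorbed)."""
    np.random.seed(seed)
    code = int(pv[_CODE])
    om = pv[_OM]
    m = float(y0[0])
    p = float(y0[1])
    s = float(y0[2])
    c = float(y0[3])
    t = 0.0
    while True:
        # regulated mRNA production
        if code == 2:
            prod_m = om * (pv[_A0] + pv[_A1] * pv[_G3])
        else:
            x = p * pv[_F1] / (om * pv[_KR])
            prod_m = om * (pv[_A0] + pv[_A1] / (1.0 + x ** pv[_NR]))
        a1 = prod_m
        a2 = pv[_DM] * m
        a3 = pv[_KAP] * m
        a4 = pv[_DP] * p
        if code == 0:
            total = a1 + a2 + a3 + a4
            a5 = 0.0
            a6 = 0.0
            a7 = 0.0
        else:
            if code == 1:
                prod_s = om * (pv[_B0] + pv[_B1] * pv[_F2])
            else:
                xa = p * pv[_F2] / (om * pv[_KA])
                h = xa ** pv[_NA]
                prod_s = om * (pv[_B0] + pv[_B1] * (h / (1.0 + h)))
            a5 = prod_s
            a6 = pv[_DS] * s
            a7 = pv[_K] * s * m / om
            a8 = pv[_DC] * c
            total = a1 + a2 + a3 + a4 + a5 + a6 + a7 + a8
        if total <= 0.0:
            return np.array([m, p, s, c]), True
        t -= math.log(np.random.random()) / total
        if t >= t_end:
            return np.array([m, p, s, c]), False
        r = np.random.random() * total
        if r < a1:
            m += 1.0
        elif r < a1 + a2:
            m -= 1.0
        elif r < a1 + a2 + a3:
            p += 1.0
        elif r < a1 + a2 + a3 + a4:
            p -= 1.0
        elif r < a1 + a2 + a3 + a4 + a5:
            s += 1.0
        elif r < a1 + a2 + a3 + a4 + a5 + a6:
            s -= 1.0
        elif r < a1 + a2 + a3 + a4 + a5 + a6 + a7:
            m -= 1.0
            s -= 1.0
            c += 1.0
        else:
            c -= 1.0
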