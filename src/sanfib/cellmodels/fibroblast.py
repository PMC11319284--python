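"""Active atrial fibroblast model (MacCannell-type).

Non-excitable cell with its own membrane dynamics: a time- and
voltage-dependent K+ current (activation ``r``, inactivation ``s``), an
inward-rectifier K+ current, an Na+/K+ pump and a background Na+ leak, on a
6.3 pF membrane.  Intracellular concentrations are held fixed.  The
background-sodium conductance is set by requiring zero net current at the
model's published resting potential of -49.6 mV (see docs/methods.md); the
depolarised rest is the property that matters for fibroblast-myocyte
coupling, where the fibroblast acts as a current source whenever its
myocyte neighbours are below that potential.

State layout: 0 V (mV), 1 r, 2 s.  Time constants are in ms natively.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

N_STATES = 3

CM_PF = 6.3
_CM = 0.0063  # nF

_R = 8314.472
_T = 310.0
_F = 96485.3415
_RTF = _R * _T / _F

_KO = 5.4
_KI = 129.4
_NAO = 140.0
_NAI = 8.5

_G_KV = 0.25             # nS/pF
_G_K1 = 0.4822 / CM_PF   # inward rectifier: 0.4822 nS total, per pF here
_I_NAK_MAX = 2.002       # pA/pF
_KM_K = 1.0
_KM_NA = 11.0

V_REST = -49.6  # mV, published resting potential


def _g_b_na() -> float:
    """Background Na+ conductance (nS/pF) pinned by zero net current at
    the published resting potential."""
    V = V_REST
    EK = _RTF * math.log(_KO / _KI)
    ENa = _RTF * math.log(_NAO / _NAI)
    r_inf = 1.0 / (1.0 + math.exp(-(V + 20.0) / 11.0))
    s_inf = 1.0 / (1.0 + math.exp((V + 23.0) / 2.7))
    i_Kv = _G_KV * r_inf * s_inf * (V - EK)
    i_K1 = _G_K1 * (V - EK) / (1.0 + math.exp(0.07 * (V + 80.0)))
    pna = _NAI ** 1.5
    i_NaK = (_I_NAK_MAX * (_KO / (_KO + _KM_K)) * pna / (pna + _KM_NA ** 1.5)
             * (V + 150.0) / (V + 200.0))
    return (i_Kv + i_K1 + i_NaK) / (ENa - V)


_G_B_NA = _g_b_na()

STATE_NAMES = ("V", "r", "s")


def initial_state() -> np.ndarray:
    s = np.zeros(N_STATES)
    V = V_REST
    s[0] = V
    s[1] = 1.0 / (1.0 + math.exp(-(V + 20.0) / 11.0))
    s[2] = 1.0 / (1.0 + math.exp((V + 23.0) / 2.7))
    return s


@njit(cache=True, fastmath=True)
def rhs(s, d, i_ext):
    """Derivative of the fibroblast state (per ms); ``i_ext`` in nA,
    depolarising negative."""
    V = s[0]
    r = s[1]
    ss = s[2]

    EK = _RTF * math.log(_KO / _KI)
    ENa = _RTF * math.log(_NAO / _NAI)

    r_inf = 1.0 / (1.0 + math.exp(-(V + 20.0) / 11.0))
    tau_r = 20.3 + 138.0 * math.exp(-((V + 20.0) / 25.9) ** 2)
    s_inf = 1.0 / (1.0 + math.exp((V + 23.0) / 2.7))
    tau_s = 1574.0 + 5268.0 * math.exp(-((V + 23.0) / 22.7) ** 2)
    d[1] = (r_inf - r) / tau_r
    d[2] = (s_inf - ss) / tau_s

    i_Kv = _G_KV * r * ss * (V - EK)
    i_K1 = _G_K1 * (V - EK) / (1.0 + math.exp(0.07 * (V + 80.0)))
    pna = _NAI ** 1.5
    i_NaK = (_I_NAK_MAX * (_KO / (_KO + _KM_K)) * pna / (pna + _KM_NA ** 1.5)
             * (V + 150.0) / (V + 200.0))
    i_b_Na = _G_B_NA * (V - ENa)

    # currents above are pA/pF; i_ext (nA) -> pA then per pF
    d[0] = -((i_Kv + i_K1 + i_NaK + i_b_Na) + i_ext * 1000.0 / CM_PF)
    # dV/dt already in mV/ms (pA/pF); gates are per ms natively


# ---------------------------------------------------------------------------
# Tabulated right-hand side (same contract as the myocyte models)
# ---------------------------------------------------------------------------

_EK_C = _RTF * math.log(_KO / _KI)
_ENA_C = _RTF * math.log(_NAO / _NAI)
_INAK_C = (_I_NAK_MAX * (_KO / (_KO + _KM_K))
           * (_NAI ** 1.5) / (_NAI ** 1.5 + _KM_NA ** 1.5))

V_GRID_MIN = -100.0
V_GRID_MAX = 80.0
V_GRID_STEP = 0.05
N_TAB_COLS = 5

CM_NF = 0.0063  # dV/dt [mV/ms] = -(i_tot + i_ext)[nA] / CM_NF


def make_table():
    V = np.arange(V_GRID_MIN, V_GRID_MAX + V_GRID_STEP / 2, V_GRID_STEP)
    tab = np.zeros((V.size, N_TAB_COLS))
    r_inf = 1.0 / (1.0 + np.exp(-(V + 20.0) / 11.0))
    tau_r = 20.3 + 138.0 * np.exp(-((V + 20.0) / 25.9) ** 2)
    s_inf = 1.0 / (1.0 + np.exp((V + 23.0) / 2.7))
    tau_s = 1574.0 + 5268.0 * np.exp(-((V + 23.0) / 22.7) ** 2)
    tab[:, 0] = r_inf / tau_r
    tab[:, 1] = 1.0 / tau_r
    tab[:, 2] = s_inf / tau_s
    tab[:, 3] = 1.0 / tau_s
    tab[:, 4] = 1.0 / (1.0 + np.exp(0.07 * (V + 80.0)))
    return V_GRID_MIN, 1.0 / V_GRID_STEP, tab.astype(np.float32)


@njit(cache=True, fastmath=True)
def rhs_tab(s, d, tab, v0, dvinv):
    """Tabulated equivalent of ``rhs``; returns total ionic current in nA."""
    V = s[0]
    u = (V - v0) * dvinv
    i0 = int(u)
    if i0 < 0:
        i0 = 0
    elif i0 > tab.shape[0] - 2:
        i0 = tab.shape[0] - 2
    f = u - i0
    t0 = tab[i0]
    t1 = tab[i0 + 1]

    EK = _EK_C
    ENa = _ENA_C
    r_a = t0[0] + f * (t1[0] - t0[0])
    r_b = t0[1] + f * (t1[1] - t0[1])
    s_a = t0[2] + f * (t1[2] - t0[2])
    s_b = t0[3] + f * (t1[3] - t0[3])
    d[1] = r_a - r_b * s[1]
    d[2] = s_a - s_b * s[2]

    k1g = t0[4] + f * (t1[4] - t0[4])
    i_Kv = _G_KV * s[1] * s[2] * (V - EK)
    i_K1 = _G_K1 * (V - EK) * k1g
    i_NaK = _INAK_C * (V + 150.0) / (V + 200.0)
    i_b_Na = _G_B_NA * (V - ENa)
    return (i_Kv + i_K1 + i_NaK + i_b_Na) * CM_PF * 1e-3  # pA/pF -> nA
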