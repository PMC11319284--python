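"""Single-cell integration utilities: forward-Euler drivers, steady states,
spontaneous cycle length and the atrial threshold-charge curve.

All integration uses the tabulated right-hand sides (identical numerics to
the tissue engine) with forward Euler at dt = 5 us by default.  Steady
states are cached per parameter set within a process because the 500 s
equilibration dominates run time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import atrial, fibroblast, san
from .base import CellParams, CellState, Phenotype

DT_MS = 0.005          # 5 us
EQUIL_S = 500.0        # single-cell equilibration


# ---------------------------------------------------------------------------
# drivers (one per phenotype; numba requires monomorphic call sites)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _drive_san(state, mult, tab, v0, dvinv, auton, dt, n_steps, stride,
               rec, stim_amp, stim_t0, stim_t1):
    d = np.empty(san.N_STATES)
    w = np.empty(san.N_TAB_COLS)
    k = 0
    for i in range(n_steps):
        t = i * dt
        i_ext = stim_amp if (t >= stim_t0 and t < stim_t1) else 0.0
        i_tot = san.rhs_tab(state, d, mult, tab, v0, dvinv, auton, w)
        d[0] = -(i_tot + i_ext) / san.CM_NF
        if stride > 0 and i % stride == 0 and k < rec.shape[0]:
            rec[k] = state[0]   # pre-update sample, matching the engine
            k += 1
        for j in range(san.N_STATES):
            state[j] += dt * d[j]
    return k


@njit(cache=True, fastmath=True)
def _drive_atrial(state, gna, tab, v0, dvinv, dt, n_steps, stride,
                  rec, stim_amp, stim_t0, stim_t1):
    d = np.empty(atrial.N_STATES)
    w = np.empty(atrial.N_TAB_COLS)
    k = 0
    for i in range(n_steps):
        t = i * dt
        i_ext = stim_amp if (t >= stim_t0 and t < stim_t1) else 0.0
        i_tot = atrial.rhs_tab(state, d, gna, tab, v0, dvinv, w)
        d[0] = -(i_tot + i_ext) / atrial.CM_NF
        if stride > 0 and i % stride == 0 and k < rec.shape[0]:
            rec[k] = state[0]   # pre-update sample, matching the engine
            k += 1
        for j in range(atrial.N_STATES):
            state[j] += dt * d[j]
    return k


@njit(cache=True, fastmath=True)
def _drive_fib(state, tab, v0, dvinv, dt, n_steps, stride,
               rec, stim_amp, stim_t0, stim_t1):
    d = np.empty(fibroblast.N_STATES)
    k = 0
    for i in range(n_steps):
        t = i * dt
        i_ext = stim_amp if (t >= stim_t0 and t < stim_t1) else 0.0
        i_tot = fibroblast.rhs_tab(state, d, tab, v0, dvinv)
        d[0] = -(i_tot + i_ext) / fibroblast.CM_NF
        if stride > 0 and i % stride == 0 and k < rec.shape[0]:
            rec[k] = state[0]   # pre-update sample, matching the engine
            k += 1
        for j in range(fibroblast.N_STATES):
            state[j] += dt * d[j]
    return k


@njit(cache=True, fastmath=True)
def _san_to_upstroke_max(state, mult, tab, v0, dvinv, auton, dt, max_steps):
    """Advance a spontaneously beating SAN cell to the dV/dt maximum of the
    next upstroke (phase convention for tissue initialisation)."""
    d = np.empty(san.N_STATES)
    w = np.empty(san.N_TAB_COLS)
    best = np.empty(san.N_STATES)
    best_dvdt = -1.0e30
    seen_upstroke = False
    for i in range(max_steps):
        i_tot = san.rhs_tab(state, d, mult, tab, v0, dvinv, auton, w)
        d[0] = -i_tot / san.CM_NF
        dvdt = d[0]
        if state[0] > -30.0 and dvdt > 0.5:
            seen_upstroke = True
            if dvdt > best_dvdt:
                best_dvdt = dvdt
                for j in range(san.N_STATES):
                    best[j] = state[j]
        elif seen_upstroke and state[0] > 0.0 and dvdt < 0.0:
            # upstroke complete
            for j in range(san.N_STATES):
                state[j] = best[j]
            return 0
        for j in range(san.N_STATES):
            state[j] += dt * d[j]
    return 1


def evaluate_rhs(state: CellState, params: CellParams,
                 injected_current: float = 0.0) -> np.ndarray:
    """Reference state derivative (per ms) for one cell.

    ``injected_current`` is in nA, depolarising negative.  Uses the
    closed-form (non-tabulated) right-hand sides.
    """
    if state.phenotype is not params.phenotype:
        raise ValueError("state/params phenotype mismatch")
    s = state.vector
    d = np.zeros_like(s)
    if params.phenotype is Phenotype.SAN:
        san.rhs(s, d, params.mult_vector(), params.ach_mM,
                1.0 if params.iso_active else 0.0, injected_current)
    elif params.phenotype is Phenotype.ATRIAL:
        atrial.rhs(s, d, float(params.mult_vector()[0]), injected_current)
    else:
        fibroblast.rhs(s, d, injected_current)
    if not np.all(np.isfinite(d)):
        bad = int(np.flatnonzero(~np.isfinite(d))[0])
        from .base import state_names
        raise FloatingPointError(
            f"non-finite derivative for {state_names(params.phenotype)[bad]!r} "
            f"in {params.phenotype.value} cell"
        )
    return d


def _tables_for(params: CellParams):
    if params.phenotype is Phenotype.SAN:
        v0, dvinv, tab = san.make_table(params.ach_mM, params.iso_active)
        auton = san.autonomic_scalars(params.ach_mM, params.iso_active)
        return v0, dvinv, tab, auton
    if params.phenotype is Phenotype.ATRIAL:
        return (*atrial.make_table(), None)
    return (*fibroblast.make_table(), None)


def integrate(params: CellParams, state: np.ndarray, duration_ms: float,
              dt_ms: float = DT_MS, record_stride_ms: float = 0.2,
              stim: tuple | None = None):
    """Integrate one cell in place; returns (times_ms, voltage_trace).

    ``stim`` is (amplitude_nA, t_on_ms, t_off_ms); depolarising negative.
    """
    v0, dvinv, tab, auton = _tables_for(params)
    n_steps = int(round(duration_ms / dt_ms))
    if record_stride_ms is None:
        stride, n_rec = 0, 0
    else:
        stride = max(1, int(round(record_stride_ms / dt_ms)))
        n_rec = n_steps // stride + 1
    rec = np.empty(n_rec)
    amp, t0, t1 = stim if stim is not None else (0.0, -1.0, -1.0)
    if params.phenotype is Phenotype.SAN:
        k = _drive_san(state, params.mult_vector(), tab, v0, dvinv, auton,
                       dt_ms, n_steps, stride, rec, amp, t0, t1)
    elif params.phenotype is Phenotype.ATRIAL:
        k = _drive_atrial(state, float(params.mult_vector()[0]), tab, v0,
                          dvinv, dt_ms, n_steps, stride, rec, amp, t0, t1)
    else:
        k = _drive_fib(state, tab, v0, dvinv, dt_ms, n_steps, stride, rec,
                       amp, t0, t1)
    if not np.isfinite(state).all():
        bad = int(np.flatnonzero(~np.isfinite(state))[0])
        from .base import state_names
        raise FloatingPointError(
            f"non-finite state {state_names(params.phenotype)[bad]!r} after "
            f"single-cell integration ({params.phenotype.value})"
        )
    times = np.arange(k) * dt_ms * max(stride, 1)
    return times, rec[:k]


_SS_CACHE: dict = {}


def _params_key(params: CellParams, equil_s: float, dt_ms: float):
    return (
        params.phenotype,
        tuple(np.round(params.mult_vector(), 12)),
        round(params.ach_concentration, 9),
        params.iso_active,
        equil_s,
        dt_ms,
    )


def steady_state(params: CellParams, equil_s: float = EQUIL_S,
                 dt_ms: float = DT_MS, use_cache: bool = True) -> CellState:
    """Single-cell steady state after ``equil_s`` seconds of integration.

    For the SAN the returned state sits at the dV/dt maximum of an upstroke
    (so phase-aligned tissues can be built from copies); for the atrial and
    fibroblast phenotypes it is the quiescent endpoint.
    """
    key = _params_key(params, equil_s, dt_ms)
    if use_cache and key in _SS_CACHE:
        return CellState(params.phenotype, _SS_CACHE[key].copy())

    if params.phenotype is Phenotype.SAN:
        s = san.initial_state()
    elif params.phenotype is Phenotype.ATRIAL:
        s = atrial.initial_state()
    else:
        s = fibroblast.initial_state()

    integrate(params, s, equil_s * 1000.0, dt_ms, record_stride_ms=None)

    if params.phenotype is Phenotype.SAN:
        v0, dvinv, tab, auton = _tables_for(params)
        status = _san_to_upstroke_max(s, params.mult_vector(), tab, v0, dvinv,
                                      auton, dt_ms, int(5000.0 / dt_ms))
        if status != 0:
            raise RuntimeError(
                "SAN cell shows no spontaneous upstroke after equilibration"
            )
    elif params.phenotype is Phenotype.FIBROBLAST:
        v0, dvinv, tab, _ = _tables_for(params)
        d = np.zeros_like(s)
        i_tot = fibroblast.rhs_tab(s, d, tab, v0, dvinv)
        if abs(i_tot / fibroblast.CM_NF) > 1e-6:
            raise RuntimeError("fibroblast failed to reach rest (|dV/dt| > 1e-6)")

    if use_cache:
        _SS_CACHE[key] = s.copy()
    return CellState(params.phenotype, s)


def spontaneous_cycle_length(params: CellParams, measure_s: float = 10.0,
                             equil_s: float = EQUIL_S,
                             dt_ms: float = DT_MS) -> float:
    """Mean CL (ms) over ``measure_s`` seconds following equilibration,
    measured between successive AP overshoot peaks."""
    from ..metrics import detect_cycle_lengths

    st = steady_state(params, equil_s, dt_ms)
    times, v = integrate(params, st.vector.copy(), measure_s * 1000.0, dt_ms)
    cls = detect_cycle_lengths(times, v, mode="SAN")
    if len(cls) == 0:
        raise RuntimeError("no spontaneous activity detected")
    return float(np.mean(cls))


# ---------------------------------------------------------------------------
# threshold charge
# ---------------------------------------------------------------------------

@dataclass
class ThresholdCurve:
    """Charge needed to elicit a full atrial AP vs stimulus duration.

    ``charges[i]`` is the minimal (amplitude x duration) product at
    ``durations[i]`` (ms, grid up to 4 ms); beyond ``saturation_ms`` the
    threshold charge is constant at its 4 ms value.
    """

    durations: np.ndarray   # ms
    charges: np.ndarray     # pC
    saturation_ms: float = 4.0

    def qthr(self, ta_ms: float) -> float:
        ta = min(ta_ms, self.saturation_ms)
        ta = max(ta, float(self.durations[0]))
        return float(np.interp(ta, self.durations, self.charges))


def _elicits_ap(params: CellParams, base_state: np.ndarray, amp_nA: float,
                dur_ms: float, dt_ms: float) -> bool:
    s = base_state.copy()
    _, v = integrate(params, s, dur_ms + 100.0, dt_ms,
                     record_stride_ms=0.05, stim=(-abs(amp_nA), 0.0, dur_ms))
    return bool(np.max(v) > 0.0)


def threshold_charge_curve(params: CellParams,
                           durations_ms=(0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0),
                           amp_max_nA: float = 10.0,
                           rel_tol: float = 1e-3,
                           dt_ms: float = DT_MS) -> ThresholdCurve:
    """Bisection on stimulus amplitude for each duration; a full AP is an
    upstroke crossing 0 mV."""
    if params.phenotype is not Phenotype.ATRIAL:
        raise ValueError("threshold charge is defined for the atrial phenotype")
    base = steady_state(params).vector
    charges = []
    for dur in durations_ms:
        # cap the search so the stimulus cannot push the membrane far past
        # the physiological range (~+80 mV), where the model is undefined;
        # thresholds sit well below this bound for every duration
        amp_hi = min(amp_max_nA, 8.0 / dur)
        lo, hi = 0.0, amp_hi
        if not _elicits_ap(params, base, hi, dur, dt_ms):
            raise RuntimeError(
                f"no AP elicited at {amp_hi} nA for {dur} ms stimulus"
            )
        while (hi - lo) > rel_tol * hi:
            mid = 0.5 * (lo + hi)
            if _elicits_ap(params, base, mid, dur, dt_ms):
                hi = mid
            else:
                lo = mid
        charges.append(hi * dur)
    return ThresholdCurve(np.asarray(durations_ms, dtype=float),
                          np.asarray(charges))
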