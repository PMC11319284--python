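"""Analysis of simulated traces: cycle lengths, safety factor for
conduction, sinus-node recovery time, conduction velocity/time, activation
maps, leading exit pathway and the study's statistical comparisons.

Conventions
-----------
* SAN cycle lengths are intervals between successive AP overshoot peaks
  (above 0 mV); atrial cycle lengths are intervals between successive
  maxima of dV/dt during upstrokes (a dV/dt > 1 mV/ms gate rejects
  subthreshold deflections).
* The safety factor compares the depolarising gap-junctional charge a cell
  receives against the threshold charge from single-cell stimulation:
  SF = |integral of Igap over ta| / Qthr(ta), where ta runs from the
  instant |Igap| first reaches 1 % of its depolarising peak (pre-peak) to
  the next sign change, and Qthr saturates at its 4 ms value.
* A depolarising gap current is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CELL_LENGTH_UM = 67.0

#: corrected SNRT above this value is classified as nodal dysfunction (ms)
SNRT_DYSFUNCTION_MS = 525.0

_DVDT_GATE = 1.0  # mV/ms, atrial upstroke detection gate


# ---------------------------------------------------------------------------
# event detection / cycle lengths
# ---------------------------------------------------------------------------

def _san_event_times(times: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Overshoot (AP peak) times: local maxima above 0 mV."""
    if len(v) < 3:
        return np.empty(0)
    core = (v[1:-1] >= v[:-2]) & (v[1:-1] > v[2:]) & (v[1:-1] > 0.0)
    idx = np.flatnonzero(core) + 1
    if len(idx) == 0:
        return np.empty(0)
    # collapse plateau-split duplicates closer than 5 ms
    keep = [idx[0]]
    for i in idx[1:]:
        if times[i] - times[keep[-1]] > 5.0:
            keep.append(i)
    return times[np.asarray(keep)]


def _atrial_event_times(times: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Times of dV/dt maxima of detected upstrokes."""
    if len(v) < 3:
        return np.empty(0)
    dt = times[1] - times[0]
    dv = np.diff(v) / dt
    above = dv > _DVDT_GATE
    if not above.any():
        return np.empty(0)
    segs = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            segs.append((i, j))
            i = j
        else:
            i += 1
    events = []
    for i, j in segs:
        k = i + int(np.argmax(dv[i:j]))
        events.append(times[k])
    return np.asarray(events)


def detect_cycle_lengths(times: np.ndarray, voltage: np.ndarray,
                         mode: str = "SAN") -> np.ndarray:
    """Successive event intervals (ms) for one voltage trace.

    ``mode`` is ``"SAN"`` (overshoot convention) or ``"ATRIUM"`` (dV/dt
    maximum convention).  Fewer than two events yields an empty array
    (no drive).
    """
    times = np.asarray(times, dtype=float)
    voltage = np.asarray(voltage, dtype=float)
    if mode.upper() == "SAN":
        ev = _san_event_times(times, voltage)
    elif mode.upper() in ("ATRIUM", "ATRIAL"):
        ev = _atrial_event_times(times, voltage)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(ev) < 2:
        return np.empty(0)
    return np.diff(ev)


def event_times(times: np.ndarray, voltage: np.ndarray, mode: str) -> np.ndarray:
    """Public access to the per-mode AP event times."""
    if mode.upper() == "SAN":
        return _san_event_times(np.asarray(times), np.asarray(voltage))
    return _atrial_event_times(np.asarray(times), np.asarray(voltage))


# ---------------------------------------------------------------------------
# safety factor
# ---------------------------------------------------------------------------

def safety_factor(times: np.ndarray, igap: np.ndarray, threshold_curve) -> float:
    """SF for one cell over one beat of its gap-current trace.

    Returns NaN when the trace has no depolarising (negative) phase, which
    callers report as failed conduction.
    """
    times = np.asarray(times, dtype=float)
    igap = np.asarray(igap, dtype=float)
    ipk = int(np.argmin(igap))
    peak = igap[ipk]
    if not (peak < 0.0):
        return float("nan")
    level = 0.01 * peak  # negative number, 1 % of the depolarising peak
    pre = np.flatnonzero(igap[:ipk + 1] > level)
    i_on = int(pre[-1]) + 1 if len(pre) else 0
    i_on = min(i_on, ipk)
    post = np.flatnonzero(igap[ipk:] >= 0.0)
    i_off = ipk + int(post[0]) if len(post) else len(igap) - 1
    if i_off <= i_on:
        return float("nan")
    ta = times[i_off] - times[i_on]
    qgap = abs(np.trapezoid(igap[i_on:i_off + 1], times[i_on:i_off + 1]))
    return qgap / threshold_curve.qthr(ta)


# ---------------------------------------------------------------------------
# sinus node recovery time
# ---------------------------------------------------------------------------

def sinus_node_recovery_time(times: np.ndarray, atrial_voltage: np.ndarray,
                             last_stim_ms: float,
                             basal_cl_ms: float | None = None,
                             exclusion_ms: float = 200.0):
    """SNRT (ms) from an atrial voltage trace after overdrive pacing.

    The stimulus-evoked AP is excluded by ignoring upstrokes within
    ``exclusion_ms`` of the last stimulus (the evoked wave crosses the
    tissue within tens of ms).  Returns (snrt, corrected) where
    ``corrected = snrt - basal_cl_ms`` (NaN when no basal CL is given);
    both NaN when no recovery beat occurs in the window (arrest/pause).
    """
    ev = _atrial_event_times(np.asarray(times), np.asarray(atrial_voltage))
    ev = ev[ev > last_stim_ms + exclusion_ms]
    if len(ev) == 0:
        return float("nan"), float("nan")
    snrt = float(ev[0] - last_stim_ms)
    corr = snrt - basal_cl_ms if basal_cl_ms is not None else float("nan")
    return snrt, corr


def is_nodal_dysfunction(corrected_snrt_ms: float) -> bool:
    """Corrected SNRT classification flag (> 525 ms = dysfunction)."""
    return bool(corrected_snrt_ms > SNRT_DYSFUNCTION_MS)


# ---------------------------------------------------------------------------
# conduction velocity / activation maps
# ---------------------------------------------------------------------------

def conduction_velocity(activation_ms: np.ndarray,
                        cell_length_um: float = CELL_LENGTH_UM):
    """(CV in cm/s, CT in ms) along an ordered path of activation times."""
    act = np.asarray(activation_ms, dtype=float)
    if np.isnan(act).any():
        raise ValueError("non-activated cells on path")
    ct = float(act[-1] - act[0])
    if ct <= 0:
        raise ValueError("activation not monotone along path (CT <= 0)")
    length_cm = len(act) * cell_length_um * 1e-4
    return length_cm / (ct * 1e-3), ct


def activation_times(times: np.ndarray, voltages: np.ndarray,
                     is_san: np.ndarray, window: tuple) -> np.ndarray:
    """Per-cell first event time within ``window`` (ms); NaN if none.

    ``voltages`` is (n_samples, n_cells); ``is_san`` selects the overshoot
    convention per cell, others use the atrial upstroke convention.
    Fibroblast columns should be excluded by the caller.
    """
    t0, t1 = window
    times = np.asarray(times)
    sel = (times >= t0) & (times <= t1)
    tw = times[sel]
    out = np.full(voltages.shape[1], np.nan)
    for c in range(voltages.shape[1]):
        v = np.asarray(voltages[sel, c], dtype=float)
        ev = _san_event_times(tw, v) if is_san[c] else _atrial_event_times(tw, v)
        if len(ev):
            out[c] = ev[0]
    return out


def activation_map(times: np.ndarray, voltages: np.ndarray,
                   is_san: np.ndarray, cycle_index: int = -1,
                   max_spread_ms: float = 1200.0) -> np.ndarray:
    """Activation-time map for one beat, relative to the earliest event.

    The beat is anchored on the earliest-activating cell's event train
    (``cycle_index`` selects which of its beats); each cell contributes its
    first event within [anchor - 50 ms, anchor + max_spread_ms].
    """
    times = np.asarray(times)
    # reference = cell with the most events (robust pacemaker proxy)
    best_c, best_ev = 0, np.empty(0)
    for c in range(voltages.shape[1]):
        v = np.asarray(voltages[:, c], dtype=float)
        ev = _san_event_times(times, v) if is_san[c] else _atrial_event_times(times, v)
        if len(ev) > len(best_ev):
            best_c, best_ev = c, ev
    if len(best_ev) == 0:
        return np.full(voltages.shape[1], np.nan)
    anchor = best_ev[cycle_index]
    act = activation_times(times, voltages, is_san,
                           (anchor - 50.0, anchor + max_spread_ms))
    finite = act[np.isfinite(act)]
    if len(finite):
        act = act - np.nanmin(act)
    return act


def leading_sep(activation_ms: np.ndarray, interface_cells: dict) -> int | None:
    """Exit pathway whose interface atrial cells activate earliest.

    ``interface_cells`` maps SEP id -> array of cell indices (the first
    atrial column beyond that SEP's exit).  Ties break to the lowest id;
    returns None when no interface cell activated.
    """
    best_id, best_t = None, np.inf
    for sep_id in sorted(interface_cells):
        cells = interface_cells[sep_id]
        t = np.nanmin(activation_ms[cells]) if len(cells) else np.nan
        if np.isfinite(t) and t < best_t - 1e-12:
            best_id, best_t = sep_id, t
    return best_id


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _guarded_p(a, b=None, popmean=None):
    a = np.asarray(a, dtype=float)
    if b is not None:
        diff = a - np.asarray(b, dtype=float)
        if np.std(diff) == 0:
            return (1.0 if abs(np.mean(diff)) < 1e-12 else 0.0), 0.0
        t, p = stats.ttest_rel(a, b)
        return float(p), float(t)
    if np.std(a) == 0:
        return (1.0 if abs(np.mean(a) - popmean) < 1e-12 else 0.0), 0.0
    t, p = stats.ttest_1samp(a, popmean)
    return float(p), float(t)


def compare_setups(values_by_setup: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided paired t-tests between the n=5 setups and one-sample
    t-tests against the scalar uniform (U) value.

    ``values_by_setup`` maps setup name -> scalar (U) or length-n array.
    Returns a tidy frame (setup_a, setup_b, t, p, significant).
    """
    rows = []
    names = list(values_by_setup)
    u_val = values_by_setup.get("U")
    for i, a in enumerate(names):
        va = np.atleast_1d(np.asarray(values_by_setup[a], dtype=float))
        if a != "U" and u_val is not None:
            if len(va) < 2:
                raise ValueError(f"setup {a}: need n >= 2 samples")
            p, t = _guarded_p(va, popmean=float(np.atleast_1d(u_val)[0]))
            rows.append((a, "U", t, p, p <= alpha))
        for b in names[i + 1:]:
            if a == "U" or b == "U":
                continue
            vb = np.atleast_1d(np.asarray(values_by_setup[b], dtype=float))
            if len(va) != len(vb) or len(va) < 2:
                raise ValueError(f"paired test {a} vs {b}: need equal n >= 2")
            p, t = _guarded_p(va, vb)
            rows.append((a, b, t, p, p <= alpha))
    return pd.DataFrame(rows, columns=["setup_a", "setup_b", "t", "p",
                                       "significant"])


# ---------------------------------------------------------------------------
# aggregate result container
# ---------------------------------------------------------------------------

@dataclass
class MetricsResult:
    """Study metrics for one tissue run."""

    atrial_cl_ms: float = float("nan")
    atrial_cl_sd_ms: float = float("nan")
    san_cl_ms: float = float("nan")
    san_cl_sd_ms: float = float("nan")
    safety_factor: float = float("nan")
    snrt_ms: float = float("nan")
    snrt_corrected_ms: float = float("nan")
    sep_cv_cm_s: float = float("nan")
    sep_ct_ms: float = float("nan")
    leading_sep: int | None = None
    outcome: str = "unknown"   # drive | pace-no-drive | arrest | n:1-block
    activation: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("activation", "extras")}
        d.update(self.extras)
        return d
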