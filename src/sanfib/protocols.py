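"""Study orchestration: the experiment matrix (setups x conditions x
seeds x scales), end-to-end runs (generate -> simulate -> analyse), result
tables and reproducibility manifests.

Conditions mirror the study protocols: control, 25 nM ACh, 1 uM ISO,
2 Hz overdrive pacing (alone or on top of a drug), 50 % If block, 25 %
ICaL block, alternative exit-pathway widths, and the "full" configuration
(mosaic pathways, ACh+ISO combined additively, reduced SAN/fibroblast
gap resistances).

The default scale is the desk-size ``strip`` preset; the ``full``
200 x 200-cell, 50 s configuration is expressed by the same machinery and
flagged as a long run.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics
from .cellmodels import CellParams, Phenotype, threshold_charge_curve
from .engine import PacingConfig, SimulationConfig, TraceSet, run
from .tissue_generator import (ATRIAL, SAN, CouplingConfig, GeometryConfig,
                               build_coupling, build_setup, full_preset,
                               half_preset, strip_preset)

SCALES = ("full", "half", "strip")

#: condition name -> (simulation overrides, coupling overrides, geometry overrides)
CONDITIONS = {
    "control":     ({}, {}, {}),
    "ach25":       ({"ach_nM": 25.0}, {}, {}),
    "iso1uM":      ({"iso": True}, {}, {}),
    "pace":        ({"paced": True}, {}, {}),
    "ach25+pace":  ({"ach_nM": 25.0, "paced": True}, {}, {}),
    "iso+pace":    ({"iso": True, "paced": True}, {}, {}),
    "ifblock50":   ({"blocks": {"If": 0.5}}, {}, {}),
    "icalblock25": ({"blocks": {"ICaL": 0.25}}, {}, {}),
    "sepwidth7":   ({}, {}, {"sep_width": 7}),
    "sepwidth11":  ({}, {}, {"sep_width": 11}),
    "sepwidth15":  ({}, {}, {"sep_width": 15}),
    "sepwidth19":  ({}, {}, {"sep_width": 19}),
    "full":        ({"ach_nM": 25.0, "iso": True},
                    {"R_SAN": 10.0, "R_fib": 100.0},
                    {"mosaic": True}),
}

#: (duration_s, record_window_s, pacing start/stop) per scale
_SCALE_TIMING = {
    "full": dict(duration=50.0, window=5.0, pace_start=32.0, pace_stop=41.5,
                 paced_window=10.0),
    "half": dict(duration=30.0, window=5.0, pace_start=14.0, pace_stop=23.5,
                 paced_window=6.0),
    "strip": dict(duration=6.0, window=4.0, pace_start=6.0, pace_stop=15.5,
                  paced_window=6.0),
}
_STRIP_PACED_DURATION = 18.0


@dataclass(frozen=True)
class Experiment:
    """One cell of the study matrix."""

    setup: str = "U"             # U | H | UF | HF
    condition: str = "control"
    seed: int = 1                # tissue seed (1..5; U is deterministic)
    scale: str = "strip"
    duration_s: float | None = None      # override
    record_window_s: float | None = None

    def __post_init__(self):
        if self.setup not in ("U", "H", "UF", "HF"):
            raise ValueError(f"unknown setup {self.setup!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")


def _preset_for(scale: str, sep_width: int, mosaic: bool) -> GeometryConfig:
    if scale == "full":
        return full_preset(sep_width=sep_width, mosaic=mosaic)
    if scale == "half":
        return half_preset(sep_width=sep_width, mosaic=mosaic)
    return strip_preset(sep_width=sep_width, mosaic=mosaic)


def build_experiment(exp: Experiment):
    """Materialise (geometry, heterogeneity, coupling, sim_config)."""
    sim_over, coup_over, geo_over = (dict(d) for d in CONDITIONS[exp.condition])
    width = geo_over.pop("sep_width", 11)
    mosaic = geo_over.pop("mosaic", False)
    cfg = _preset_for(exp.scale, width, mosaic)
    geom, het = build_setup(exp.setup, seed=exp.seed, config=cfg)
    coupling = build_coupling(geom, CouplingConfig(**coup_over))

    timing = _SCALE_TIMING[exp.scale]
    paced = sim_over.pop("paced", False)
    duration = exp.duration_s or timing["duration"]
    window = exp.record_window_s or timing["window"]
    pacing = None
    if paced:
        if exp.scale == "strip" and exp.duration_s is None:
            duration = _STRIP_PACED_DURATION
        window = exp.record_window_s or timing["paced_window"]
        pacing = PacingConfig(start_s=timing["pace_start"],
                              stop_s=timing["pace_stop"])
    sim = SimulationConfig(duration_s=duration, record_window_s=window,
                           pacing=pacing, seed=exp.seed,
                           label=f"{exp.setup}-{exp.condition}-s{exp.seed}-{exp.scale}",
                           **sim_over)
    return geom, het, coupling, sim


_QTHR_CACHE: dict = {}


def atrial_threshold_curve(gna_mult: float = 2.0):
    """Threshold-charge curve of the tissue's atrial phenotype (cached)."""
    key = round(gna_mult, 9)
    if key not in _QTHR_CACHE:
        _QTHR_CACHE[key] = threshold_charge_curve(
            CellParams(Phenotype.ATRIAL, multipliers={"gNa": gna_mult}))
    return _QTHR_CACHE[key]


def _column_cls(ts: TraceSet, cols, mode: str):
    out = []
    for c in cols:
        cls = metrics.detect_cycle_lengths(ts.times_ms,
                                           ts.voltages[:, c].astype(float),
                                           mode)
        out.append(cls)
    return out


def analyze_run(ts: TraceSet, basal_cl_ms: float | None = None,
                compute_sf: bool = True,
                max_cl_cells: int = 400) -> metrics.MetricsResult:
    """Full metric extraction for one tissue run.

    CL conventions: atrial CLs are averaged in time then across cells; the
    SAN reports the *last* CL of each cell averaged across cells (their
    synchronisation measure).  SF is evaluated on the leading pathway's
    interface cells over the last conducted beat (averaged over all
    pathways when every pathway conducts).  ``max_cl_cells`` caps the
    number of columns scanned per phenotype (uniform subsample) to bound
    analysis cost on large grids.
    """
    res = metrics.MetricsResult()
    is_san = ts.cell_type == SAN
    is_atr = ts.cell_type == ATRIAL
    san_cols = np.flatnonzero(is_san)
    atr_cols = np.flatnonzero(is_atr)
    if len(san_cols) > max_cl_cells:
        san_cols = san_cols[:: len(san_cols) // max_cl_cells + 1]
    if len(atr_cols) > max_cl_cells:
        atr_cols = atr_cols[:: len(atr_cols) // max_cl_cells + 1]

    san_cls = _column_cls(ts, san_cols, "SAN")
    atr_cls = _column_cls(ts, atr_cols, "ATRIUM")

    last_cls = [c[-1] for c in san_cls if len(c)]
    if last_cls:
        res.san_cl_ms = float(np.mean(last_cls))
        res.san_cl_sd_ms = float(np.std(last_cls))
    cell_means = [np.mean(c) for c in atr_cls if len(c)]
    if cell_means:
        res.atrial_cl_ms = float(np.mean(cell_means))
        res.atrial_cl_sd_ms = float(np.std(cell_means))

    n_san_beating = sum(len(c) > 0 for c in san_cls)
    n_atr_beating = sum(len(c) > 0 for c in atr_cls)
    if n_atr_beating > 0.5 * len(atr_cls):
        if (np.isfinite(res.san_cl_ms) and np.isfinite(res.atrial_cl_ms)
                and res.atrial_cl_ms > 1.55 * res.san_cl_ms):
            ratio = int(round(res.atrial_cl_ms / res.san_cl_ms))
            res.outcome = f"{ratio}:1-block"
        else:
            res.outcome = "drive"
    elif n_san_beating > 0.5 * max(len(san_cls), 1):
        res.outcome = "pace-no-drive"
    else:
        res.outcome = "arrest"

    # activation map over myocyte columns (last complete beat)
    myo = np.flatnonzero(is_san | is_atr)
    sub = myo[:: max(1, len(myo) // 2500)]
    act = metrics.activation_map(ts.times_ms,
                                 ts.voltages[:, sub].astype(float),
                                 is_san[sub], cycle_index=-2)
    res.activation = (sub, act)

    # leading pathway
    ifc = {sid: np.asarray(ix) for sid, ix in ts.interface_cells.items()}
    act_full = np.full(ts.voltages.shape[1], np.nan)
    act_full[sub] = act
    for sid, ix in ifc.items():
        for c in ix:
            if not np.isfinite(act_full[c]):
                ev = metrics.event_times(ts.times_ms,
                                         ts.voltages[:, c].astype(float),
                                         "ATRIUM")
                act_full[c] = ev[-1] if len(ev) else np.nan
    # use absolute last-event times at interfaces for lead determination
    lead_t = {}
    for sid, ix in ifc.items():
        ts_last = [act_full[c] for c in ix if np.isfinite(act_full[c])]
        lead_t[sid] = min(ts_last) if ts_last else np.nan
    finite = {s: t for s, t in lead_t.items() if np.isfinite(t)}
    if finite:
        res.leading_sep = min(sorted(finite), key=lambda s: finite[s])

    # safety factor at the leading interface (all pathways if all conduct)
    if compute_sf and res.leading_sep is not None and ts.igap.shape[1]:
        curve = atrial_threshold_curve(ts.config.atrial_gna_mult)
        all_drive = all(np.isfinite(t) for t in lead_t.values())
        sep_ids = sorted(finite) if all_drive else [res.leading_sep]
        sfs = []
        for sid in sep_ids:
            for k, c in enumerate(ifc[sid]):
                pos = _igap_column(ts, sid, k)
                if pos is None:
                    continue
                t_act = act_full[c]
                if not np.isfinite(t_act):
                    continue
                sel = ((ts.igap_times_ms >= t_act - 300.0)
                       & (ts.igap_times_ms <= t_act + 60.0))
                sf = metrics.safety_factor(ts.igap_times_ms[sel],
                                           ts.igap[sel, pos].astype(float),
                                           curve)
                if np.isfinite(sf):
                    sfs.append(sf)
        if sfs:
            res.safety_factor = float(np.mean(sfs))

    # conduction along the leading pathway centreline
    if res.leading_sep is not None:
        sep = next(s for s in ts.geometry.seps if s.sep_id == res.leading_sep)
        row = sep.center_row
        path_cols = []
        for c in range(sep.col_start, sep.col_exit):
            try:
                path_cols.append(ts.column(row, c))
            except KeyError:
                path_cols.append(None)
        ok = [p for p in path_cols if p is not None]
        if len(ok) >= sep.col_exit - sep.col_start - 2:
            acts = []
            for p in ok:
                ev = metrics.event_times(ts.times_ms,
                                         ts.voltages[:, p].astype(float),
                                         "SAN" if ts.cell_type[p] == SAN
                                         else "ATRIUM")
                acts.append(ev[-1] if len(ev) else np.nan)
            acts = np.asarray(acts)
            if np.isfinite(acts).all() and acts[-1] > acts[0]:
                try:
                    cv, ct = metrics.conduction_velocity(acts)
                    res.sep_cv_cm_s, res.sep_ct_ms = cv, ct
                except ValueError:
                    pass

    # SNRT after pacing
    if len(ts.stim_times_ms):
        last = float(ts.stim_times_ms[-1])
        far = _far_atrial_column(ts)
        if far is not None:
            snrt, corr = metrics.sinus_node_recovery_time(
                ts.times_ms, ts.voltages[:, far].astype(float), last,
                basal_cl_ms)
            res.snrt_ms = snrt
            res.snrt_corrected_ms = corr
    return res


def _igap_column(ts: TraceSet, sep_id: int, k: int):
    pos = 0
    for sid in sorted(ts.interface_cells):
        n = len(ts.interface_cells[sid])
        if sid == sep_id:
            return pos + k if k < n else None
        pos += n
    return None


def _far_atrial_column(ts: TraceSet):
    """An atrial cell far from both the pacing block and the pathways."""
    is_atr = ts.cell_type == ATRIAL
    if not is_atr.any():
        return None
    rc = ts.cell_rc
    nr = ts.geometry.nrows
    score = (rc[:, 0] - nr // 2) ** 2 * 1.0
    score[~is_atr] = np.inf
    cexit = max((s.col_exit for s in ts.geometry.seps), default=0)
    score[rc[:, 1] < cexit + 5] = np.inf
    c = int(np.argmin(score))
    return None if not np.isfinite(score[c]) else c


def run_experiment(exp: Experiment, basal_cl_ms: float | None = None,
                   save_traces=None):
    """Deterministic end-to-end run; returns (MetricsResult, manifest).

    No-drive outcomes are reported as structured results, never raised.
    ``save_traces`` may be a path for the HDF5 trace archive.
    """
    geom, het, coupling, sim = build_experiment(exp)
    t0 = time.time()
    ts = run(sim, geom, coupling, het)
    res = analyze_run(ts, basal_cl_ms=basal_cl_ms)
    manifest = {
        "experiment": exp.__dict__ | {},
        "geometry_hash": zlib.crc32(geom.type_map.tobytes()),
        "n_cells": {k: int(v) for k, v in geom.counts().items()},
        "wall_s": round(time.time() - t0, 1),
        "outcome": res.outcome,
        "versions": _versions(),
    }
    if save_traces:
        ts.save(save_traces)
    return res, ts, manifest


def _versions() -> dict:
    import numba
    import numpy
    import scipy

    from . import __version__
    return {"sanfib": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "numba": numba.__version__}


def summarize(results: dict) -> pd.DataFrame:
    """Tidy mean +- sd table.

    ``results`` maps (setup, condition) -> list of MetricsResult (one per
    seed).  Returns one row per setup/condition/metric with n, mean, sd.
    """
    rows = []
    for (setup, condition), rlist in results.items():
        if not rlist:
            continue
        frame = pd.DataFrame([r.as_dict() for r in rlist])
        for col in ("atrial_cl_ms", "san_cl_ms", "safety_factor",
                    "snrt_ms", "snrt_corrected_ms", "sep_cv_cm_s",
                    "sep_ct_ms"):
            vals = frame[col].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            rows.append({
                "setup": setup, "condition": condition, "metric": col,
                "n": len(vals), "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            })
        outcomes = ";".join(r.outcome for r in rlist)
        rows.append({"setup": setup, "condition": condition,
                     "metric": "outcome", "n": len(rlist),
                     "mean": np.nan, "sd": np.nan, "note": outcomes})
    cols = ["setup", "condition", "metric", "n", "mean", "sd", "note"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    return df[cols]


def save_manifest(path, manifest: dict):
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2, default=str)
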