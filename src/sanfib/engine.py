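"""Coupled-network forward-Euler engine.

Integrates every non-insulator cell of a tissue with its phenotype's ionic
model, exchanging ohmic gap-junctional current with its four von Neumann
neighbours (no-flux boundaries are simply absent edges).  The integration
step is 5 us by default; full-grid voltages are recorded at 200 us within
the analysis window, and gap currents of the pathway-interface cells are
recorded at integration resolution for safety-factor analysis.

Sign conventions: a depolarising external or gap current is negative;
``Igap_i = sum_j g_ij (V_i - V_j)`` so a cell ahead of the wavefront
(neighbours more depolarised) sees a negative Igap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .cellmodels import atrial, fibroblast, san, singlecell
from .cellmodels.base import CellParams, Phenotype
from .tissue_generator import (ATRIAL, FIBROBLAST, INSULATOR, SAN,
                               CouplingMap, TissueGeometry)


@dataclass
class PacingConfig:
    """High-frequency atrial pacing (overdrive-suppression protocol)."""

    rate_hz: float = 2.0
    amplitude_nA: float = 5.0      # depolarising magnitude
    pulse_ms: float = 1.0
    start_s: float = 32.0
    stop_s: float = 41.5
    region_size: int = 15          # square block at the top-right corner

    @property
    def stim_times_ms(self) -> np.ndarray:
        period = 1000.0 / self.rate_hz
        return np.arange(self.start_s * 1000.0, self.stop_s * 1000.0 + 0.5 * period,
                         period)


@dataclass
class SimulationConfig:
    dt_ms: float = 0.005
    duration_s: float = 50.0
    record_window_s: float = 5.0       # last N seconds (10 when paced)
    record_stride_ms: float = 0.2
    pacing: PacingConfig | None = None
    ach_nM: float = 0.0
    iso: bool = False
    blocks: dict = field(default_factory=dict)   # current -> fraction
    atrial_gna_mult: float = 2.0       # crista-terminalis calibration
    record: str = "myocytes"           # "myocytes" | "all"
    igap_stride_steps: int = 1
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        if self.record_stride_ms < self.dt_ms:
            raise ValueError("record_stride_ms must be >= dt_ms")
        if self.pacing is not None:
            if self.pacing.stop_s > self.duration_s:
                raise ValueError("pacing window exceeds duration")


@dataclass
class TraceSet:
    """Recorded voltages (and interface gap currents) of one tissue run."""

    times_ms: np.ndarray           # (n_rec,)
    voltages: np.ndarray           # (n_rec, n_recorded) float32, mV
    cell_rc: np.ndarray            # (n_recorded, 2) grid coordinates
    cell_type: np.ndarray          # (n_recorded,) type codes
    igap_times_ms: np.ndarray      # (n_igap,)
    igap: np.ndarray               # (n_igap, n_interface) float32, nA
    interface_cells: dict          # sep_id -> indices into recorded arrays
    stim_times_ms: np.ndarray
    config: SimulationConfig
    geometry: TissueGeometry

    def column(self, r, c):
        hit = np.flatnonzero((self.cell_rc[:, 0] == r) & (self.cell_rc[:, 1] == c))
        if len(hit) == 0:
            raise KeyError(f"cell ({r},{c}) not recorded")
        return int(hit[0])

    def save(self, path):
        import zlib

        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=self.times_ms)
            f.create_dataset("voltage", data=self.voltages,
                             compression="gzip", compression_opts=1)
            f.create_dataset("cell_rc", data=self.cell_rc)
            f.create_dataset("cell_type", data=self.cell_type)
            f.create_dataset("igap_time", data=self.igap_times_ms)
            f.create_dataset("igap", data=self.igap,
                             compression="gzip", compression_opts=1)
            f.create_dataset("stim_times", data=self.stim_times_ms)
            for sep_id, idx in self.interface_cells.items():
                f.create_dataset(f"interface/{sep_id}", data=np.asarray(idx))
            f.create_dataset("type_map", data=self.geometry.type_map)
            f.create_dataset("seps", data=np.array(
                [[s.sep_id, s.row0, s.row1, s.col_start, s.col_exit,
                  s.center_row] for s in self.geometry.seps],
                dtype=np.int64).reshape(-1, 6))
            for k, v in self.geometry.config.__dict__.items():
                f.attrs[f"geom_{k}"] = v
            f.attrs["label"] = self.config.label
            f.attrs["dt_ms"] = self.config.dt_ms
            f.attrs["duration_s"] = self.config.duration_s
            f.attrs["atrial_gna_mult"] = self.config.atrial_gna_mult
            f.attrs["geometry_hash"] = zlib.crc32(
                self.geometry.type_map.tobytes())

    @classmethod
    def load(cls, path) -> "TraceSet":
        import h5py

        from .tissue_generator import GeometryConfig, SepInfo

        with h5py.File(path, "r") as f:
            gattrs = {k[5:]: v for k, v in f.attrs.items()
                      if k.startswith("geom_")}
            gattrs["center"] = tuple(int(x) for x in gattrs["center"])
            for key in ("nrows", "ncols", "n_seps", "sep_length",
                        "sep_width", "border", "semi_major", "semi_minor"):
                gattrs[key] = int(gattrs[key])
            gattrs["mosaic"] = bool(gattrs["mosaic"])
            cfg = GeometryConfig(**gattrs)
            seps = [SepInfo(int(a), int(b), int(c), int(d), int(e), int(fr),
                            d + cfg.sep_length / 2.0 - 0.5)
                    for a, b, c, d, e, fr in f["seps"][...]]
            geom = TissueGeometry(cfg, f["type_map"][...], seps)
            sim = SimulationConfig(
                dt_ms=float(f.attrs["dt_ms"]),
                duration_s=float(f.attrs["duration_s"]),
                record_window_s=float(f.attrs["duration_s"]),
                atrial_gna_mult=float(f.attrs["atrial_gna_mult"]),
                label=str(f.attrs["label"]),
            )
            return cls(
                times_ms=f["time"][...],
                voltages=f["voltage"][...],
                cell_rc=f["cell_rc"][...],
                cell_type=f["cell_type"][...],
                igap_times_ms=f["igap_time"][...],
                igap=f["igap"][...],
                interface_cells={int(k): f[f"interface/{k}"][...]
                                 for k in f.get("interface", {})},
                stim_times_ms=f["stim_times"][...],
                config=sim,
                geometry=geom,
            )


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _simulate(san_states, atr_states, fib_states, san_mult,
              san_tab, san_v0, san_dvinv, san_auton,
              atr_tab, atr_v0, atr_dvinv, atr_gna,
              fib_tab, fib_v0, fib_dvinv,
              ctype, clocal, neigh, gedge, v,
              dt, n_steps,
              stim_mask, stim_amp, stim_period, stim_pulse,
              stim_start, stim_stop,
              rec_map, rec_v, rec_start_step, rec_stride,
              ifc_idx, rec_igap, igap_stride):
    n = ctype.shape[0]
    d_san = np.empty(san_states.shape[1])
    d_atr = np.empty(atr_states.shape[1])
    d_fib = np.empty(fib_states.shape[1])
    w_san = np.empty(san_tab.shape[1])
    w_atr = np.empty(atr_tab.shape[1])
    v_new = v.copy()
    rec_row = 0
    igap_row = 0
    for step in range(n_steps):
        t = step * dt
        stim_on = False
        if stim_amp != 0.0 and t >= stim_start and t < stim_stop:
            if (t - stim_start) % stim_period < stim_pulse:
                stim_on = True

        recording = step >= rec_start_step
        if recording and (step - rec_start_step) % rec_stride == 0:
            for i in range(n):
                m = rec_map[i]
                if m >= 0:
                    rec_v[rec_row, m] = v[i]
            rec_row += 1
        igap_now = recording and (step - rec_start_step) % igap_stride == 0

        # single fused pass: gather gap current, advance, stage new voltage
        for i in range(n):
            ig = 0.0
            for k in range(4):
                j = neigh[i, k]
                if j >= 0:
                    ig += gedge[i, k] * (v[i] - v[j])
            ie = ig
            if stim_on and stim_mask[i]:
                ie -= stim_amp    # depolarising (negative) stimulus
            ct = ctype[i]
            li = clocal[i]
            if ct == 0:
                st = san_states[li]
                itot = san.rhs_tab(st, d_san, san_mult[li], san_tab,
                                   san_v0, san_dvinv, san_auton, w_san)
                d_san[0] = -(itot + ie) / san.CM_NF
                for j in range(st.shape[0]):
                    st[j] += dt * d_san[j]
            elif ct == 1:
                st = atr_states[li]
                itot = atrial.rhs_tab(st, d_atr, atr_gna, atr_tab,
                                      atr_v0, atr_dvinv, w_atr)
                d_atr[0] = -(itot + ie) / atrial.CM_NF
                for j in range(st.shape[0]):
                    st[j] += dt * d_atr[j]
            else:
                st = fib_states[li]
                itot = fibroblast.rhs_tab(st, d_fib, fib_tab,
                                          fib_v0, fib_dvinv)
                d_fib[0] = -(itot + ie) / fibroblast.CM_NF
                for j in range(st.shape[0]):
                    st[j] += dt * d_fib[j]
            v_new[i] = st[0]

        if igap_now:
            for k in range(ifc_idx.shape[0]):
                i = ifc_idx[k]
                ig = 0.0
                for kk in range(4):
                    j = neigh[i, kk]
                    if j >= 0:
                        ig += gedge[i, kk] * (v[i] - v[j])
                rec_igap[igap_row, k] = ig
            igap_row += 1

        for i in range(n):
            v[i] = v_new[i]

        if step % 20000 == 0:
            for i in range(n):
                if not np.isfinite(v[i]):
                    return step, i
    return -1, -1


def _edge_conductance(gi, gj, rule: str):
    """Per-edge conductance from the two cells' nominal conductances.

    ``"mean"`` averages the two local conductivities (the default: the
    coupling map is a conductivity field sampled at each cell, and an edge
    sits between the two samples); ``"series"`` combines them as two half-
    cell resistances in series, which biases every edge toward the weaker
    cell and, in steep gradients, starves the pathway exit (see
    docs/methods.md).  Either rule leaves edges at insulator faces at 0.
    """
    gi = np.asarray(gi, dtype=float)
    gj = np.asarray(gj, dtype=float)
    both = (gi > 0) & (gj > 0)
    if rule == "series":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(both, 2.0 * gi * gj / (gi + gj + 1e-300), 0.0)
    elif rule == "mean":
        out = np.where(both, 0.5 * (gi + gj), 0.0)
    else:
        raise ValueError(f"unknown edge rule {rule!r}")
    return out


def gap_current(voltages: np.ndarray, coupling: CouplingMap,
                geometry: TissueGeometry) -> np.ndarray:
    """Net exchanged current (nA) per grid cell for a voltage field.

    ``voltages`` is (nrows, ncols); insulator cells return 0.  Satisfies
    charge conservation: the sum over all cells is zero to round-off.
    """
    tm = geometry.type_map
    g = coupling.g_cell
    nr, nc = tm.shape
    out = np.zeros((nr, nc))
    for dr, dc in ((0, 1), (1, 0)):
        r0 = slice(0, nr - dr)
        r1 = slice(dr, nr)
        c0 = slice(0, nc - dc)
        c1 = slice(dc, nc)
        act0 = tm[r0, c0] != INSULATOR
        act1 = tm[r1, c1] != INSULATOR
        ga = np.where(act0, g[r0, c0], 0.0)
        gb = np.where(act1, g[r1, c1], 0.0)
        ge = _edge_conductance(ga, gb, coupling.config.edge_rule)
        dv = voltages[r0, c0] - voltages[r1, c1]
        out[r0, c0] += ge * dv
        out[r1, c1] -= ge * dv
    return out


def step(states: dict, params: dict, geometry: TissueGeometry,
         coupling: CouplingMap, stimulus: dict | None, dt_ms: float) -> dict:
    """One explicit-Euler update of every cell (reference path).

    ``states`` maps (row, col) -> state vector for every non-insulator
    cell; ``params`` maps (row, col) -> CellParams.  ``stimulus`` maps a
    subset of cells to injected current in nA (depolarising negative).
    Returns a new state dict.  This O(n)-Python implementation exists as an
    independent oracle for the fused kernel and for small tests; ``run`` is
    the production path.
    """
    from .cellmodels.singlecell import evaluate_rhs
    from .cellmodels.base import CellState

    nr, nc = geometry.type_map.shape
    vgrid = np.zeros((nr, nc))
    for (r, c), s in states.items():
        vgrid[r, c] = s[0]
    igap = gap_current(vgrid, coupling, geometry)
    out = {}
    for (r, c), s in states.items():
        i_ext = igap[r, c]
        if stimulus is not None:
            i_ext += stimulus.get((r, c), 0.0)
        p = params[(r, c)]
        d = evaluate_rhs(CellState(p.phenotype, s), p, i_ext)
        out[(r, c)] = s + dt_ms * d
    return out


def _modulated_san_params(config: SimulationConfig) -> CellParams:
    return CellParams(Phenotype.SAN, block_fractions=dict(config.blocks),
                      ach_concentration=config.ach_nM,
                      iso_active=config.iso)


def interface_columns(geometry: TissueGeometry) -> dict:
    """sep_id -> list of (row, col) of the first atrial-phenotype cells
    beyond each pathway exit (the SF measurement set)."""
    tm = geometry.type_map
    out = {}
    for s in geometry.seps:
        cells = []
        for r in range(s.row0, s.row1):
            for c in range(s.col_exit, min(s.col_exit + 3, tm.shape[1])):
                if tm[r, c] == ATRIAL:
                    cells.append((r, c))
                    break
        out[s.sep_id] = cells
    return out


def run(config: SimulationConfig, geometry: TissueGeometry,
        coupling: CouplingMap, heterogeneity=None) -> TraceSet:
    """Generate initial states, integrate the network and record traces.

    Every cell starts from its phenotype's 500 s single-cell steady state;
    SAN cells start phase-aligned at the upstroke dV/dt maximum, with the
    run's autonomic/block modulation already installed (continuous-infusion
    protocol).  Heterogeneity multipliers scale SAN maximal conductances
    only; the modulation applies to SAN cells only.
    """
    tm = geometry.type_map
    nr, nc = tm.shape
    active = np.flatnonzero((tm != INSULATOR).ravel())
    n = active.size
    rows, cols = np.unravel_index(active, tm.shape)
    types = tm.ravel()[active]
    grid_to_active = np.full(nr * nc, -1, dtype=np.int64)
    grid_to_active[active] = np.arange(n)

    # neighbours / edge conductances
    g_flat = coupling.g_cell.ravel()
    neigh = np.full((n, 4), -1, dtype=np.int64)
    gedge = np.zeros((n, 4))
    offs = ((-1, 0), (1, 0), (0, -1), (0, 1))
    for k, (dr, dc) in enumerate(offs):
        rr = rows + dr
        ccc = cols + dc
        ok = (rr >= 0) & (rr < nr) & (ccc >= 0) & (ccc < nc)
        flat = rr[ok] * nc + ccc[ok]
        tgt = grid_to_active[flat]
        sel = np.flatnonzero(ok)
        good = tgt >= 0
        neigh[sel[good], k] = tgt[good]
        gi = g_flat[active[sel[good]]]
        gj = g_flat[flat[good]]
        gedge[sel[good], k] = _edge_conductance(gi, gj,
                                                coupling.config.edge_rule)

    # per-phenotype state blocks
    idx_san = np.flatnonzero(types == SAN)
    idx_atr = np.flatnonzero(types == ATRIAL)
    idx_fib = np.flatnonzero(types == FIBROBLAST)
    clocal = np.zeros(n, dtype=np.int64)
    clocal[idx_san] = np.arange(idx_san.size)
    clocal[idx_atr] = np.arange(idx_atr.size)
    clocal[idx_fib] = np.arange(idx_fib.size)
    ctype = np.where(types == SAN, 0, np.where(types == ATRIAL, 1, 2)).astype(np.int64)

    san_params = _modulated_san_params(config)
    ss_san = singlecell.steady_state(san_params).vector
    atr_params = CellParams(Phenotype.ATRIAL,
                            multipliers={"gNa": config.atrial_gna_mult})
    ss_atr = singlecell.steady_state(atr_params).vector
    ss_fib = singlecell.steady_state(CellParams(Phenotype.FIBROBLAST)).vector

    san_states = np.tile(ss_san, (max(idx_san.size, 1), 1))
    atr_states = np.tile(ss_atr, (max(idx_atr.size, 1), 1))
    fib_states = np.tile(ss_fib, (max(idx_fib.size, 1), 1))

    san_mult = np.ones((max(idx_san.size, 1), san.N_MULT))
    base_mult = san_params.mult_vector()
    san_mult *= base_mult[None, :]
    if heterogeneity is not None:
        het_lookup = {(int(r), int(c)): i
                      for i, (r, c) in enumerate(heterogeneity.cell_rc)}
        for ai in idx_san:
            key = (int(rows[ai]), int(cols[ai]))
            hi = het_lookup.get(key)
            if hi is not None:
                san_mult[clocal[ai]] = base_mult * heterogeneity.multipliers[hi]

    san_v0, san_dvinv, san_tab = san.make_table(san_params.ach_mM,
                                                san_params.iso_active)
    san_auton = san.autonomic_scalars(san_params.ach_mM, san_params.iso_active)
    atr_v0, atr_dvinv, atr_tab = atrial.make_table()
    fib_v0, fib_dvinv, fib_tab = fibroblast.make_table()

    v = np.empty(n)
    v[idx_san] = san_states[clocal[idx_san], 0]
    v[idx_atr] = atr_states[clocal[idx_atr], 0]
    v[idx_fib] = fib_states[clocal[idx_fib], 0]

    # stimulus block (top-right corner, atrial cells)
    stim_mask = np.zeros(n, dtype=np.bool_)
    if config.pacing is not None:
        size = min(config.pacing.region_size, nr, nc)
        block = (rows < size) & (cols >= nc - size) & (types == ATRIAL)
        if not block.any():
            raise ValueError("no atrial cells in the pacing region")
        stim_mask[block] = True
        stim_amp = config.pacing.amplitude_nA
        stim_period = 1000.0 / config.pacing.rate_hz
        stim_pulse = config.pacing.pulse_ms
        stim_start = config.pacing.start_s * 1000.0
        stim_stop = config.pacing.stop_s * 1000.0 + stim_pulse
        stim_times = config.pacing.stim_times_ms
    else:
        stim_amp = 0.0
        stim_period = 1e30
        stim_pulse = 0.0
        stim_start = -1.0
        stim_stop = -1.0
        stim_times = np.empty(0)

    # recording maps
    if config.record == "all":
        rec_sel = np.arange(n)
    else:
        rec_sel = np.flatnonzero(types != FIBROBLAST)
    rec_map = np.full(n, -1, dtype=np.int64)
    rec_map[rec_sel] = np.arange(rec_sel.size)

    dt = config.dt_ms
    n_steps = int(round(config.duration_s * 1000.0 / dt))
    window_ms = config.record_window_s * 1000.0
    rec_start_step = max(0, n_steps - int(round(window_ms / dt)))
    rec_stride = max(1, int(round(config.record_stride_ms / dt)))
    n_rec = (n_steps - rec_start_step + rec_stride - 1) // rec_stride
    rec_v = np.zeros((n_rec, rec_sel.size), dtype=np.float32)

    ifc = interface_columns(geometry)
    ifc_active = []
    ifc_slices = {}
    pos = 0
    for sep_id in sorted(ifc):
        cells = [int(grid_to_active[r * nc + c]) for r, c in ifc[sep_id]]
        cells = [c for c in cells if c >= 0]
        ifc_active.extend(cells)
        ifc_slices[sep_id] = np.arange(pos, pos + len(cells))
        pos += len(cells)
    ifc_idx = np.asarray(ifc_active, dtype=np.int64)
    igap_stride = max(1, int(config.igap_stride_steps))
    n_igap = (n_steps - rec_start_step + igap_stride - 1) // igap_stride
    rec_igap = np.zeros((n_igap, max(ifc_idx.size, 1)), dtype=np.float32)

    bad_step, bad_cell = _simulate(
        san_states, atr_states, fib_states, san_mult,
        san_tab, san_v0, san_dvinv, san_auton,
        atr_tab, atr_v0, atr_dvinv, config.atrial_gna_mult,
        fib_tab, fib_v0, fib_dvinv,
        ctype, clocal, neigh, gedge, v,
        dt, n_steps,
        stim_mask, stim_amp, stim_period, stim_pulse, stim_start, stim_stop,
        rec_map, rec_v, rec_start_step, rec_stride,
        ifc_idx, rec_igap, igap_stride,
    )
    if bad_step >= 0:
        r, c = rows[bad_cell], cols[bad_cell]
        raise FloatingPointError(
            f"non-finite voltage at cell ({r},{c}) near t="
            f"{bad_step * dt:.3f} ms"
        )

    times = (rec_start_step + np.arange(n_rec) * rec_stride) * dt
    igap_times = (rec_start_step + np.arange(n_igap) * igap_stride) * dt
    return TraceSet(
        times_ms=times,
        voltages=rec_v,
        cell_rc=np.column_stack([rows[rec_sel], cols[rec_sel]]),
        cell_type=types[rec_sel].copy(),
        igap_times_ms=igap_times,
        igap=rec_igap if ifc_idx.size else rec_igap[:, :0],
        interface_cells={
            sep_id: np.array([int(rec_map[a]) for a in
                              np.asarray(ifc_active)[sl]], dtype=np.int64)
            for sep_id, sl in ifc_slices.items()
        },
        stim_times_ms=stim_times,
        config=config,
        geometry=geometry,
    )
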