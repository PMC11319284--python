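"""Randomised SAN/atrium tissue construction.

Builds the 2D cell-type layout (elliptical SAN surrounded by an insulating
border, perforated by rectangular sinoatrial exit pathways into the
atrium), places fibroblasts along a density gradient, samples log-normal
conductance heterogeneity for the SAN myocytes, and constructs the
gap-junctional coupling map with the sigmoidal conductance gradient
centred in the exit pathways and spread semicircularly into the atrium.

Geometry conventions: the SAN ellipse is elongated vertically (semi-major
axis along rows); exit pathways are horizontal channels on the right-hand
border, numbered top to bottom; the atrium fills the remainder of the
grid.  Cell size is 67 um, so a 20-cell pathway is 1.34 mm long.

All stochastic steps (fibroblast placement, heterogeneity, mosaic
interspersion) are driven by explicit integer seeds and are bitwise
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cellmodels.san import MULT_NAMES, N_MULT

# cell-type codes used across the package
SAN, ATRIAL, FIBROBLAST, INSULATOR = 0, 1, 2, 3
TYPE_NAMES = {SAN: "SAN", ATRIAL: "ATRIAL", FIBROBLAST: "FIBROBLAST",
              INSULATOR: "INSULATOR"}

CELL_LENGTH_UM = 67.0

#: fibroblast density at the plateau (central SAN), fraction
FIB_CENTRAL_DENSITY = 0.457
#: gradient reaches zero this many cells beyond a pathway exit
FIB_DROP_CELLS = 10


@dataclass(frozen=True)
class GeometryConfig:
    nrows: int = 200
    ncols: int = 200
    center: tuple = (100, 100)          # (row, col) of the SAN ellipse
    semi_major: int = 75                # rows (vertical elongation)
    semi_minor: int = 12                # cols
    n_seps: int = 5
    sep_length: int = 20
    sep_width: int = 11
    border: int = 2                     # insulating ring thickness, cells
    sep_span_frac: float = 0.75         # SEP centres span +- frac * semi_major
    mosaic: bool = False
    cell_length_um: float = CELL_LENGTH_UM


@dataclass
class SepInfo:
    sep_id: int                 # 1-based, numbered top to bottom
    row0: int
    row1: int                   # exclusive
    col_start: int              # first channel column
    col_exit: int               # first atrial column beyond the channel
    center_row: int
    center_col: float           # sigmoid midpoint reference (channel centre)


@dataclass
class TissueGeometry:
    config: GeometryConfig
    type_map: np.ndarray        # (nrows, ncols) int8
    seps: list = field(default_factory=list)

    @property
    def nrows(self):
        return self.config.nrows

    @property
    def ncols(self):
        return self.config.ncols

    def counts(self) -> dict:
        return {name: int(np.sum(self.type_map == code))
                for code, name in TYPE_NAMES.items()}

    def san_region_mask(self) -> np.ndarray:
        """Central-SAN region: the ellipse interior (excluding channels)."""
        cr, cc = self.config.center
        rr, cols = np.mgrid[0:self.nrows, 0:self.ncols]
        a, b = self.config.semi_major, self.config.semi_minor
        return ((rr - cr) / a) ** 2 + ((cols - cc) / b) ** 2 <= 1.0

    def sep_region_mask(self) -> np.ndarray:
        m = np.zeros_like(self.type_map, dtype=bool)
        for s in self.seps:
            m[s.row0:s.row1, s.col_start:s.col_exit] = True
        return m


def build_geometry(config: GeometryConfig, seed: int = 0) -> TissueGeometry:
    """Deterministic layout (the seed matters only for the mosaic option)."""
    cfg = config
    cr, cc = cfg.center
    a, b = cfg.semi_major, cfg.semi_minor
    if cr - a - cfg.border < 0 or cr + a + cfg.border >= cfg.nrows:
        raise ValueError("SAN ellipse (plus border) exceeds the grid rows")
    if cc - b - cfg.border < 0:
        raise ValueError("SAN ellipse (plus border) exceeds the grid columns")

    tm = np.full((cfg.nrows, cfg.ncols), ATRIAL, dtype=np.int8)
    rr, cols = np.mgrid[0:cfg.nrows, 0:cfg.ncols]
    inner = ((rr - cr) / a) ** 2 + ((cols - cc) / b) ** 2 <= 1.0
    outer = (((rr - cr) / (a + cfg.border)) ** 2
             + ((cols - cc) / (b + cfg.border)) ** 2) <= 1.0
    tm[outer] = INSULATOR
    tm[inner] = SAN

    # exit pathways, evenly spaced top to bottom on the right border
    if cfg.n_seps > 0:
        span = cfg.sep_span_frac * a
        centers = (np.linspace(-span, span, cfg.n_seps) if cfg.n_seps > 1
                   else np.array([0.0]))
        rng = np.random.default_rng(seed)
        seps = []
        prev_r1 = -1
        for i, off in enumerate(centers):
            c_row = int(round(cr + off))
            r0 = c_row - cfg.sep_width // 2
            r1 = r0 + cfg.sep_width
            if r0 <= prev_r1:
                raise ValueError("SEP width exceeds the available border arc")
            prev_r1 = r1
            # ellipse boundary column for each channel row
            frac = 1.0 - ((np.arange(r0, r1) - cr) / a) ** 2
            if (frac <= 0).any():
                raise ValueError("SEP rows fall outside the SAN ellipse")
            cb = cc + np.floor(b * np.sqrt(frac)).astype(int)
            col_start = int(cb.max()) + 1
            col_exit = col_start + cfg.sep_length
            if col_exit >= cfg.ncols - 1:
                raise ValueError("SEP exceeds the grid columns")
            # throat: connect each row to the ellipse boundary
            for j, r in enumerate(range(r0, r1)):
                tm[r, cb[j] + 1:col_start] = SAN
            tm[r0:r1, col_start:col_exit] = SAN
            if cfg.mosaic:
                # probability of an atrial cell rises linearly SAN -> atrium
                u = rng.random((r1 - r0, cfg.sep_length))
                p = (np.arange(cfg.sep_length) + 0.5) / cfg.sep_length
                sel = u < p[None, :]
                block = tm[r0:r1, col_start:col_exit]
                block[sel] = ATRIAL
            seps.append(SepInfo(i + 1, r0, r1, col_start, col_exit,
                                c_row, col_start + cfg.sep_length / 2.0 - 0.5))
    else:
        seps = []
    return TissueGeometry(cfg, tm, seps)


def place_fibroblasts(geometry: TissueGeometry, seed: int,
                      p_central: float = FIB_CENTRAL_DENSITY,
                      drop_cells: int = FIB_DROP_CELLS) -> TissueGeometry:
    """Replace cells by fibroblasts along the left-to-right density gradient.

    The probability is ``p_central`` throughout the SAN up to the plateau
    edge (near the right edge of the ellipse), then falls linearly to zero
    ``drop_cells`` columns beyond the pathway exits.  Atrial cells are
    eligible only inside the pathway row bands out to that zero line; the
    remaining atrium stays fibroblast-free.
    """
    cfg = geometry.config
    tm = geometry.type_map.copy()
    if not geometry.seps:
        col_zero = cfg.center[1] + cfg.semi_minor + cfg.border + drop_cells
    else:
        col_zero = max(s.col_exit for s in geometry.seps) + drop_cells
    plateau_col = cfg.center[1] + cfg.semi_minor - 2

    def prob(col):
        if col <= plateau_col:
            return p_central
        return max(0.0, p_central * (col_zero - col) / (col_zero - plateau_col))

    rng = np.random.default_rng(seed)
    eligible = np.zeros_like(tm, dtype=bool)
    eligible[tm == SAN] = True
    for s in geometry.seps:
        band = tm[s.row0:s.row1, s.col_exit:col_zero] == ATRIAL
        eligible[s.row0:s.row1, s.col_exit:col_zero] |= band
        # mosaic atrial cells inside the channel are eligible too
        band2 = tm[s.row0:s.row1, s.col_start:s.col_exit] == ATRIAL
        eligible[s.row0:s.row1, s.col_start:s.col_exit] |= band2
    rows, cols = np.nonzero(eligible)
    u = rng.random(rows.size)
    p = np.array([prob(c) for c in cols])
    tm[rows[u < p], cols[u < p]] = FIBROBLAST
    return TissueGeometry(cfg, tm, list(geometry.seps))


@dataclass
class HeterogeneityField:
    """Per-SAN-cell log-normal multipliers for the 11 randomised parameters.

    ``multipliers[i]`` belongs to the SAN-phenotype cell at
    ``cell_rc[i]`` (row-major order over the type map).
    """

    sigma: float
    seed: int
    cell_rc: np.ndarray        # (n_san, 2) int
    multipliers: np.ndarray    # (n_san, N_MULT)
    param_names: tuple = MULT_NAMES


def sample_heterogeneity(geometry: TissueGeometry, seed: int,
                         sigma: float = 0.2) -> HeterogeneityField:
    """Independent multiplier per parameter per SAN cell: exp(N(0, sigma^2)),
    median 1.  Atrial cells and fibroblasts carry no multipliers."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rows, cols = np.nonzero(geometry.type_map == SAN)
    rng = np.random.default_rng(seed)
    mult = np.exp(rng.normal(0.0, sigma, size=(rows.size, N_MULT)))
    return HeterogeneityField(sigma, seed, np.column_stack([rows, cols]), mult)


@dataclass
class CouplingConfig:
    R_SAN: float = 1000.0      # MOhm (1 GOhm)
    R_fib: float = 1000.0      # MOhm
    R_RA: float = 1.0          # MOhm
    alpha: float = 0.5         # per cell
    center_offset: float = 21.0  # sigmoid midpoint offset, cells toward the exit
    halo_radius: float = 26.0  # semicircular spread reach, cells
    edge_rule: str = "mean"    # "mean" | "series": per-edge conductance from
                               # the two cells' nominal values


@dataclass
class CouplingMap:
    """Nominal per-cell coupling conductance (uS); insulator cells are 0.

    Edge conductances are the series combination of the two cells' nominal
    values, ``g_ij = 2 g_i g_j / (g_i + g_j)``, assembled by the engine.
    """

    config: CouplingConfig
    g_cell: np.ndarray


def sigmoid_profile(x, R_SAN: float, R_RA: float, alpha: float, beta: float):
    """Coupling conductivity S(x) [uS]: x runs along a pathway axis, pointing
    from the atrium into the SAN, so S rises to 1/R_SAN deep in the node and
    falls to 1/R_RA in the atrium; the midpoint sits at x = beta/alpha."""
    z = np.clip(-alpha * np.asarray(x, dtype=float) + beta, -700.0, 700.0)
    return 1.0 / R_RA + (1.0 / R_SAN - 1.0 / R_RA) / (1.0 + np.exp(z))


def build_coupling(geometry: TissueGeometry,
                   coupling: CouplingConfig | None = None) -> CouplingMap:
    """Per-cell conductances with the pathway gradient and halo.

    Fibroblasts couple at 1/R_fib everywhere.  SAN and atrial cells inside a
    pathway's row band (and, beyond the exit, within the semicircular halo)
    follow the sigmoidal profile; elsewhere they take their type's base
    value.
    """
    cc = coupling or CouplingConfig()
    for name in ("R_SAN", "R_fib", "R_RA"):
        if getattr(cc, name) <= 0:
            raise ValueError(f"{name} must be > 0")
    tm = geometry.type_map
    g = np.zeros(tm.shape, dtype=float)
    g[tm == SAN] = 1.0 / cc.R_SAN
    g[tm == ATRIAL] = 1.0 / cc.R_RA
    g[tm == FIBROBLAST] = 1.0 / cc.R_fib

    for s in geometry.seps:
        mid_col = s.center_col + cc.center_offset
        # corridor: pathway rows, from inside the SAN to the exit face
        for r in range(s.row0, s.row1):
            for c in range(0, s.col_exit):
                if tm[r, c] in (SAN, ATRIAL):
                    x = mid_col - c          # into-the-SAN axis
                    val = sigmoid_profile(x, cc.R_SAN, cc.R_RA, cc.alpha,
                                          0.0)
                    if tm[r, c] == SAN:
                        g[r, c] = max(val, 1.0 / cc.R_SAN)
                    else:
                        g[r, c] = val
        # semicircular halo beyond the exit
        rc = s.center_row
        r0 = max(0, int(rc - cc.halo_radius) - 1)
        r1 = min(tm.shape[0], int(rc + cc.halo_radius) + 2)
        c1 = min(tm.shape[1], int(s.col_exit + cc.halo_radius) + 2)
        for r in range(r0, r1):
            for c in range(s.col_exit, c1):
                if tm[r, c] != ATRIAL:
                    continue
                dist = np.hypot(r - rc, c - s.col_exit)
                if dist > cc.halo_radius:
                    continue
                x = mid_col - (s.col_exit + dist)
                val = sigmoid_profile(x, cc.R_SAN, cc.R_RA, cc.alpha, 0.0)
                g[r, c] = min(g[r, c], val) if g[r, c] > 0 else val
    g[tm == INSULATOR] = 0.0
    return CouplingMap(cc, g)


# ---------------------------------------------------------------------------
# presets and setup factory
# ---------------------------------------------------------------------------

def full_preset(sep_width: int = 11, mosaic: bool = False) -> GeometryConfig:
    """The study's full-scale layout (200 x 200 cells, five pathways)."""
    return GeometryConfig(sep_width=sep_width, mosaic=mosaic)


def strip_preset(sep_width: int = 11, mosaic: bool = False) -> GeometryConfig:
    """Desk-scale strip: a reduced SAN ellipse, one exit pathway of full
    length, and an atrial field deep enough to act as a realistic sink."""
    return GeometryConfig(
        nrows=42, ncols=80, center=(21, 14), semi_major=15, semi_minor=11,
        n_seps=1, sep_length=20, sep_width=sep_width, border=2,
        mosaic=mosaic,
    )


def half_preset(sep_width: int = 11, mosaic: bool = False) -> GeometryConfig:
    """Half-scale ellipse with all five pathways (full-length channels)."""
    return GeometryConfig(
        nrows=100, ncols=110, center=(50, 40), semi_major=37, semi_minor=8,
        n_seps=5, sep_length=20, sep_width=sep_width, border=2,
        sep_span_frac=0.8, mosaic=mosaic,
    )


SETUPS = ("U", "H", "UF", "HF")


def build_setup(setup: str, seed: int = 1,
                config: GeometryConfig | None = None,
                sigma: float = 0.2):
    """U/H/UF/HF factory: U = uniform, H = heterogeneity only, UF =
    fibroblasts only, HF = both.  Returns (geometry, heterogeneity|None)."""
    if setup not in SETUPS:
        raise ValueError(f"setup must be one of {SETUPS}")
    cfg = config or full_preset()
    geom = build_geometry(cfg, seed=seed)
    if setup in ("UF", "HF"):
        geom = place_fibroblasts(geom, seed=seed)
    het = None
    if setup in ("H", "HF"):
        het = sample_heterogeneity(geom, seed=seed, sigma=sigma)
    return geom, het


# ---------------------------------------------------------------------------
# serialization / plotting
# ---------------------------------------------------------------------------

def save_geometry(path, geometry: TissueGeometry,
                  coupling: CouplingMap | None = None):
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("type_map", data=geometry.type_map)
        cfg = geometry.config
        for k, v in cfg.__dict__.items():
            f.attrs[k] = v
        sep_arr = np.array([[s.sep_id, s.row0, s.row1, s.col_start,
                             s.col_exit, s.center_row] for s in geometry.seps],
                           dtype=np.int64)
        f.create_dataset("seps", data=sep_arr)
        if coupling is not None:
            d = f.create_dataset("g_cell", data=coupling.g_cell)
            for k, v in coupling.config.__dict__.items():
                d.attrs[k] = v


def load_geometry(path):
    import h5py

    with h5py.File(path, "r") as f:
        attrs = dict(f.attrs)
        attrs["center"] = tuple(int(x) for x in attrs["center"])
        for key in ("nrows", "ncols", "n_seps", "sep_length", "sep_width",
                    "border", "semi_major", "semi_minor"):
            attrs[key] = int(attrs[key])
        attrs["mosaic"] = bool(attrs["mosaic"])
        cfg = GeometryConfig(**attrs)
        tm = f["type_map"][...]
        seps = [SepInfo(int(a), int(b), int(c), int(d), int(e), int(fr),
                        d + cfg.sep_length / 2.0 - 0.5)
                for a, b, c, d, e, fr in f["seps"][...]]
        coupling = None
        if "g_cell" in f:
            cattrs = dict(f["g_cell"].attrs)
            coupling = CouplingMap(CouplingConfig(**cattrs), f["g_cell"][...])
    geom = TissueGeometry(cfg, tm, seps)
    return (geom, coupling) if coupling is not None else (geom, None)


def plot_maps(geometry: TissueGeometry, coupling: CouplingMap | None = None,
              path=None):
    """Type map (and log10 conductance map) figure; returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ncol = 2 if coupling is not None else 1
    fig, axes = plt.subplots(1, ncol, figsize=(5 * ncol, 5), squeeze=False)
    ax = axes[0, 0]
    im = ax.imshow(geometry.type_map, interpolation="nearest", cmap="viridis")
    ax.set_title("cell types (0 SAN, 1 atrial, 2 fibroblast, 3 insulator)")
    fig.colorbar(im, ax=ax, shrink=0.7)
    if coupling is not None:
        ax = axes[0, 1]
        with np.errstate(divide="ignore"):
            logg = np.log10(np.where(coupling.g_cell > 0, coupling.g_cell,
                                     np.nan))
        im = ax.imshow(logg, interpolation="nearest", cmap="magma")
        ax.set_title("log10 coupling conductance (uS)")
        fig.colorbar(im, ax=ax, shrink=0.7)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
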