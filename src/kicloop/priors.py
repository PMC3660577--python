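"""Ramachandran torsion priors, torsion-bin classification and omega sampling.

The bundled phi/psi tables are SYNTHETIC: per residue class (general, glycine,
proline, pre-proline) a mixture of 2-3 wrapped bivariate Gaussians centred on
the canonical basins, rasterised on a 5 degree grid
(fine enough that the cell-constant energy does not flatten sub-Angstrom
differences).  They reproduce the
qualitative shape of residue-specific Ramachandran preferences — not the
statistics of any curated structural database — and exist so that the sampling
machinery can be exercised and tested end to end.  Real tables in the same
plain-text format can be substituted via :func:`load_table`.

Neighbour-dependent ("rama2b") tables are derived from the base table by a
deterministic neighbour-class-dependent reweighting, one grid per
(class, neighbour class, side) with side in {left, right}.

Torsion bins follow the four-letter alphabet used for taboo bookkeeping:

    A: phi <= 0 and -130 <= psi <= 50
    B: phi <= 0 and (psi < -130 or psi > 50)
    E: phi >  0 and (psi < -90 or psi > 90)
    G: phi >  0 and -90 <= psi <= 90

Omega is trans-planar by default; in sampled mode it is drawn from a Gaussian
with mean 179.1 and sd 6.3 degrees, and for pre-prolines a cis value
(Gaussian around 0, same sd) is drawn at a rate of 1 in 10,000.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import normalize_angle

logger = logging.getLogger(__name__)

BINS = "ABEG"

OMEGA_TRANS_MEAN = 179.1
OMEGA_SD = 6.3
CIS_RATE = 1.0 / 10_000.0
RAMA_EPS = 1e-8

GRID_RESOLUTION = 5  # degrees per cell; bin boundaries lie on cell edges
NCELL = 360 // GRID_RESOLUTION

#: residue classes with their own phi/psi grid
CLASSES = ("general", "glycine", "proline", "prepro")
NEIGHBOR_CLASSES = ("general", "glycine", "proline")
SIDES = ("left", "right")


def classify_bin(phi: float, psi: float) -> str:
    """Torsion bin (A, B, E or G) for angles in degrees, normalised to
    (-180, 180].  The four conditions partition the whole torus."""
    phi = float(normalize_angle(phi))
    psi = float(normalize_angle(psi))
    if phi <= 0.0:
        return "A" if -130.0 <= psi <= 50.0 else "B"
    return "E" if (psi < -90.0 or psi > 90.0) else "G"


def residue_class(aa: str, next_aa: str | None = None) -> str:
    """Residue class used for table lookup; a residue preceding a proline
    uses the pre-proline table unless it is itself glycine or proline."""
    aa = aa.upper()
    if aa == "G":
        return "glycine"
    if aa == "P":
        return "proline"
    if next_aa is not None and next_aa.upper() == "P":
        return "prepro"
    return "general"


def neighbor_class(aa: str | None) -> str | None:
    if aa is None:
        return None
    aa = aa.upper()
    return {"G": "glycine", "P": "proline"}.get(aa, "general")


def _cell_centers():
    edges = np.arange(-180.0, 180.1, GRID_RESOLUTION)
    return (edges[:-1] + edges[1:]) / 2.0


def _wrapped_gaussian_grid(components) -> np.ndarray:
    """Rasterise a mixture of wrapped 2-D Gaussians onto the grid.

    ``components``: iterable of (weight, mu_phi, mu_psi, sd_phi, sd_psi).
    """
    centers = _cell_centers()
    P, S = np.meshgrid(centers, centers, indexing="ij")  # phi rows, psi cols
    grid = np.zeros_like(P)
    for w, mp, ms, sp, ss in components:
        for dp in (-360.0, 0.0, 360.0):
            for ds in (-360.0, 0.0, 360.0):
                grid += w * np.exp(
                    -0.5 * (((P - mp + dp) / sp) ** 2 + ((S - ms + ds) / ss) ** 2)
                )
    return grid / grid.sum()


# mixture definitions: canonical alpha, beta, left-handed-alpha and sparse
# epsilon basins; weights/spreads chosen to caricature each residue class.
_MIXTURES = {
    "general": [
        (0.50, -63.0, -43.0, 9.0, 10.0),   # alpha (bin A)
        (0.40, -120.0, 135.0, 12.0, 12.0),  # beta (bin B)
        (0.08, 58.0, 42.0, 9.0, 9.0),       # alpha-L (bin G)
        (0.02, 70.0, 170.0, 12.0, 12.0),    # epsilon (bin E)
    ],
    "glycine": [
        (0.30, -70.0, -35.0, 13.0, 13.0),
        (0.28, -110.0, 150.0, 14.0, 14.0),
        (0.30, 70.0, 35.0, 13.0, 13.0),
        (0.12, 85.0, -170.0, 13.0, 13.0),
    ],
    "proline": [
        (0.55, -63.0, -35.0, 7.0, 9.0),
        (0.45, -63.0, 145.0, 7.0, 10.0),
    ],
    "prepro": [
        (0.38, -63.0, -43.0, 9.0, 10.0),
        (0.52, -125.0, 140.0, 11.0, 11.0),
        (0.10, 55.0, 40.0, 9.0, 9.0),
    ],
}


def bin_grid_labels() -> np.ndarray:
    """(NCELL, NCELL) array of bin letters, one per (phi, psi) cell.  Bin
    boundaries coincide with cell edges at 5 degree resolution, so every
    cell lies wholly in one bin."""
    centers = _cell_centers()
    out = np.empty((NCELL, NCELL), dtype="U1")
    for i, p in enumerate(centers):
        for j, s in enumerate(centers):
            out[i, j] = classify_bin(p, s)
    return out


_BIN_LABELS = None


def _labels() -> np.ndarray:
    global _BIN_LABELS
    if _BIN_LABELS is None:
        _BIN_LABELS = bin_grid_labels()
    return _BIN_LABELS


@dataclass
class RamaTable:
    """Per-class phi/psi probability grids at 5 degree resolution."""

    grids: dict = field(default_factory=dict)
    resolution: int = GRID_RESOLUTION

    def __post_init__(self):
        for name, g in self.grids.items():
            if g.shape != (NCELL, NCELL):
                raise ValueError(f"grid {name} has shape {g.shape}")
            if np.any(g < 0):
                raise ValueError(f"grid {name} has negative mass")
            self.grids[name] = g / g.sum()
        self._cdfs: dict = {}

    def grid(self, cls: str) -> np.ndarray:
        if cls not in self.grids:
            raise KeyError(f"no Ramachandran table for residue class {cls!r}")
        return self.grids[cls]

    def cdf(self, cls: str) -> np.ndarray:
        if cls not in self._cdfs:
            self._cdfs[cls] = np.cumsum(self.grid(cls).ravel())
        return self._cdfs[cls]

    def bin_cdf(self, cls: str, bin_: str) -> np.ndarray:
        """Cumulative distribution of the grid renormalised to one bin."""
        key = (cls, bin_)
        if key not in self._cdfs:
            g = self.grid(cls).copy()
            g[_labels() != bin_] = 0.0
            total = g.sum()
            if total <= 0.0:
                raise ValueError(
                    f"torsion bin {bin_} has zero mass for class {cls}")
            self._cdfs[key] = np.cumsum(g.ravel() / total)
        return self._cdfs[key]


@dataclass
class Rama2bTable:
    """Neighbour-dependent grids keyed by (class, neighbour class, side)."""

    grids: dict = field(default_factory=dict)
    resolution: int = GRID_RESOLUTION

    def __post_init__(self):
        self._cdfs: dict = {}

    def grid(self, cls: str, nb_cls: str, side: str) -> np.ndarray:
        return self.grids[(cls, nb_cls, side)]

    def has(self, cls: str, nb_cls: str, side: str) -> bool:
        return (cls, nb_cls, side) in self.grids

    def cdf(self, cls: str, nb_cls: str, side: str) -> np.ndarray:
        key = (cls, nb_cls, side)
        if key not in self._cdfs:
            self._cdfs[key] = np.cumsum(self.grids[key].ravel())
        return self._cdfs[key]


@dataclass
class Tables:
    """Bundle of the standard and neighbour-dependent tables."""

    rama: RamaTable
    rama2b: Rama2bTable


def _neighbor_tilt(base: np.ndarray, nb_cls: str, side: str) -> np.ndarray:
    """Deterministic reweighting of a base grid by neighbour identity.

    Glycine neighbours flatten the distribution, proline neighbours push mass
    towards the beta basin (more strongly from the right/following side),
    general neighbours tilt mildly.  Purely synthetic, but smooth, positive
    and side-asymmetric so the left/right machinery is exercised.
    """
    centers = _cell_centers()
    P, S = np.meshgrid(centers, centers, indexing="ij")
    sgn = 1.0 if side == "right" else -1.0
    if nb_cls == "glycine":
        tilt = np.exp(0.15 * sgn * np.cos(np.radians(P)))
        out = (base ** 0.8) * tilt
    elif nb_cls == "proline":
        k = 0.8 if side == "right" else 0.4
        tilt = np.exp(k * np.cos(np.radians(S - 140.0)))
        out = base * tilt
    else:
        tilt = np.exp(0.1 * sgn * np.sin(np.radians(S)))
        out = base * tilt
    return out / out.sum()


def default_tables() -> Tables:
    """The bundled synthetic tables (built deterministically, cached)."""
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        rama = RamaTable({c: _wrapped_gaussian_grid(_MIXTURES[c]) for c in CLASSES})
        grids2b = {}
        for cls in CLASSES:
            for nb in NEIGHBOR_CLASSES:
                for side in SIDES:
                    grids2b[(cls, nb, side)] = _neighbor_tilt(
                        rama.grid(cls), nb, side
                    )
        _DEFAULT_TABLES = Tables(rama=rama, rama2b=Rama2bTable(grids2b))
    return _DEFAULT_TABLES


_DEFAULT_TABLES = None


# ---------------------------------------------------------------------------
# sampling and lookups

def _cell_index(angle: float) -> int:
    idx = int((normalize_angle(angle) + 180.0) // GRID_RESOLUTION)
    return min(idx, NCELL - 1)  # angle == +180 folds into the last cell


def cell_of(phi: float, psi: float) -> tuple:
    return _cell_index(phi), _cell_index(psi)


def _draw_from_cdf(cdf: np.ndarray, rng: np.random.Generator) -> tuple:
    """Cell-proportional draw, uniform within the chosen cell."""
    flat = int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))
    flat = min(flat, cdf.size - 1)
    i, j = divmod(flat, NCELL)
    phi = -180.0 + (i + rng.random()) * GRID_RESOLUTION
    psi = -180.0 + (j + rng.random()) * GRID_RESOLUTION
    return float(normalize_angle(phi)), float(normalize_angle(psi))


def _draw_from_grid(grid: np.ndarray, rng: np.random.Generator) -> tuple:
    return _draw_from_cdf(np.cumsum(grid.ravel()), rng)


def sample_phi_psi(aa: str, tables: Tables, rng: np.random.Generator,
                   next_aa: str | None = None) -> tuple:
    """Draw (phi, psi) from the residue-specific standard table."""
    return _draw_from_cdf(tables.rama.cdf(residue_class(aa, next_aa)), rng)


def sample_phi_psi_rama2b(aa: str, left_aa: str | None, right_aa: str | None,
                          tables: Tables, rng: np.random.Generator,
                          next_aa: str | None = None) -> tuple:
    """Neighbour-dependent draw: one side chosen at random with probability
    1/2; a chain terminus (missing neighbour) forces the other side; if no
    neighbour entry exists at all, falls back to the standard table with a
    logged warning."""
    cls = residue_class(aa, next_aa)
    options = []
    if left_aa is not None and tables.rama2b.has(cls, neighbor_class(left_aa), "left"):
        options.append(("left", neighbor_class(left_aa)))
    if right_aa is not None and tables.rama2b.has(cls, neighbor_class(right_aa), "right"):
        options.append(("right", neighbor_class(right_aa)))
    if not options:
        logger.warning("no rama2b entry for %s (neighbours %s/%s); "
                       "falling back to standard table", aa, left_aa, right_aa)
        return sample_phi_psi(aa, tables, rng, next_aa)
    side, nb = options[rng.integers(len(options))] if len(options) == 2 \
        else options[0]
    return _draw_from_cdf(tables.rama2b.cdf(cls, nb, side), rng)


def _bin_mass(grid: np.ndarray, bin_: str) -> float:
    return float(grid[_labels() == bin_].sum())


def bin_probability(aa: str, bin_: str, tables: Tables, mode: str = "standard",
                    left_aa: str | None = None, right_aa: str | None = None,
                    next_aa: str | None = None) -> float:
    """Prior probability of a torsion bin for a residue.

    Standard mode sums the table mass inside the bin.  Rama2b mode integrates
    the two neighbours by taking the minimum of the left-side and right-side
    bin masses; a missing neighbour contributes the standard-table mass.
    """
    if bin_ not in BINS:
        raise ValueError(f"unknown torsion bin {bin_!r}")
    cls = residue_class(aa, next_aa)
    if mode == "standard":
        return _bin_mass(tables.rama.grid(cls), bin_)
    if mode == "rama2b":
        masses = []
        for side, nb_aa in (("left", left_aa), ("right", right_aa)):
            if nb_aa is None:
                masses.append(_bin_mass(tables.rama.grid(cls), bin_))
            else:
                masses.append(
                    _bin_mass(tables.rama2b.grid(cls, neighbor_class(nb_aa), side), bin_)
                )
        return min(masses)
    raise ValueError(f"unknown mode {mode!r}")


def sample_bin_restricted(aa: str, bin_: str, tables: Tables,
                          rng: np.random.Generator,
                          next_aa: str | None = None) -> tuple:
    """Draw (phi, psi) from the table renormalised to one torsion bin.

    The draw always re-classifies to the requested bin; a bin with zero mass
    for the residue class raises ``ValueError``.
    """
    cls = residue_class(aa, next_aa)
    try:
        cdf = tables.rama.bin_cdf(cls, bin_)
    except ValueError as err:
        raise ValueError(f"{err} (aa {aa})") from None
    while True:  # cell edges sit exactly on bin boundaries; redraw the
        phi, psi = _draw_from_cdf(cdf, rng)  # measure-zero edge hits
        if classify_bin(phi, psi) == bin_:
            return phi, psi


def sample_omega(is_pre_proline: bool, mode: str, rng: np.random.Generator) -> float:
    """One omega draw in degrees.

    planar mode: exactly 180.  sampled mode: Gaussian(179.1, 6.3) wrapped to
    (-180, 180]; for pre-prolines a cis value Gaussian(0, 6.3) is returned
    with probability 1/10,000.
    """
    if mode == "planar":
        return 180.0
    if mode != "sampled":
        raise ValueError(f"unknown omega mode {mode!r}")
    if is_pre_proline and rng.random() < CIS_RATE:
        return float(normalize_angle(rng.normal(0.0, OMEGA_SD)))
    return float(normalize_angle(rng.normal(OMEGA_TRANS_MEAN, OMEGA_SD)))


def phi_psi_probability(aa: str, phi: float, psi: float, tables: Tables,
                        mode: str = "standard", left_aa: str | None = None,
                        right_aa: str | None = None,
                        next_aa: str | None = None) -> float:
    """Probability mass of the grid cell containing (phi, psi); rama2b mode
    takes the minimum over the two neighbour-side grids (consistent with the
    bin-integration rule)."""
    cls = residue_class(aa, next_aa)
    i, j = cell_of(phi, psi)
    if mode == "standard":
        return float(tables.rama.grid(cls)[i, j])
    ps = []
    for side, nb_aa in (("left", left_aa), ("right", right_aa)):
        if nb_aa is None:
            ps.append(float(tables.rama.grid(cls)[i, j]))
        else:
            ps.append(float(tables.rama2b.grid(cls, neighbor_class(nb_aa), side)[i, j]))
    return min(ps)


def rama_energy(aa: str, phi: float, psi: float, tables: Tables,
                mode: str = "standard", left_aa: str | None = None,
                right_aa: str | None = None, next_aa: str | None = None) -> float:
    """-log(cell probability + eps): lower is more favourable."""
    p = phi_psi_probability(aa, phi, psi, tables, mode, left_aa, right_aa, next_aa)
    return float(-np.log(p + RAMA_EPS))


# ---------------------------------------------------------------------------
# plain-text table I/O: "class phi_index psi_index probability" per line

def save_table(table: RamaTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# resolution {table.resolution}\n")
        for cls, grid in sorted(table.grids.items()):
            for i in range(NCELL):
                for j in range(NCELL):
                    if grid[i, j] > 0:
                        fh.write(f"{cls} {i} {j} {grid[i, j]:.10e}\n")


def load_table(path) -> RamaTable:
    grids: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cls, i, j, p = line.split()
            grids.setdefault(cls, np.zeros((NCELL, NCELL)))[int(i), int(j)] = float(p)
    return RamaTable(grids)
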