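"""Methyl-probe energy grid over a protein chain.

The chain is boxed in an axis-aligned cubic grid (0.9 Å resolution by
default, padded so the probe's favourable shell around the surface is
covered).  At each grid point a united-atom methyl (-CH3) probe is placed
and its van der Waals interaction energy with every protein heavy atom is
accumulated with a 12-6 Lennard-Jones potential::

    E_ij(r) = eps_ij * [ (rmin_ij / r)**12 - 2 * (rmin_ij / r)**6 ]

with Lorentz–Berthelot combination (geometric-mean eps, summed rmin
halves), an 8 Å cutoff beyond which a pair contributes nothing, and a hard
clamp at +1000 kcal/mol inside atomic cores.  The pair minimum is exactly
-eps_ij at r = rmin_ij.

Grid points with energy more favourable (more negative) than a threshold
are retained; clamping guarantees points buried in the protein interior are
never retained, which restricts prediction to the molecular surface.
Retained points are then given residue-propensity scores: every protein
atom within 1.6 Å of a grid point contributes its per-atom scale score, and
the three per-scale scores are combined into an overall binding propensity
as a weighted sum of per-scale z-scores (standardised over the retained
points so the differently-scaled quantities are commensurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._data import load_columns
from .pdb_io import AtomRecord, Chain
from .scales import PropensityTable

DEFAULT_SPACING = 0.9  # Å, grid resolution
DEFAULT_PADDING = 4.5  # Å, box margin around the atom bounding box
DEFAULT_CUTOFF = 8.0  # Å, nonbonded cutoff
DEFAULT_PROPENSITY_RADIUS = 1.6  # Å, atom-to-grid-point contact radius
ENERGY_CLAMP = 1.0e3  # kcal/mol, core repulsion clamp

#: Default orientation-aligned weights for combining the three standardised
#: propensities: RIP grows toward interfaces while the Hessa ϕ and
#: Wimley–White ΔG free energies *decrease* toward hydrophobic,
#: interface-prone composition, hence the negative signs.
DEFAULT_WEIGHTS = {"rip": 1.0, "hydrophobicity": -1.0, "solvation": -1.0}


class ProbeParams:
    """Lennard-Jones parameters for the methyl probe against each element.

    Loaded from a ``atom<TAB>epsilon<TAB>rmin_half`` TSV containing a
    ``PROBE`` row for the methyl probe itself; pairwise parameters follow
    Lorentz–Berthelot combination.
    """

    def __init__(self, table: Mapping[str, tuple[float, float]] | None = None):
        if table is None:
            table = load_columns("methyl_probe_lj.tsv", 2)
        table = {k.upper(): (float(e), float(r)) for k, (e, r) in table.items()}
        if "PROBE" not in table:
            raise ValueError("probe parameter table must contain a PROBE row")
        for name, (eps, rmin) in table.items():
            if eps <= 0 or rmin <= 0:
                raise ValueError(f"non-positive LJ parameter for {name!r}")
        self._probe = table.pop("PROBE")
        self._elements = table

    @classmethod
    def from_file(cls, path: str | Path) -> "ProbeParams":
        return cls(load_columns(path, 2, packaged=False))

    def covers(self, element: str) -> bool:
        return element.upper() in self._elements

    def pair(self, element: str) -> tuple[float, float]:
        """(eps_ij, rmin_ij) of the probe against *element*."""
        try:
            eps, rmin = self._elements[element.upper()]
        except KeyError:
            raise KeyError(f"no probe LJ parameters for element {element!r}") from None
        return math.sqrt(self._probe[0] * eps), self._probe[1] + rmin

    def pair_arrays(self, elements: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        pairs = [self.pair(e) for e in elements]
        eps = np.array([p[0] for p in pairs])
        rmin = np.array([p[1] for p in pairs])
        return eps, rmin


@dataclass(frozen=True)
class GridMap:
    """Axis-aligned cubic grid covering a chain plus padding."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]
    padding: float

    @property
    def n_points(self) -> int:
        return self.dims[0] * self.dims[1] * self.dims[2]

    def indices(self) -> np.ndarray:
        """(N, 3) integer lattice indices in C order."""
        nx, ny, nz = self.dims
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        return np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])

    def points(self) -> np.ndarray:
        """(N, 3) Cartesian coordinates of every grid point."""
        return np.asarray(self.origin) + self.indices() * self.spacing

    def linear_index(self, index: tuple[int, int, int]) -> int:
        i, j, k = index
        return (i * self.dims[1] + j) * self.dims[2] + k


@dataclass(frozen=True)
class GridPoint:
    """One retained grid point with its energy and propensity scores."""

    index: tuple[int, int, int]
    coords: tuple[float, float, float]
    energy: float
    rip_score: float = 0.0
    hydro_score: float = 0.0
    solv_score: float = 0.0
    overall_propensity: float = 0.0

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords)


def build_grid(
    chain: Chain, spacing: float = DEFAULT_SPACING, padding: float = DEFAULT_PADDING
) -> GridMap:
    """Cubic grid over the chain's atom bounding box expanded by *padding*."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    xyz = chain.coords_array()
    if xyz.size == 0:
        raise ValueError("cannot grid an empty chain")
    lo = xyz.min(axis=0) - padding
    hi = xyz.max(axis=0) + padding
    dims = tuple(int(math.floor((h - l) / spacing + 1e-9)) + 1 for l, h in zip(lo, hi))
    return GridMap(tuple(float(v) for v in lo), spacing, dims, padding)


def _lj_pair_energy(r: np.ndarray, eps: np.ndarray, rmin: np.ndarray) -> np.ndarray:
    r = np.maximum(r, 1e-3)  # guard exact overlap; clamp dominates anyway
    q = (rmin / r) ** 6
    return np.minimum(eps * (q * q - 2.0 * q), ENERGY_CLAMP)


def probe_energy(
    point_coords: Sequence[float],
    atoms: Sequence[AtomRecord],
    params: ProbeParams,
    cutoff: float = DEFAULT_CUTOFF,
) -> float:
    """Probe-vs-protein vdW energy at one point (reference scalar form)."""
    total = 0.0
    point = np.asarray(point_coords, dtype=float)
    for atom in atoms:
        r = float(np.linalg.norm(atom.xyz - point))
        if r >= cutoff:
            continue
        eps, rmin = params.pair(atom.element)
        total += float(_lj_pair_energy(np.array(r), np.array(eps), np.array(rmin)))
    return float(min(total, ENERGY_CLAMP))


def energy_field(
    grid: GridMap,
    chain: Chain,
    params: ProbeParams,
    cutoff: float = DEFAULT_CUTOFF,
    chunk: int = 4096,
) -> np.ndarray:
    """Probe energies at every grid point (flat array, C order).

    Vectorised over point chunks; exact pair distances, the same cutoff and
    clamp as :func:`probe_energy`.
    """
    atoms = chain.atoms
    xyz = chain.coords_array()
    eps, rmin = params.pair_arrays([a.element for a in atoms])
    points = grid.points()
    energies = np.zeros(len(points))
    for start in range(0, len(points), chunk):
        block = points[start : start + chunk]
        d = np.linalg.norm(block[:, None, :] - xyz[None, :, :], axis=2)
        e = _lj_pair_energy(d, eps[None, :], rmin[None, :])
        e[d >= cutoff] = 0.0
        energies[start : start + chunk] = np.minimum(e.sum(axis=1), ENERGY_CLAMP)
    return energies


def retain_favorable(
    grid: GridMap,
    energies: np.ndarray,
    threshold: float,
) -> list[GridPoint]:
    """Grid points with energy strictly below a (negative) threshold."""
    if threshold >= 0:
        raise ValueError("threshold must be negative (favourable energies)")
    keep = np.flatnonzero(energies < threshold)
    indices = grid.indices()[keep]
    coords = np.asarray(grid.origin) + indices * grid.spacing
    return [
        GridPoint(tuple(int(v) for v in idx), tuple(float(v) for v in pt), float(e))
        for idx, pt, e in zip(indices, coords, energies[keep])
    ]


def grid_point_propensity(
    point_coords: Sequence[float],
    chain: Chain,
    table: PropensityTable,
    radius: float = DEFAULT_PROPENSITY_RADIUS,
) -> float:
    """Sum of per-atom scale scores of chain atoms within *radius* of the
    point (0 when no atom is that close)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    point = np.asarray(point_coords, dtype=float)
    total = 0.0
    for atom in chain.atoms:
        if not atom.is_standard:
            continue
        if np.linalg.norm(atom.xyz - point) <= radius:
            total += table.per_atom_score(atom.residue_type)
    return total


def propensity_fields(
    points: Sequence[GridPoint],
    chain: Chain,
    tables: Mapping[str, PropensityTable],
    radius: float = DEFAULT_PROPENSITY_RADIUS,
) -> dict[str, np.ndarray]:
    """Per-scale propensity of each retained point (vectorised neighbour
    scan; identical to :func:`grid_point_propensity` per point)."""
    atoms = [a for a in chain.atoms if a.is_standard]
    result = {name: np.zeros(len(points)) for name in tables}
    if not points or not atoms:
        return result
    pts = np.array([p.coords for p in points])
    per_atom = {
        name: np.array([t.per_atom_score(a.residue_type) for a in atoms])
        for name, t in tables.items()
    }
    tree = cKDTree(np.array([a.coords for a in atoms]))
    neighborhoods = tree.query_ball_point(pts, r=radius)
    for i, js in enumerate(neighborhoods):
        if js:
            for name in tables:
                result[name][i] = per_atom[name][js].sum()
    return result


def standardize(values: np.ndarray) -> np.ndarray:
    """Z-score over the retained points; all-equal input maps to zeros."""
    sd = float(np.std(values))
    if sd == 0.0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def overall_propensity(
    rip: np.ndarray,
    hydro: np.ndarray,
    solv: np.ndarray,
    weights: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Combined binding propensity: weighted sum of standardised scores."""
    w = DEFAULT_WEIGHTS if weights is None else weights
    return (
        w.get("rip", 0.0) * standardize(np.asarray(rip, dtype=float))
        + w.get("hydrophobicity", 0.0) * standardize(np.asarray(hydro, dtype=float))
        + w.get("solvation", 0.0) * standardize(np.asarray(solv, dtype=float))
    )


def score_points(
    points: Sequence[GridPoint],
    chain: Chain,
    tables: Mapping[str, PropensityTable],
    radius: float = DEFAULT_PROPENSITY_RADIUS,
    weights: Mapping[str, float] | None = None,
) -> list[GridPoint]:
    """Attach per-scale and overall propensities to retained grid points."""
    fields = propensity_fields(points, chain, tables, radius)
    overall = overall_propensity(
        fields["rip"], fields["hydrophobicity"], fields["solvation"], weights
    )
    return [
        GridPoint(
            p.index,
            p.coords,
            p.energy,
            rip_score=float(fields["rip"][i]),
            hydro_score=float(fields["hydrophobicity"][i]),
            solv_score=float(fields["solvation"][i]),
            overall_propensity=float(overall[i]),
        )
        for i, p in enumerate(points)
    ]
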