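"""Candidate interaction sites: clustering, ranking and evaluation.

Retained grid points are grouped by single-linkage spatial proximity
(connected components at a linkage cutoff; on a cubic grid the default
cutoff of spacing·√3 connects the 26-neighbourhood).  At most 15 clusters
are kept — the largest ones, ties broken toward lower total probe energy —
and each cluster becomes a candidate PPI site.  A site's atoms are the
protein atoms occluded by its grid points (within the 1.6 Å propensity
radius of any member point).

Predicted sites are compared against an actual interacting patch with the
site score Ƭ, a precision/coverage combination over atom sets::

    p = |P ∩ A| / |P|,   c = |P ∩ A| / |A|,   Ƭ = 2pc / (p + c)

(harmonic mean by default; ``min(p, c)`` is available as an alternative).
A prediction with Ƭ ≥ 0.25 counts as correct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .gridprobe import DEFAULT_PROPENSITY_RADIUS, DEFAULT_SPACING, GridPoint
from .interface import Patch
from .pdb_io import AtomRecord, Chain
from .scales import PatchScores, PropensityTable, patch_scores

DEFAULT_MAX_CLUSTERS = 15
DEFAULT_TAU_MIN = 0.25


def default_linkage_cutoff(spacing: float = DEFAULT_SPACING) -> float:
    """26-connectivity on a cubic grid: spacing·√3 plus a tiny guard."""
    return spacing * math.sqrt(3.0) + 1e-9


@dataclass(frozen=True)
class Cluster:
    """A connected set of retained grid points."""

    points: tuple[GridPoint, ...]

    def __len__(self) -> int:
        return len(self.points)

    @property
    def total_energy(self) -> float:
        return sum(p.energy for p in self.points)

    @property
    def total_propensity(self) -> float:
        return sum(p.overall_propensity for p in self.points)

    def min_index(self, dims_hint: int = 10**6) -> tuple[int, ...]:
        return min(p.index for p in self.points)


@dataclass
class PredictedSite:
    """A ranked candidate PPI site with its cumulative scores."""

    rank: int
    grid_points: tuple[GridPoint, ...]
    site_atoms: tuple[AtomRecord, ...]
    cumulative_scores: PatchScores
    total_energy: float
    total_propensity: float
    tau: float | None = None

    @property
    def atom_keys(self) -> frozenset:
        return frozenset(a.key for a in self.site_atoms)


def cluster_points(
    points: Sequence[GridPoint],
    max_clusters: int = DEFAULT_MAX_CLUSTERS,
    linkage_cutoff: float | None = None,
) -> list[Cluster]:
    """Single-linkage connected components of the retained points.

    If more than *max_clusters* components exist, the largest are kept
    (ties toward lower total energy, then lowest member grid index).  Every
    retained point belongs to at most one cluster.
    """
    points = list(points)
    if not points:
        return []
    if linkage_cutoff is None:
        linkage_cutoff = default_linkage_cutoff()
    xyz = np.array([p.coords for p in points])
    pairs = cKDTree(xyz).query_pairs(r=linkage_cutoff, output_type="ndarray")
    n = len(points)
    if len(pairs):
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        adj = coo_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=False)
    clusters = [
        Cluster(tuple(points[i] for i in np.flatnonzero(labels == c)))
        for c in range(n_comp)
    ]
    clusters.sort(key=lambda cl: (-len(cl), cl.total_energy, cl.min_index()))
    return clusters[:max_clusters]


def site_atoms(
    cluster: Cluster,
    chain: Chain,
    radius: float = DEFAULT_PROPENSITY_RADIUS,
) -> tuple[AtomRecord, ...]:
    """Chain atoms within *radius* of any member grid point (deduplicated,
    ordered by serial)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    atoms = [a for a in chain.atoms if a.is_standard]
    if not atoms or not cluster.points:
        return ()
    tree = cKDTree(np.array([a.coords for a in atoms]))
    hit: set[int] = set()
    for js in tree.query_ball_point(np.array([p.coords for p in cluster.points]), r=radius):
        hit.update(js)
    return tuple(sorted((atoms[j] for j in hit), key=lambda a: a.serial))


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = float(np.std(values))
    if sd == 0.0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def rank_sites(
    clusters: Sequence[Cluster],
    chain: Chain,
    tables: Mapping[str, PropensityTable],
    radius: float = DEFAULT_PROPENSITY_RADIUS,
) -> list[PredictedSite]:
    """Turn clusters into ranked candidate sites.

    Ranking is by the sum of two z-scores computed across the candidate
    clusters: cumulative overall propensity and probe-energy magnitude
    |total energy| (both extensive, favouring strong, high-propensity
    pockets).  Ties break deterministically by cluster size, then lowest
    member grid index.
    """
    if not clusters:
        return []
    sites: list[tuple[Cluster, tuple[AtomRecord, ...], PatchScores]] = []
    for cl in clusters:
        atoms = site_atoms(cl, chain, radius)
        scores = patch_scores(Patch(chain.chain_id, atoms), tables)
        sites.append((cl, atoms, scores))

    prop = _standardize(np.array([cl.total_propensity for cl, _, _ in sites]))
    emag = _standardize(np.array([abs(cl.total_energy) for cl, _, _ in sites]))
    combined = prop + emag
    order = sorted(
        range(len(sites)),
        key=lambda i: (-combined[i], -len(sites[i][0]), sites[i][0].min_index()),
    )
    ranked = []
    for rank, i in enumerate(order, start=1):
        cl, atoms, scores = sites[i]
        ranked.append(
            PredictedSite(
                rank=rank,
                grid_points=cl.points,
                site_atoms=atoms,
                cumulative_scores=scores,
                total_energy=cl.total_energy,
                total_propensity=cl.total_propensity,
            )
        )
    return ranked


def site_overlap_score(
    predicted_atoms: Iterable[AtomRecord],
    actual_atoms: Iterable[AtomRecord],
    combiner: str = "harmonic",
) -> float:
    """Site score Ƭ ∈ [0, 1] between predicted and actual atom sets.

    Atoms are matched by identity key (chain, residue, insertion code,
    atom name).  ``combiner`` is ``"harmonic"`` (2pc/(p+c), default) or
    ``"min"`` (min(p, c)).
    """
    pred = {a.key for a in predicted_atoms}
    actual = {a.key for a in actual_atoms}
    if not actual:
        raise ValueError("actual atom set must be non-empty")
    if not pred:
        return 0.0
    overlap = len(pred & actual)
    if overlap == 0:
        return 0.0
    p = overlap / len(pred)
    c = overlap / len(actual)
    if combiner == "harmonic":
        return 2.0 * p * c / (p + c)
    if combiner == "min":
        return min(p, c)
    raise ValueError(f"unknown combiner {combiner!r}")


@dataclass(frozen=True)
class EvaluationRecord:
    """Outcome of scoring the top-k predicted sites against an actual patch."""

    best_tau: float
    correct: bool
    coverage: float
    best_rank: int | None = None


def evaluate_topk(
    predicted_sites: Sequence[PredictedSite],
    actual_atoms: Iterable[AtomRecord],
    k: int,
    tau_min: float = DEFAULT_TAU_MIN,
    combiner: str = "harmonic",
) -> EvaluationRecord:
    """Best Ƭ among the top-k sites and whether it clears ``tau_min``.

    ``coverage`` is the actual-patch coverage of the best-Ƭ site.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    actual = list(actual_atoms)
    actual_keys = {a.key for a in actual}
    best_tau, best_cov, best_rank = 0.0, 0.0, None
    for site in predicted_sites[:k]:
        tau = site_overlap_score(site.site_atoms, actual, combiner)
        if tau > best_tau or best_rank is None:
            overlap = len(site.atom_keys & actual_keys)
            best_tau, best_rank = tau, site.rank
            best_cov = overlap / len(actual_keys)
    return EvaluationRecord(
        best_tau=best_tau, correct=best_tau >= tau_min, coverage=best_cov, best_rank=best_rank
    )
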