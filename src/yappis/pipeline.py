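"""Two-phase orchestration: training (domain scan) and testing (prediction).

Training examines the unbound chains of demarcated complexes with the
energy grid, takes the parametric scales two at a time together with a
probe-energy threshold, and records which score domains (bins) candidate
sites with Ƭ ≥ 0.25 against the actual patch fall into.  The union of the
accepting bins per scale, per scale pair, plus the threshold that maximises
the number of chains with an accepted site, form the *optimal ranges*.

Testing predicts up to ``max_sites`` (default 10) sites per unbound chain:
grid → retain at the trained threshold → cluster (≤15) → drop candidate
sites whose cumulative scores fall outside every accepted range pair →
rank.  Domain membership is tested on a candidate site's *cumulative*
scores, the same construction as the patch scores the domains were derived
from.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .gridprobe import (
    DEFAULT_CUTOFF,
    DEFAULT_PADDING,
    DEFAULT_SPACING,
    ProbeParams,
    build_grid,
    energy_field,
    retain_favorable,
    score_points,
)
from .interface import (
    DEFAULT_MIN_ACPS,
    DEFAULT_TOLERANCE,
    Interface,
    Patch,
    demarcate,
)
from .pdb_io import Chain
from .ranges import DomainSet, make_domains, remove_outliers_iqr
from .scales import PropensityTable, default_tables, derive_rip, patch_score
from .sites import (
    DEFAULT_MAX_CLUSTERS,
    DEFAULT_TAU_MIN,
    PredictedSite,
    cluster_points,
    default_linkage_cutoff,
    rank_sites,
    site_overlap_score,
)

logger = logging.getLogger("yappis.pipeline")

SCALE_PAIRS = (
    ("rip", "hydrophobicity"),
    ("rip", "solvation"),
    ("hydrophobicity", "solvation"),
)

#: Default probe-energy threshold grid (kcal/mol) scanned during training.
DEFAULT_ENERGY_THRESHOLDS = (-0.5, -1.0, -1.5, -2.0, -2.5, -3.0)


@dataclass(frozen=True)
class RunConfig:
    """All tunable knobs of a run, with field-standard defaults."""

    spacing: float = DEFAULT_SPACING
    padding: float = DEFAULT_PADDING
    tolerance: float = DEFAULT_TOLERANCE
    min_acps: int = DEFAULT_MIN_ACPS
    tau_min: float = DEFAULT_TAU_MIN
    max_sites: int = 10
    max_clusters: int = DEFAULT_MAX_CLUSTERS
    #: Occlusion radius used by the full pipeline.  A favourable methyl
    #: probe position sits near the pair's Lennard-Jones minimum (~4.2 Å
    #: for carbon), so the atoms it occludes are those within roughly one
    #: contact distance of the grid point; 4.5 Å captures that first shell.
    propensity_radius: float = 4.5
    energy_cutoff: float = DEFAULT_CUTOFF
    iqr_k: float = 1.5
    #: How patch/site scores are compared with the trained domains:
    #: "mean" divides the cumulative score by the atom count (intensive,
    #: composition-only), "cumulative" uses the raw sum (grows with site
    #: size, so sites smaller than training patches fall below the domain
    #: floor regardless of composition).
    domain_score_mode: str = "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.spacing <= 5):
            raise ValueError("spacing out of bounds")
        if self.tau_min < 0 or self.tau_min > 1:
            raise ValueError("tau_min must be in [0, 1]")
        if self.max_sites < 1 or self.max_clusters < 1:
            raise ValueError("max_sites and max_clusters must be >= 1")
        if self.domain_score_mode not in ("mean", "cumulative"):
            raise ValueError("domain_score_mode must be 'mean' or 'cumulative'")

    @property
    def linkage_cutoff(self) -> float:
        return default_linkage_cutoff(self.spacing)


@dataclass(frozen=True)
class TrainingComplex:
    """A two-chain complex with its demarcated interface."""

    chain_a: Chain
    chain_b: Chain
    interface: Interface

    def sides(self) -> list[tuple[Chain, Patch]]:
        """(unbound chain, actual patch) for both partners."""
        return [(self.chain_a, self.interface.patch_a), (self.chain_b, self.interface.patch_b)]


def demarcate_complex(chain_a: Chain, chain_b: Chain, config: RunConfig | None = None) -> TrainingComplex:
    config = config or RunConfig()
    iface = demarcate(chain_a, chain_b, config.tolerance)
    return TrainingComplex(chain_a, chain_b, iface)


def build_domain_sets(
    interfaces: Iterable[Interface],
    tables: Mapping[str, PropensityTable],
    iqr_k: float = 1.5,
    score_mode: str = "mean",
) -> dict[str, DomainSet]:
    """Domains of the patch-score distributions: for each scale, score
    every patch of every interface, drop IQR outliers, Scott-bin.

    ``score_mode="mean"`` bins the per-atom mean of the cumulative patch
    score so that candidate sites of any size are commensurable with the
    training patches; ``"cumulative"`` bins the raw sums.
    """
    interfaces = list(interfaces)
    domain_sets = {}
    for name, table in tables.items():
        values = []
        for iface in interfaces:
            for patch in (iface.patch_a, iface.patch_b):
                s = patch_score(patch, table)
                if score_mode == "mean" and len(patch) > 0:
                    s /= len(patch)
                values.append(s)
        retained = remove_outliers_iqr(values, k=iqr_k)
        domain_sets[name] = make_domains(retained, scale_name=name)
    return domain_sets


def _domain_scores(site: PredictedSite, mode: str) -> dict[str, float]:
    scores = site.cumulative_scores.by_scale()
    if mode == "mean" and site.site_atoms:
        n = len(site.site_atoms)
        scores = {k: v / n for k, v in scores.items()}
    return scores


@dataclass
class OptimalRanges:
    """Trained acceptance ranges: per scale pair, the union of score
    intervals that produced correct sites, plus the best energy threshold."""

    energy_threshold: float
    accepted: dict[str, dict[str, list[tuple[float, float]]]]
    stats: dict[str, float] = field(default_factory=dict)
    tau_min: float = DEFAULT_TAU_MIN
    domain_edges: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.energy_threshold >= 0:
            raise ValueError("energy_threshold must be negative")

    @staticmethod
    def pair_key(x: str, y: str) -> str:
        return f"{x}|{y}"

    def has_ranges(self) -> bool:
        return any(ivs for by_scale in self.accepted.values() for ivs in by_scale.values())

    def site_accepted(self, scores: Mapping[str, float]) -> bool:
        """True when at least one scale pair accepts the site's cumulative
        scores (each score inside that pair's interval union, closed)."""
        for x, y in SCALE_PAIRS:
            by_scale = self.accepted.get(self.pair_key(x, y))
            if not by_scale:
                continue
            if _in_union(scores[x], by_scale.get(x, [])) and _in_union(
                scores[y], by_scale.get(y, [])
            ):
                return True
        return False

    def to_json(self) -> str:
        payload = {
            "energy_threshold": self.energy_threshold,
            "tau_min": self.tau_min,
            "accepted": {
                pair: {scale: [list(iv) for iv in ivs] for scale, ivs in by_scale.items()}
                for pair, by_scale in self.accepted.items()
            },
            "stats": self.stats,
            "domain_edges": self.domain_edges,
        }
        return json.dumps(payload, sort_keys=True, indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "OptimalRanges":
        obj = json.loads(text)
        return cls(
            energy_threshold=obj["energy_threshold"],
            accepted={
                pair: {scale: [tuple(iv) for iv in ivs] for scale, ivs in by_scale.items()}
                for pair, by_scale in obj["accepted"].items()
            },
            stats=obj.get("stats", {}),
            tau_min=obj.get("tau_min", DEFAULT_TAU_MIN),
            domain_edges=obj.get("domain_edges", {}),
        )


def _in_union(value: float, intervals: Sequence[tuple[float | None, float | None]]) -> bool:
    # None bounds mark open-ended edge domains.
    return any(
        (lo is None or lo <= value) and (hi is None or value <= hi)
        for lo, hi in intervals
    )


def _clamped_bin(domains: DomainSet, value: float) -> int:
    """Domain index with open-ended boundary domains: scores beyond the
    tiled range belong to the nearest edge domain."""
    idx = domains.bin_index(value)
    if idx is not None:
        return idx
    return 0 if value < domains.bin_edges[0] else domains.n_bins - 1


def _merge_bins(
    domains: DomainSet, bin_ids: set[int]
) -> list[tuple[float | None, float | None]]:
    """Contiguous hull of the accepting bins.

    Scores of correct training sites sample an underlying *range* of the
    parameter; the optimal range is therefore the span from the lowest to
    the highest accepting bin (a contiguous union of bins), not the
    possibly gappy set of individually hit bins.  A hull touching the first
    or last domain is open at that end, because the training patches bound
    the domain grid but not the scores a genuine site may take.
    """
    if not bin_ids:
        return []
    lo: float | None = domains.interval(min(bin_ids))[0]
    hi: float | None = domains.interval(max(bin_ids))[1]
    if min(bin_ids) == 0:
        lo = None
    if max(bin_ids) == domains.n_bins - 1:
        hi = None
    return [(lo, hi)]


class _ChainState:
    """Cached grid and energy field of one unbound chain."""

    def __init__(self, chain: Chain, config: RunConfig, params: ProbeParams):
        self.chain = chain
        self.grid = build_grid(chain, config.spacing, config.padding)
        self.energies = energy_field(self.grid, chain, params, config.energy_cutoff)

    def candidates(
        self,
        threshold: float,
        tables: Mapping[str, PropensityTable],
        config: RunConfig,
        weights: Mapping[str, float] | None = None,
    ) -> list[PredictedSite]:
        retained = retain_favorable(self.grid, self.energies, threshold)
        if not retained:
            return []
        scored = score_points(
            retained, self.chain, tables, config.propensity_radius, weights
        )
        clusters = cluster_points(scored, config.max_clusters, config.linkage_cutoff)
        return rank_sites(clusters, self.chain, tables, config.propensity_radius)


def scan_domains(
    training_complexes: Sequence[TrainingComplex],
    domain_sets: Mapping[str, DomainSet],
    energy_thresholds: Sequence[float] = DEFAULT_ENERGY_THRESHOLDS,
    tables: Mapping[str, PropensityTable] | None = None,
    config: RunConfig | None = None,
    params: ProbeParams | None = None,
    weights: Mapping[str, float] | None = None,
) -> OptimalRanges:
    """Training-phase scan over (scale pair, domain combo, threshold).

    For every threshold, every unbound training chain is examined with the
    grid; candidate sites whose Ƭ against the chain's actual patch clears
    ``tau_min`` mark their score bins as accepting for each scale pair.
    Accepting bins accumulate across the whole scan and are merged into
    the returned interval unions; the returned threshold is the one that
    kept the most chains with an accepted site.
    """
    training_complexes = list(training_complexes)
    if not training_complexes:
        raise ValueError("empty training set")
    if not energy_thresholds:
        raise ValueError("need at least one energy threshold")
    config = config or RunConfig()
    if tables is None:
        interfaces = [tc.interface for tc in training_complexes]
        chains = [c for tc in training_complexes for c in (tc.chain_a, tc.chain_b)]
        tables = default_tables(derive_rip(interfaces, chains))
    params = params or ProbeParams()

    sides = [
        (f"{i}:{chain.chain_id}", _ChainState(chain, config, params), patch)
        for i, tc in enumerate(training_complexes)
        for chain, patch in tc.sides()
    ]
    n_chains = len(sides)

    # Accepting bins accumulate over every (pair, domain, threshold) combo
    # that conformed; the threshold is optimised separately by chain count.
    accepted_bins = {
        OptimalRanges.pair_key(x, y): {x: set(), y: set()} for x, y in SCALE_PAIRS
    }
    stats: dict[str, float] = {}
    for threshold in energy_thresholds:
        chains_hit: set[str] = set()
        for side_id, state, actual_patch in sides:
            for site in state.candidates(threshold, tables, config, weights):
                tau = site_overlap_score(site.site_atoms, actual_patch.interacting_atoms)
                scores = _domain_scores(site, config.domain_score_mode)
                for x, y in SCALE_PAIRS:
                    bx = _clamped_bin(domain_sets[x], scores[x])
                    by = _clamped_bin(domain_sets[y], scores[y])
                    logger.debug(
                        "scan side=%s thr=%.2f pair=%s|%s bins=(%s,%s) tau=%.3f",
                        side_id, threshold, x, y, bx, by, tau,
                    )
                    if tau < config.tau_min:
                        continue
                    key = OptimalRanges.pair_key(x, y)
                    accepted_bins[key][x].add(bx)
                    accepted_bins[key][y].add(by)
                    chains_hit.add(side_id)
        stats[f"{threshold:g}"] = len(chains_hit) / n_chains

    best = max(energy_thresholds, key=lambda t: stats[f"{t:g}"])
    accepted = {
        pair: {
            scale: _merge_bins(domain_sets[scale], bins)
            for scale, bins in by_scale.items()
        }
        for pair, by_scale in accepted_bins.items()
    }
    return OptimalRanges(
        energy_threshold=best,
        accepted=accepted,
        stats=stats,
        tau_min=config.tau_min,
        domain_edges={name: list(ds.bin_edges) for name, ds in domain_sets.items()},
    )


def predict(
    chain: Chain,
    optimal_ranges: OptimalRanges,
    tables: Mapping[str, PropensityTable],
    config: RunConfig | None = None,
    max_sites: int | None = None,
    params: ProbeParams | None = None,
    weights: Mapping[str, float] | None = None,
) -> list[PredictedSite]:
    """Predict up to ``max_sites`` PPI sites on an unbound chain."""
    config = config or RunConfig()
    max_sites = config.max_sites if max_sites is None else max_sites
    state = _ChainState(chain, config, params or ProbeParams())
    candidates = state.candidates(optimal_ranges.energy_threshold, tables, config, weights)
    if not candidates:
        warnings.warn(f"no favourable grid points on chain {chain.chain_id!r}")
        return []
    if optimal_ranges.has_ranges():
        candidates = [
            s for s in candidates
            if optimal_ranges.site_accepted(_domain_scores(s, config.domain_score_mode))
        ]
    kept = candidates[:max_sites]
    return [
        PredictedSite(
            rank=i,
            grid_points=s.grid_points,
            site_atoms=s.site_atoms,
            cumulative_scores=s.cumulative_scores,
            total_energy=s.total_energy,
            total_propensity=s.total_propensity,
        )
        for i, s in enumerate(kept, start=1)
    ]


@dataclass(frozen=True)
class ChainEvaluation:
    complex_index: int
    chain_id: str
    n_sites: int
    best_tau: float
    correct: bool
    top1_coverage: float
    top2_coverage: float


@dataclass(frozen=True)
class DatasetSummary:
    records: tuple[ChainEvaluation, ...]
    accuracy: float
    mean_top1_coverage: float
    mean_top2_coverage: float


def _union_coverage(sites: Sequence[PredictedSite], actual_keys: frozenset, k: int) -> float:
    covered: set = set()
    for site in sites[:k]:
        covered |= site.atom_keys & actual_keys
    return len(covered) / len(actual_keys)


def evaluate_dataset(
    complexes: Sequence[TrainingComplex],
    optimal_ranges: OptimalRanges,
    tables: Mapping[str, PropensityTable],
    config: RunConfig | None = None,
    tau_min: float | None = None,
    params: ProbeParams | None = None,
    weights: Mapping[str, float] | None = None,
) -> DatasetSummary:
    """Predict on every unbound chain of a demarcated dataset and compare
    against the actual patches.

    ``accuracy`` is the fraction of chains with at least one predicted site
    of Ƭ ≥ tau_min among all (≤ max_sites) predictions; top-k coverage is
    the fraction of actual patch atoms recovered by the union of the k
    best-ranked sites.
    """
    config = config or RunConfig()
    tau_min = config.tau_min if tau_min is None else tau_min
    params = params or ProbeParams()
    records: list[ChainEvaluation] = []
    for idx, tc in enumerate(complexes):
        for chain, patch in tc.sides():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sites = predict(chain, optimal_ranges, tables, config, params=params, weights=weights)
            actual_keys = patch.atom_keys
            best_tau = max(
                (site_overlap_score(s.site_atoms, patch.interacting_atoms) for s in sites),
                default=0.0,
            )
            records.append(
                ChainEvaluation(
                    complex_index=idx,
                    chain_id=chain.chain_id,
                    n_sites=len(sites),
                    best_tau=best_tau,
                    correct=best_tau >= tau_min,
                    top1_coverage=_union_coverage(sites, actual_keys, 1),
                    top2_coverage=_union_coverage(sites, actual_keys, 2),
                )
            )
    n = len(records)
    return DatasetSummary(
        records=tuple(records),
        accuracy=sum(r.correct for r in records) / n if n else 0.0,
        mean_top1_coverage=sum(r.top1_coverage for r in records) / n if n else 0.0,
        mean_top2_coverage=sum(r.top2_coverage for r in records) / n if n else 0.0,
    )


class YappisFinder:
    """High-level two-phase facade.

    ``fit`` demarcates (or takes pre-demarcated) training complexes,
    derives the RIP table, builds the score domains and runs the threshold
    scan; ``predict`` maps a single unbound chain; ``evaluate`` scores a
    demarcated test set.
    """

    def __init__(
        self,
        config: RunConfig | None = None,
        energy_thresholds: Sequence[float] = DEFAULT_ENERGY_THRESHOLDS,
        params: ProbeParams | None = None,
        weights: Mapping[str, float] | None = None,
    ):
        self.config = config or RunConfig()
        self.energy_thresholds = tuple(energy_thresholds)
        self.params = params or ProbeParams()
        self.weights = weights
        self.tables_: dict[str, PropensityTable] | None = None
        self.optimal_ranges_: OptimalRanges | None = None

    def fit(self, training_complexes: Sequence[TrainingComplex]) -> "YappisFinder":
        interfaces = [tc.interface for tc in training_complexes]
        chains = [c for tc in training_complexes for c in (tc.chain_a, tc.chain_b)]
        self.tables_ = default_tables(derive_rip(interfaces, chains))
        domain_sets = build_domain_sets(
            interfaces, self.tables_, self.config.iqr_k, self.config.domain_score_mode
        )
        self.optimal_ranges_ = scan_domains(
            training_complexes,
            domain_sets,
            self.energy_thresholds,
            self.tables_,
            self.config,
            self.params,
            self.weights,
        )
        return self

    def _check_fitted(self) -> None:
        if self.optimal_ranges_ is None or self.tables_ is None:
            raise RuntimeError("YappisFinder must be fitted first")

    def predict(self, chain: Chain, max_sites: int | None = None) -> list[PredictedSite]:
        self._check_fitted()
        return predict(
            chain, self.optimal_ranges_, self.tables_, self.config, max_sites,
            self.params, self.weights,
        )

    def evaluate(self, complexes: Sequence[TrainingComplex]) -> DatasetSummary:
        self._check_fitted()
        return evaluate_dataset(
            complexes, self.optimal_ranges_, self.tables_, self.config,
            params=self.params, weights=self.weights,
        )
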