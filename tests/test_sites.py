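"""Clustering of retained points, site ranking and the overlap score Ƭ."""

import numpy as np
import pytest

from yappis.gridprobe import GridPoint
from yappis.sites import (
    Cluster,
    cluster_points,
    default_linkage_cutoff,
    evaluate_topk,
    rank_sites,
    site_atoms,
    site_overlap_score,
)

from .conftest import flat_table, make_atom, point_chain


def grid_points(coords, energy=-1.0, propensity=0.0):
    return [
        GridPoint((i, 0, 0), tuple(map(float, xyz)), energy, overall_propensity=propensity)
        for i, xyz in enumerate(np.atleast_2d(coords))
    ]


def blob(center, n=8, spread=0.5, seed=0):
    rng = np.random.default_rng(seed)
    return np.asarray(center) + rng.uniform(-spread, spread, (n, 3))


class TestClusterPoints:
    def test_two_distant_blobs(self):
        cutoff = default_linkage_cutoff()
        pts = grid_points(np.vstack([blob([0, 0, 0]), blob([10 * cutoff, 0, 0], seed=1)]))
        clusters = cluster_points(pts)
        assert len(clusters) == 2

    def test_forty_singletons_keep_fifteen(self):
        pts = grid_points([[5.0 * i, 0, 0] for i in range(40)])
        clusters = cluster_points(pts, max_clusters=15)
        assert len(clusters) == 15

    def test_single_point(self):
        clusters = cluster_points(grid_points([[1, 2, 3]]))
        assert len(clusters) == 1 and len(clusters[0]) == 1

    def test_empty_input(self):
        assert cluster_points([]) == []

    def test_partition_no_point_in_two_clusters(self):
        rng = np.random.default_rng(3)
        pts = grid_points(rng.uniform(0, 15, (120, 3)))
        clusters = cluster_points(pts, max_clusters=1000)
        seen = [p.index for c in clusters for p in c.points]
        assert len(seen) == len(set(seen)) == len(pts)

    def test_size_ties_broken_by_lower_energy(self):
        a = [GridPoint((0, 0, 0), (0.0, 0, 0), -1.0)]
        b = [GridPoint((9, 0, 0), (50.0, 0, 0), -3.0)]
        clusters = cluster_points(a + b, max_clusters=1)
        assert clusters[0].total_energy == -3.0


class TestSiteAtoms:
    def test_far_cluster_empty(self):
        chain = point_chain("A", [[0, 0, 0]])
        cl = Cluster(tuple(grid_points([[40, 0, 0]])))
        assert site_atoms(cl, chain, radius=1.6) == ()

    def test_within_radius(self):
        chain = point_chain("A", [[0, 0, 0]])
        cl = Cluster(tuple(grid_points([[1.5, 0, 0]])))
        atoms = site_atoms(cl, chain, radius=1.6)
        assert [a.serial for a in atoms] == [1]

    def test_union_matches_brute_force(self):
        rng = np.random.default_rng(5)
        chain = point_chain("A", rng.uniform(0, 12, (40, 3)))
        cl = Cluster(tuple(grid_points(rng.uniform(0, 12, (15, 3)))))
        got = {a.serial for a in site_atoms(cl, chain, radius=3.0)}
        expected = {
            a.serial
            for a in chain.atoms
            if any(np.linalg.norm(a.xyz - p.xyz) <= 3.0 for p in cl.points)
        }
        assert got == expected

    def test_radius_validation(self):
        chain = point_chain("A", [[0, 0, 0]])
        with pytest.raises(ValueError):
            site_atoms(Cluster(()), chain, radius=0.0)


def _tables():
    return {
        "rip": flat_table("rip", 1.0),
        "hydrophobicity": flat_table("hydrophobicity", 0.0),
        "solvation": flat_table("solvation", 0.0),
    }


class TestRankSites:
    def test_higher_propensity_outranks_at_equal_energy(self):
        chain = point_chain("A", [[0, 0, 0], [30, 0, 0]])
        weak = Cluster(tuple(grid_points([[2, 0, 0]], energy=-1.0, propensity=0.5)))
        strong = Cluster(tuple(grid_points([[32, 0, 0]], energy=-1.0, propensity=2.0)))
        ranked = rank_sites([weak, strong], chain, _tables(), radius=3.0)
        assert ranked[0].total_propensity == 2.0
        assert [s.rank for s in ranked] == [1, 2]

    def test_duplicate_clusters_stable_adjacent_ranks(self):
        chain = point_chain("A", [[0, 0, 0]])
        cl = Cluster(tuple(grid_points([[2, 0, 0]], energy=-1.0, propensity=1.0)))
        ranked = rank_sites([cl, cl], chain, _tables(), radius=3.0)
        assert [s.rank for s in ranked] == [1, 2]
        assert ranked[0].site_atoms == ranked[1].site_atoms

    def test_engineered_winner_ranks_first(self):
        rng = np.random.default_rng(6)
        chain = point_chain("A", rng.uniform(0, 20, (30, 3)))
        losers = [
            Cluster(tuple(grid_points(blob([5, 5, 5], seed=i), energy=-0.6, propensity=0.1)))
            for i in range(4)
        ]
        winner = Cluster(
            tuple(grid_points(blob([10, 10, 10], n=12, seed=9), energy=-3.0, propensity=5.0))
        )
        ranked = rank_sites(losers + [winner], chain, _tables(), radius=3.0)
        assert ranked[0].total_energy == pytest.approx(winner.total_energy)

    def test_empty(self):
        chain = point_chain("A", [[0, 0, 0]])
        assert rank_sites([], chain, _tables()) == []


def atoms_at(serials):
    return [make_atom(s, [float(s), 0, 0], residue_seq=s) for s in serials]


class TestOverlapScore:
    def test_identical_sets(self):
        atoms = atoms_at(range(1, 11))
        assert site_overlap_score(atoms, atoms) == 1.0

    def test_disjoint_sets(self):
        assert site_overlap_score(atoms_at(range(10)), atoms_at(range(20, 30))) == 0.0

    def test_half_overlap(self):
        pred = atoms_at(range(1, 11))
        actual = atoms_at(range(6, 16))
        # |P∩A| = 5, |P| = |A| = 10 -> p = c = 0.5 -> harmonic 0.5
        assert site_overlap_score(pred, actual) == pytest.approx(0.5)

    def test_empty_predicted_is_zero(self):
        assert site_overlap_score([], atoms_at([1])) == 0.0

    def test_empty_actual_is_error(self):
        with pytest.raises(ValueError):
            site_overlap_score(atoms_at([1]), [])

    def test_min_combiner(self):
        pred = atoms_at(range(1, 5))  # |P|=4, overlap 2
        actual = atoms_at(range(3, 11))  # |A|=8
        p, c = 2 / 4, 2 / 8
        assert site_overlap_score(pred, actual, combiner="min") == pytest.approx(min(p, c))
        with pytest.raises(ValueError):
            site_overlap_score(pred, actual, combiner="mean")

    def test_order_and_duplication_invariance(self):
        pred = atoms_at([3, 1, 2]) + atoms_at([2])
        actual = atoms_at([2, 3, 9])
        assert site_overlap_score(pred, actual) == site_overlap_score(
            atoms_at([1, 2, 3]), atoms_at([9, 3, 2])
        )

    def test_harmonic_between_min_and_max(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            pred = atoms_at(rng.choice(40, size=rng.integers(1, 20), replace=False))
            actual = atoms_at(rng.choice(40, size=rng.integers(1, 20), replace=False))
            tau = site_overlap_score(pred, actual)
            keys = {a.key for a in pred} & {a.key for a in actual}
            if not keys:
                assert tau == 0.0
                continue
            p = len(keys) / len(pred)
            c = len(keys) / len(actual)
            assert min(p, c) - 1e-12 <= tau <= max(p, c) + 1e-12

    def test_coverage_monotone_for_nested_predictions(self):
        actual = atoms_at(range(1, 21))
        p1 = atoms_at(range(1, 6))
        p2 = atoms_at(range(1, 12))
        c1 = len(p1) / 20
        c2 = len(p2) / 20
        assert c2 >= c1  # nested predictions cannot lose coverage


def _site(rank, serials):
    from yappis.scales import PatchScores
    from yappis.sites import PredictedSite

    atoms = tuple(atoms_at(serials))
    return PredictedSite(
        rank=rank,
        grid_points=(),
        site_atoms=atoms,
        cumulative_scores=PatchScores(0, 0, 0),
        total_energy=-1.0,
        total_propensity=0.0,
    )


class TestEvaluateTopK:
    def test_boundary_tau_counts_correct(self):
        actual = atoms_at(range(1, 9))
        # overlap 2, |P|=2, |A|=8: p=1, c=0.25 -> harmonic = 0.4; craft 0.25:
        # |P|=8 overlap 2 gives p=c=0.25 -> harmonic exactly 0.25
        site = _site(1, list(range(1, 3)) + list(range(100, 106)))
        rec = evaluate_topk([site], actual, k=1, tau_min=0.25)
        assert rec.best_tau == pytest.approx(0.25)
        assert rec.correct

    def test_below_boundary_incorrect(self):
        actual = atoms_at(range(1, 101))
        site = _site(1, list(range(1, 13)) + list(range(200, 288)))
        rec = evaluate_topk([site], actual, k=1)
        assert rec.best_tau == pytest.approx(0.12)
        assert not rec.correct

    def test_topk_monotone(self):
        actual = atoms_at(range(1, 11))
        sites = [_site(1, range(50, 60)), _site(2, range(1, 11))]
        k1 = evaluate_topk(sites, actual, k=1)
        k2 = evaluate_topk(sites, actual, k=2)
        assert k2.best_tau >= k1.best_tau
        assert k2.best_rank == 2 and k2.coverage == 1.0

    def test_no_sites(self):
        rec = evaluate_topk([], atoms_at([1]), k=3)
        assert rec.best_tau == 0.0 and not rec.correct and rec.best_rank is None

    def test_k_validation(self):
        with pytest.raises(ValueError):
            evaluate_topk([], atoms_at([1]), k=0)
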