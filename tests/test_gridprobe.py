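"""Energy grid construction, probe energies and point propensities."""

import numpy as np
import pytest

from yappis.gridprobe import (
    ENERGY_CLAMP,
    GridPoint,
    ProbeParams,
    build_grid,
    energy_field,
    grid_point_propensity,
    overall_propensity,
    probe_energy,
    propensity_fields,
    retain_favorable,
    score_points,
    standardize,
)

from .conftest import flat_table, point_chain


@pytest.fixture(scope="module")
def params():
    return ProbeParams()


def shifted(chain, offset):
    return point_chain(chain.chain_id, chain.coords_array() + np.asarray(offset))


class TestBuildGrid:
    def test_single_atom_eleven_points_per_axis(self):
        chain = point_chain("A", [[0.0, 0.0, 0.0]])
        grid = build_grid(chain, spacing=0.9, padding=4.5)
        assert grid.dims == (11, 11, 11)
        pts = grid.points()
        assert pts.min() == pytest.approx(-4.5)
        assert pts.max() == pytest.approx(4.5)

    def test_doubling_spacing_roughly_eighths_points(self):
        chain = point_chain("A", np.random.default_rng(0).uniform(0, 20, (30, 3)))
        n1 = build_grid(chain, spacing=0.9).n_points
        n2 = build_grid(chain, spacing=1.8).n_points
        assert n1 / n2 == pytest.approx(8, rel=0.25)

    def test_atoms_inside_box(self):
        chain = point_chain("A", np.random.default_rng(1).uniform(-5, 5, (20, 3)))
        grid = build_grid(chain)
        pts = grid.points()
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        xyz = chain.coords_array()
        assert (xyz >= lo).all() and (xyz <= hi).all()

    def test_empty_chain_or_bad_spacing(self):
        chain = point_chain("A", [[0, 0, 0]])
        with pytest.raises(ValueError):
            build_grid(chain, spacing=0.0)


class TestProbeEnergy:
    def test_zero_beyond_cutoff(self, params):
        chain = point_chain("A", [[0, 0, 0]])
        assert probe_energy([9.0, 0, 0], chain.atoms, params, cutoff=8.0) == 0.0

    def test_minimum_is_minus_epsilon(self, params):
        eps, rmin = params.pair("C")
        chain = point_chain("A", [[0, 0, 0]])
        e = probe_energy([rmin, 0, 0], chain.atoms, params)
        assert e == pytest.approx(-eps, abs=1e-9)

    def test_core_clamp(self, params):
        chain = point_chain("A", [[0, 0, 0]])
        assert probe_energy([0.0, 0.0, 0.0], chain.atoms, params) == ENERGY_CLAMP
        assert probe_energy([0.5, 0.0, 0.0], chain.atoms, params) == ENERGY_CLAMP

    def test_field_matches_double_loop_oracle(self, params):
        rng = np.random.default_rng(4)
        chain = point_chain(
            "A", rng.uniform(0, 6, (10, 3)), elements=list("CNOSC") + list("CNOSC")
        )
        grid = build_grid(chain, spacing=1.7, padding=3.4)
        field = energy_field(grid, chain, params)
        # unoptimised reference: scalar probe energy per point
        for i, pt in enumerate(grid.points()):
            assert field[i] == pytest.approx(
                probe_energy(pt, chain.atoms, params), abs=1e-9
            )

    def test_translation_invariance(self, params):
        rng = np.random.default_rng(5)
        chain = point_chain("A", rng.uniform(0, 8, (12, 3)))
        moved = shifted(chain, [13.7, -4.2, 8.1])
        f1 = energy_field(build_grid(chain), chain, params)
        f2 = energy_field(build_grid(moved), moved, params)
        np.testing.assert_allclose(f1, f2, atol=1e-9)

    def test_vanishes_at_distance(self, params):
        chain = point_chain("A", [[0, 0, 0]])
        assert abs(probe_energy([8.01, 0, 0], chain.atoms, params)) < 1e-6


class TestRetainFavorable:
    def _grid_and_field(self, params):
        chain = point_chain("A", np.random.default_rng(6).uniform(0, 10, (15, 3)))
        grid = build_grid(chain)
        return chain, grid, energy_field(grid, chain, params)

    def test_exactly_below_threshold(self, params):
        chain, grid, field = self._grid_and_field(params)
        for thr in (-0.5, -1.0):
            kept = retain_favorable(grid, field, thr)
            assert len(kept) == int((field < thr).sum())
            assert all(p.energy < thr for p in kept)

    def test_monotone_in_threshold(self, params):
        chain, grid, field = self._grid_and_field(params)
        sizes = [len(retain_favorable(grid, field, t)) for t in (-0.5, -1.0, -1.5, -2.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_positive_threshold_rejected(self, params):
        chain, grid, field = self._grid_and_field(params)
        with pytest.raises(ValueError):
            retain_favorable(grid, field, 0.5)

    def test_interior_points_never_retained(self, params):
        # points clamped at the positive core energy cannot pass a negative
        # threshold, so retained points lie outside atomic cores
        chain, grid, field = self._grid_and_field(params)
        kept = retain_favorable(grid, field, -0.5)
        xyz = chain.coords_array()
        for p in kept[:50]:
            d = np.linalg.norm(xyz - p.xyz, axis=1).min()
            assert d > 2.0


class TestPropensity:
    def test_no_atom_within_radius(self):
        chain = point_chain("A", [[0, 0, 0]])
        table = flat_table(value=1.0)
        assert grid_point_propensity([5, 0, 0], chain, table, radius=1.6) == 0.0

    def test_single_gly_within_radius(self):
        chain = point_chain("A", [[0, 0, 0]], residue_type="GLY")
        table = flat_table(value=0.0, GLY=2.0)
        assert grid_point_propensity([1.5, 0, 0], chain, table, radius=1.6) == 2.0

    def test_fields_match_scalar_oracle(self, hydro_table):
        rng = np.random.default_rng(8)
        chain = point_chain("A", rng.uniform(0, 10, (25, 3)), residue_type="LEU")
        pts = [
            GridPoint((i, 0, 0), tuple(xyz), -1.0)
            for i, xyz in enumerate(rng.uniform(0, 10, (30, 3)))
        ]
        tables = {"rip": flat_table(), "hydrophobicity": hydro_table, "solvation": flat_table("solvation", 0.3)}
        fields = propensity_fields(pts, chain, tables, radius=2.5)
        for name, table in tables.items():
            for i, p in enumerate(pts):
                expected = grid_point_propensity(p.coords, chain, table, radius=2.5)
                assert fields[name][i] == pytest.approx(expected, abs=1e-12)


class TestOverallPropensity:
    def test_all_zero(self):
        z = np.zeros(5)
        np.testing.assert_array_equal(overall_propensity(z, z, z), z)

    def test_projection_weight(self):
        rng = np.random.default_rng(9)
        rip, hyd, sol = rng.normal(size=(3, 20))
        out = overall_propensity(rip, hyd, sol, weights={"rip": 1.0})
        np.testing.assert_allclose(out, standardize(rip), atol=1e-12)

    def test_default_weights_hand_combined(self):
        rng = np.random.default_rng(10)
        rip, hyd, sol = rng.normal(size=(3, 15))
        out = overall_propensity(rip, hyd, sol)
        hand = standardize(rip) - standardize(hyd) - standardize(sol)
        np.testing.assert_allclose(out, hand, atol=1e-12)

    def test_score_points_attaches_scores(self, hydro_table, solv_table):
        chain = point_chain("A", [[0, 0, 0]], residue_type="TRP")
        pts = [GridPoint((0, 0, 0), (1.0, 0, 0), -1.0)]
        tables = {"rip": flat_table(), "hydrophobicity": hydro_table, "solvation": solv_table}
        scored = score_points(pts, chain, tables, radius=2.0)
        assert scored[0].hydro_score == pytest.approx(0.30 / 11)
        assert scored[0].energy == -1.0


class TestProbeParams:
    def test_requires_probe_row(self):
        with pytest.raises(ValueError, match="PROBE"):
            ProbeParams({"C": (0.1, 2.0)})

    def test_combination_rules(self, params):
        eps, rmin = params.pair("C")
        assert eps == pytest.approx(np.sqrt(0.160 * 0.105))
        assert rmin == pytest.approx(2.17 + 2.00)

    def test_unknown_element(self, params):
        with pytest.raises(KeyError):
            params.pair("ZZ")
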