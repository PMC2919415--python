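"""Symmetry expansion, candidate enumeration and stepwise nested selection."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ccsbuild.models import Sphere, SphereModel, SymOp, UnitCell
from ccsbuild.symmetry import (
    CopyPlacement,
    SymmetryBlock,
    compactness_of,
    enumerate_candidates,
    expand_symmetry,
    point_group_score,
    stepwise_series,
)
from ccsbuild.synthetic import (
    FixtureSpec,
    make_planted_ccs_table,
    make_unit,
    planted_symmetry_series,
)

from oracles import brute_force_candidates


def _unit(seed=1, operators="p1", n_residues=60):
    return make_unit(FixtureSpec(seed=seed, n_residues=n_residues, operators=operators))


def _manual_block(coms, radius=5.0):
    """Block of translation-only copies of a single small sphere."""
    source = SphereModel([Sphere("s", (0, 0, 0), radius, 1000.0)])
    copies = [
        CopyPlacement(
            copy_id=i, op_index=0, shift=(0, 0, 0),
            R=tuple(map(tuple, np.eye(3))), t=tuple(map(float, c)),
            com=tuple(map(float, c)),
        )
        for i, c in enumerate(coms)
    ]
    return SymmetryBlock(copies=copies, source=source)


class TestExpansion:
    def test_identity_only_shell0_gives_one_copy(self):
        block = expand_symmetry(_unit(operators="identity"), shell=0)
        assert len(block) == 1

    def test_identity_shell1_gives_27_lattice_copies(self):
        block = expand_symmetry(_unit(operators="identity"), shell=1)
        assert len(block) == 27
        assert block.copies[0].shift == (0, 0, 0)

    def test_four_operators_shell1_at_most_108_after_dedup(self):
        block = expand_symmetry(_unit(operators="orthorhombic4"), shell=1)
        assert 27 < len(block) <= 108

    def test_duplicate_operators_are_removed(self):
        u = _unit(operators="identity")
        ops = [SymOp.identity(), SymOp.identity()]
        block = expand_symmetry(u, operators=ops, shell=0)
        assert len(block) == 1

    def test_fractional_and_cartesian_operators_agree(self):
        u = _unit(operators="identity")
        cell = u.cell
        M = cell.orthogonalization_matrix()
        frac = SymOp.make(np.diag([-1.0, -1.0, 1.0]), [0.5, 0.0, 0.5], fractional=True)
        cart = SymOp.make(
            np.diag([-1.0, -1.0, 1.0]), M @ np.array([0.5, 0.0, 0.5]), fractional=False
        )
        b_frac = expand_symmetry(u, operators=[SymOp.identity(True), frac], shell=0)
        b_cart = expand_symmetry(u, operators=[SymOp.identity(), cart], shell=0)
        assert np.allclose(b_frac.coms(), b_cart.coms(), atol=1e-6)

    def test_fractional_operators_require_cell(self):
        model = SphereModel([Sphere("s", (0, 0, 0), 5.0, 100.0)])
        frac = SymOp.make(np.eye(3), [0.5, 0, 0], fractional=True)
        with pytest.raises(ValueError):
            expand_symmetry(model, operators=[frac], shell=0)


class TestCompactness:
    def test_collinear_trio_compactness(self):
        block = _manual_block([(0, 0, 0), (30, 0, 0), (60, 0, 0)])
        # d + d + 2d with d = 30
        assert compactness_of(block, (0, 1, 2)) == pytest.approx(120.0)

    def test_triangle_beats_collinear(self):
        d = 30.0
        tri = _manual_block(
            [(0, 0, 0), (d, 0, 0), (d / 2, d * np.sqrt(3) / 2, 0)]
        )
        line = _manual_block([(0, 0, 0), (d, 0, 0), (2 * d, 0, 0)])
        assert compactness_of(tri, (0, 1, 2)) < compactness_of(line, (0, 1, 2))

    def test_invariant_under_global_rigid_motion(self):
        rng = np.random.default_rng(3)
        coms = rng.random((6, 3)) * 50
        R = Rotation.from_euler("xyz", [0.4, -1.0, 2.2]).as_matrix()
        moved = coms @ R.T + np.array([100.0, -40.0, 7.0])
        a = compactness_of(_manual_block(coms), (0, 2, 4, 5))
        b = compactness_of(_manual_block(moved), (0, 2, 4, 5))
        assert a == pytest.approx(b, rel=1e-12)


class TestEnumeration:
    def test_matches_brute_force_on_random_block(self):
        rng = np.random.default_rng(7)
        coms = rng.random((12, 3)) * 40
        cutoff = 25.0
        block = _manual_block(coms, radius=4.0)
        for n in (3, 4):
            got = enumerate_candidates(block, n, max_candidates=10_000, cutoff=cutoff)
            expected = brute_force_candidates(coms, n, cutoff, radius=4.0)
            assert [
                (round(c.compactness, 6), c.members) for c in got
            ] == expected

    def test_candidates_sorted_ascending_by_compactness(self):
        rng = np.random.default_rng(11)
        block = _manual_block(rng.random((10, 3)) * 30, radius=3.0)
        cands = enumerate_candidates(block, 4, max_candidates=50, cutoff=20.0)
        comps = [c.compactness for c in cands]
        assert comps == sorted(comps)
        assert all(0 in c.members for c in cands)

    def test_no_connected_subset_returns_empty(self):
        block = _manual_block([(0, 0, 0), (500, 0, 0), (1000, 0, 0)])
        assert enumerate_candidates(block, 2, cutoff=10.0) == []

    def test_deterministic_ordering(self):
        rng = np.random.default_rng(5)
        coms = rng.random((10, 3)) * 30
        a = enumerate_candidates(_manual_block(coms), 4, cutoff=25.0)
        b = enumerate_candidates(_manual_block(coms), 4, cutoff=25.0)
        assert [c.members for c in a] == [c.members for c in b]

    def test_clashing_candidates_discarded(self):
        # copies almost coincident: enormous volume overlap
        block = _manual_block([(0, 0, 0), (0.5, 0, 0), (40, 0, 0)], radius=5.0)
        cands = enumerate_candidates(block, 2, cutoff=50.0)
        assert all(set(c.members) != {0, 1} for c in cands)


class TestPointGroup:
    def test_equilateral_triangle_has_threefold_dihedral(self):
        tri = np.array([[0, 0, 0], [30, 0, 0], [15, 15 * np.sqrt(3), 0]], float)
        k, dihedral = point_group_score(tri)
        assert k == 3 and dihedral

    def test_rectangle_has_twofold_dihedral(self):
        rect = np.array([[0, 0, 0], [40, 0, 0], [0, 25, 0], [40, 25, 0]], float)
        k, dihedral = point_group_score(rect)
        assert k == 2 and dihedral

    def test_scalene_set_is_asymmetric(self):
        # side lengths 30, 13 and ~27.7: no rotation maps the set onto itself
        pts = np.array([[0, 0, 0], [30, 0, 0], [5, 12, 0]], float)
        assert point_group_score(pts) == (1, False)


class TestStepwise:
    def test_planar_rectangle_recovered_from_planted_table(self):
        u = _unit(seed=6, n_residues=80)
        block, planted = planted_symmetry_series(u, 4)
        table = make_planted_ccs_table(u, n_values=(1, 2, 3, 4), noise=0.0, seed=6)
        exp = {
            int(r.n_subunits): (float(r.ccs_A2), float(r.rel_error))
            for r in table.itertuples()
        }
        result = stepwise_series(block, 4, exp, seed=2024)
        assert result.complete
        assert [c.members for c in result.series] == planted
        # the planted tetramer is a planar rectangle of lattice copies
        coms = block.coms()[list(planted[3])]
        d = np.linalg.norm(coms[:, None, :] - coms[None, :, :], axis=2)
        pair_d = sorted(d[np.triu_indices(4, 1)])
        assert pair_d[0] == pytest.approx(pair_d[1], rel=1e-6)  # sides a
        assert pair_d[2] == pytest.approx(pair_d[3], rel=1e-6)  # sides b
        assert pair_d[4] == pytest.approx(pair_d[5], rel=1e-6)  # diagonals

    def test_nesting_invariant_along_series(self):
        u = _unit(seed=8, n_residues=80)
        block, _ = planted_symmetry_series(u, 5)
        table = make_planted_ccs_table(u, n_values=(1, 2, 3, 4, 5), noise=0.0, seed=8)
        exp = {
            int(r.n_subunits): (float(r.ccs_A2), float(r.rel_error))
            for r in table.itertuples()
        }
        result = stepwise_series(block, 5, exp, seed=1)
        for prev, cand in zip(result.series, result.series[1:]):
            assert set(prev.members) < set(cand.members)
            assert len(cand.members) == len(prev.members) + 1
            assert cand.nested_parent == prev.members

    def test_n_max_one_returns_building_block_alone(self):
        u = _unit(seed=8, n_residues=60)
        block, _ = planted_symmetry_series(u, 2)
        result = stepwise_series(block, 1, {1: (500.0, 0.05)})
        assert len(result.series) == 1 and result.series[0].members == (0,)

    def test_unreachable_experimental_ccs_reports_partial_series(self):
        u = _unit(seed=9, n_residues=60)
        block, _ = planted_symmetry_series(u, 3)
        # a dimer CCS far below anything the block can produce
        result = stepwise_series(block, 3, {2: (100.0, 0.05)}, seed=1)
        assert not result.complete
        assert result.messages
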