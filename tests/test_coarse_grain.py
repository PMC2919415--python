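"""Domain decomposition, sphere models, calibration and missing-mass spheres."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ccsbuild.ccs import pa_ccs_atoms, pa_ccs_spheres
from ccsbuild.coarse_grain import (
    DisconnectedNetworkError,
    PlacementInfeasibleError,
    _placement_frame,
    build_sphere_model,
    calibrate_radii,
    decompose_domains,
    missing_sphere_radius,
    place_missing_sphere,
)
from ccsbuild.models import AtomicStructure, Sphere, SphereModel
from ccsbuild.structio import WATER_MASS, mass_account
from ccsbuild.synthetic import FixtureSpec, make_unit


class TestDecomposition:
    def test_dumbbell_splits_inside_linker(self, dumbbell):
        # lobes are residues 1-57 and 63-120; the linker is 58-62
        decomp = decompose_domains(dumbbell)
        assert decomp.k == 2
        labels = [
            decomp.labels[key]
            for key in sorted(decomp.labels, key=lambda k: k[1])
        ]
        switches = [i + 1 for i in range(len(labels) - 1) if labels[i] != labels[i + 1]]
        assert len(switches) == 1
        assert 56 <= switches[0] <= 64

    def test_compact_globule_is_one_domain(self, globule):
        assert decompose_domains(globule).k == 1

    def test_forced_k_and_contiguous_labels(self, trilobe):
        decomp = decompose_domains(trilobe, k=3)
        assert decomp.k == 3
        assert set(decomp.labels.values()) == {1, 2, 3}
        assert set(decomp.labels) == set(trilobe.residue_keys())

    def test_automatic_k_on_trilobe(self, trilobe):
        assert decompose_domains(trilobe).k == 3

    def test_invariant_under_rigid_motion(self, dumbbell):
        base = decompose_domains(dumbbell)
        R = Rotation.from_euler("xyz", [0.5, 1.2, -0.7]).as_matrix()
        moved = dumbbell.transformed(R, np.array([42.0, -7.0, 13.0]))
        assert decompose_domains(moved).labels == base.labels

    def test_disconnected_network_errors(self):
        rng = np.random.default_rng(0)
        a = rng.random((20, 3)) * 10
        b = rng.random((20, 3)) * 10 + 100.0
        coords = np.vstack([a, b])
        st = AtomicStructure(
            elements=["C"] * 40,
            atom_names=["CA"] * 40,
            res_names=["ALA"] * 40,
            res_seq=np.arange(1, 41),
            icodes=[""] * 40,
            chain_ids=["A"] * 40,
            coords=coords,
            chains={"A": "A" * 40},
        )
        with pytest.raises(DisconnectedNetworkError):
            decompose_domains(st)


class TestSphereModel:
    def test_single_domain_sphere_at_center_of_mass(self, globule):
        decomp = decompose_domains(globule, k=1)
        model = build_sphere_model(globule, decomp, seed=0)
        assert len(model) == 1
        assert np.allclose(model.centers[0], globule.center_of_mass(), atol=1e-6)
        # radius reproduces the structure's own PA CCS by construction
        est = pa_ccs_atoms(globule, seed=0)
        assert model.radii[0] == pytest.approx(np.sqrt(est.value / np.pi), rel=0.02)

    def test_masses_sum_to_observed_residue_mass(self, trilobe):
        decomp = decompose_domains(trilobe, k=3)
        model = build_sphere_model(trilobe, decomp, seed=0)
        acc = mass_account(trilobe)
        # domain masses exclude the one water of the chain mass
        assert model.total_mass == pytest.approx(acc.m_present - WATER_MASS, abs=0.5)

    def test_three_domains_three_spheres(self, trilobe):
        model = build_sphere_model(trilobe, decompose_domains(trilobe, k=3), seed=0)
        assert len(model) == 3


class TestCalibration:
    @pytest.mark.parametrize("shape,k", [("globule", 1), ("trilobe", 3)])
    def test_calibrated_model_matches_atomic_ccs(self, shape, k):
        unit = make_unit(FixtureSpec(seed=13, n_residues=120, shape=shape))
        model = build_sphere_model(unit, decompose_domains(unit, k=k), seed=13)
        calibrated = calibrate_radii(
            unit, model, rel_tol=0.005, n_rotations=800, n_points=2000, seed=13
        )
        # paired re-measurement with a fresh orientation sample
        atomic = pa_ccs_atoms(unit, n_rotations=800, n_points=2000, seed=999)
        cg = pa_ccs_spheres(calibrated, n_rotations=800, n_points=2000, seed=999)
        assert abs(cg.value - atomic.value) / atomic.value <= 0.01

    def test_already_matching_model_gets_factor_near_one(self, globule):
        model = build_sphere_model(globule, decompose_domains(globule, k=1), seed=5)
        once = calibrate_radii(globule, model, seed=5)
        twice = calibrate_radii(globule, once, seed=5)
        assert np.allclose(twice.radii, once.radii, rtol=0.01)


class TestMissingSphere:
    def test_equal_mass_gives_equal_radius(self):
        model = SphereModel([Sphere("a", (0, 0, 0), 10.0, 8000.0)])
        assert missing_sphere_radius(model, 8000.0) == pytest.approx(10.0)

    def test_cube_root_mass_scaling(self):
        model = SphereModel([Sphere("a", (0, 0, 0), 10.0, 8000.0)])
        r1 = missing_sphere_radius(model, 3000.0)
        r2 = missing_sphere_radius(model, 6000.0)
        assert r2 / r1 == pytest.approx(2 ** (1 / 3), abs=1e-12)

    def test_pooled_density_formula(self):
        model = SphereModel(
            [Sphere("a", (0, 0, 0), 10, 10000.0), Sphere("b", (25, 0, 0), 10, 10000.0)]
        )
        assert missing_sphere_radius(model, 5000.0) == pytest.approx(
            10 * 0.5 ** (1 / 3), abs=1e-9
        )


class TestPlacement:
    def _base(self):
        return SphereModel(
            [Sphere("a", (0, 0, 0), 12.0, 12000.0), Sphere("b", (18, 0, 0), 10.0, 9000.0)]
        )

    def test_scan_recovers_reference_placement(self):
        base = self._base()
        r_mis, mass = 7.0, 5000.0
        u, v = _placement_frame(base, base.spheres[1])
        dist = 10.0 + r_mis - 0.4 * 10.0
        theta_ref = np.pi / 2
        pos = np.array([18.0, 0, 0]) + dist * (np.cos(theta_ref) * u + np.sin(theta_ref) * v)
        ref = base.with_sphere(Sphere("missing", tuple(pos), r_mis, mass, "missing"))
        target = pa_ccs_spheres(ref, n_rotations=80, n_points=1500, seed=0).value
        _, scan = place_missing_sphere(base, "b", r_mis, target, mass, seed=0)
        assert scan.best_overlap == pytest.approx(0.4, abs=0.051)
        assert scan.best_theta == pytest.approx(theta_ref, abs=2 * np.pi / 36 + 1e-9)

    def test_buried_sphere_prefers_maximal_overlap(self):
        base = self._base()
        target = pa_ccs_spheres(base, n_rotations=80, n_points=1500, seed=0).value
        _, scan = place_missing_sphere(base, "a", 3.0, target, 500.0, seed=0)
        assert scan.best_overlap == 1.0

    def test_ccs_non_decreasing_as_overlap_decreases(self):
        base = self._base()
        target = pa_ccs_spheres(base, n_rotations=80, n_points=1500, seed=0).value
        _, scan = place_missing_sphere(base, "b", 7.0, target * 1.05, 5000.0, seed=0)
        # scan rows go from overlap 0 (exposed) to 1 (buried): CCS decreases
        for j in range(scan.ccs_grid.shape[1]):
            col = scan.ccs_grid[:, j]
            assert np.all(np.diff(col) <= 3.0)  # small MC slack, Å²

    def test_mass_conservation_after_placement(self):
        base = self._base()
        target = pa_ccs_spheres(base, n_rotations=80, n_points=1500, seed=0).value
        model, _ = place_missing_sphere(base, "b", 7.0, target * 1.03, 5000.0, seed=0)
        assert model.total_mass == pytest.approx(12000 + 9000 + 5000)
        assert model.spheres[-1].kind == "missing"

    def test_scan_argmin_matches_brute_force_grid(self):
        from ccsbuild.ccs import pa_ccs_points

        base = self._base()
        target = pa_ccs_spheres(base, n_rotations=60, n_points=1000, seed=3).value * 1.04
        _, scan = place_missing_sphere(
            base, "b", 6.0, target, 4000.0, n_overlap=7, n_theta=8,
            n_rotations=60, n_points=1000, seed=3,
        )
        u, v = _placement_frame(base, base.spheres[1])
        best = None
        for o in scan.overlaps:
            dist = 10.0 + 6.0 - o * 10.0
            for th in scan.thetas:
                pos = np.array([18.0, 0, 0]) + dist * (np.cos(th) * u + np.sin(th) * v)
                val = pa_ccs_points(
                    np.vstack([base.centers, pos]), np.append(base.radii, 6.0),
                    n_rotations=60, n_points=1000, seed=3,
                ).value
                diff = abs(val - target)
                if best is None or diff < best[0] - 1e-9:
                    best = (diff, float(o), float(th))
        assert abs(scan.best_ccs - target) == pytest.approx(best[0], abs=1e-6)

    def test_infeasible_placement_raises(self):
        base = self._base()
        small = pa_ccs_spheres(base, n_rotations=80, n_points=1500, seed=0).value * 0.8
        with pytest.raises(PlacementInfeasibleError) as exc:
            place_missing_sphere(base, "b", 20.0, small, 5000.0, seed=0)
        assert exc.value.scan is not None

    def test_unknown_anchor_errors(self):
        with pytest.raises(KeyError):
            place_missing_sphere(self._base(), "nope", 5.0, 1000.0, 100.0, seed=0)
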