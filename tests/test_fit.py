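"""Map scoring, rigid docking, hinge refinement, ring rebuild."""

import numpy as np
import pytest

import conformosort.phantom as ph
from conformosort import fit as fm
from conformosort.geometry import RigidTransform, rotation_about_axis
from conformosort.maps import DensityMap, splat_atoms


@pytest.fixture(scope="module")
def subunit(geometry):
    return geometry.all_coords(), geometry.masses


@pytest.fixture(scope="module")
def ring_T(geometry, subunit):
    coords, _ = subunit
    ring, _ = fm.rebuild_ring_c7(coords, geometry)
    return ring


@pytest.fixture(scope="module")
def bottom_ring(geometry):
    return ph.build_state_model("T", "T").coords[7 * geometry.n_atoms:]


@pytest.fixture(scope="module")
def map_ring_T(ring_T):
    d = DensityMap.centered(64, 4.0)
    splat_atoms(ring_T, np.ones(len(ring_T)), d, 9.0)
    return d


class TestCCScore:
    def test_self_map_scores_unity(self, ring_T, map_ring_T):
        cc = fm.cc_score(ring_T, np.ones(len(ring_T)), map_ring_T,
                         resolution_A=9.0)
        assert cc >= 0.999

    def test_negated_map_scores_minus_unity(self, ring_T, map_ring_T):
        neg = map_ring_T.with_grid(-map_ring_T.grid)
        cc = fm.cc_score(ring_T, np.ones(len(ring_T)), neg, resolution_A=9.0)
        assert cc <= -0.999

    def test_rotated_model_scores_strictly_less(self, ring_T, map_ring_T):
        R = rotation_about_axis(np.array([0, 0, 1.0]), 10.0)
        cc_rot = fm.cc_score(ring_T @ R.T, np.ones(len(ring_T)), map_ring_T,
                             resolution_A=9.0)
        cc_ali = fm.cc_score(ring_T, np.ones(len(ring_T)), map_ring_T,
                             resolution_A=9.0)
        assert cc_rot < cc_ali

    def test_equivariance_under_joint_rotation(self, ring_T, map_ring_T):
        """Rotating map and model together by a grid-exact angle preserves cc."""
        from conformosort.maps import flip_map_x180

        R = rotation_about_axis(np.array([1.0, 0, 0]), 180.0)
        cc0 = fm.cc_score(ring_T, np.ones(len(ring_T)), map_ring_T,
                          resolution_A=9.0)
        cc1 = fm.cc_score(ring_T @ R.T, np.ones(len(ring_T)),
                          flip_map_x180(map_ring_T), resolution_A=9.0)
        assert abs(cc0 - cc1) < 1e-6

    def test_model_outside_map_rejected(self, ring_T):
        small = DensityMap.centered(16, 4.0)
        with pytest.raises(ValueError):
            fm.model_mask(ring_T, small, 6.0)


class TestRigidDock:
    def test_round_trip_recovers_placement(self, ring_T, map_ring_T):
        dock = fm.rigid_dock(ring_T, np.ones(len(ring_T)), map_ring_T,
                             resolution_A=9.0, z_start_step_deg=30.0)
        assert not dock.flagged
        from conformosort.geometry import axis_angle_of

        # placement is degenerate modulo the C7 symmetry
        ang = axis_angle_of(dock.transform.R)[1] % (360.0 / 7)
        ang = min(ang, 360.0 / 7 - ang)
        assert ang < 1.0
        assert np.linalg.norm(dock.transform.t) < 2.0  # < 0.5 voxel

    def test_symmetry_degenerate_placements_score_equally(self, ring_T,
                                                          map_ring_T):
        Rz = rotation_about_axis(np.array([0, 0, 1.0]), 360.0 / 7)
        a = fm.cc_score(ring_T, np.ones(len(ring_T)), map_ring_T,
                        resolution_A=9.0)
        b = fm.cc_score(ring_T @ Rz.T, np.ones(len(ring_T)), map_ring_T,
                        resolution_A=9.0)
        assert abs(a - b) < 1e-6

    def test_uniform_map_flagged(self, ring_T):
        flat = DensityMap.centered(64, 4.0).with_grid(np.ones((64,) * 3))
        dock = fm.rigid_dock(ring_T, np.ones(len(ring_T)), flat,
                             resolution_A=9.0)
        assert dock.flagged


class TestHingeRefine:
    def _state_map(self, geometry, tilt, elev, radial=0.0, eq=0.0):
        st = ph.StateParameters("x", tilt_deg=tilt, elevation_deg=elev,
                                radial_shift_A=radial, equatorial_tilt_deg=eq)
        m = ph.build_state_model(st, "T")
        return ph.synthesize_density(m, 4.0, 64, 9.0)

    def test_recovers_en_bloc_tilt_with_monotone_cc(self, geometry, subunit,
                                                    bottom_ring):
        coords, masses = subunit
        dmap = self._state_map(geometry, 35.0, 0.0)
        spec = fm.subunit_rigid_spec(geometry, "two_body")
        f = fm.hinge_refine(fm.RigidBodyFit(RigidTransform.identity(), {}),
                            spec, coords, masses, dmap, n_iter=4,
                            resolution_A=9.0, symmetry_expand=7,
                            context_coords=bottom_ring)
        assert abs(f.hinge_angles["hinge1"] - 35.0) <= 2.0
        assert f.cc >= 0.98
        assert all(b >= a - 1e-12
                   for a, b in zip(f.cc_history, f.cc_history[1:]))

    def test_zero_iterations_leave_fit_unchanged(self, geometry, subunit,
                                                 map_ring_T):
        coords, masses = subunit
        spec = fm.subunit_rigid_spec(geometry, "two_body")
        start = fm.RigidBodyFit(RigidTransform.identity(), {"hinge1": 7.0})
        f = fm.hinge_refine(start, spec, coords, masses, map_ring_T,
                            n_iter=0, resolution_A=9.0, symmetry_expand=7)
        assert f.hinge_angles["hinge1"] == 7.0

    def test_truth_is_a_fixed_point(self, geometry, subunit, map_ring_T,
                                    bottom_ring):
        coords, masses = subunit
        spec = fm.subunit_rigid_spec(geometry, "two_body")
        start = fm.RigidBodyFit(RigidTransform.identity(), {"hinge1": 0.0})
        f = fm.hinge_refine(start, spec, coords, masses, map_ring_T,
                            n_iter=2, resolution_A=9.0, symmetry_expand=7,
                            context_coords=bottom_ring)
        assert abs(f.hinge_angles["hinge1"]) < 0.1

    def test_state_recovery_preset_is_exact_for_the_open_state(
            self, geometry, subunit, bottom_ring):
        coords, masses = subunit
        dmap = self._state_map(geometry, 35.0, 42.0, radial=5.0, eq=22.0)
        spec = fm.subunit_rigid_spec(geometry, "state_recovery")
        f = fm.hinge_refine(fm.RigidBodyFit(RigidTransform.identity(), {}),
                            spec, coords, masses, dmap, n_iter=4,
                            resolution_A=9.0, symmetry_expand=7,
                            joint_scan=("hinge1", "hinge2"),
                            context_coords=bottom_ring)
        assert abs(f.hinge_angles["hinge1"] - 35.0) < 0.5
        assert abs(f.hinge_angles["hinge2"] - 42.0) < 0.5
        assert abs(f.hinge_angles["radial"] - 5.0) < 0.5
        assert f.cc > 0.995


class TestRebuildRing:
    def test_exactly_c7_subunit_reproduces_the_ring(self, geometry, subunit,
                                                    ring_T):
        coords, _ = subunit
        ring, info = fm.rebuild_ring_c7(coords, geometry)
        assert np.abs(ring - ring_T).max() < 1e-9
        assert info["min_intersubunit_distance_A"] > 1.0

    def test_rebuild_is_sevenfold_symmetric_after_hinge_change(self, geometry,
                                                               subunit):
        coords, _ = subunit
        spec = fm.subunit_rigid_spec(geometry, "two_body")
        moved = fm.apply_hinge_angles(coords, spec, {"hinge1": 5.0})
        ring, _ = fm.rebuild_ring_c7(moved, geometry)
        Rz = rotation_about_axis(np.array([0, 0, 1.0]), 360.0 / 7)
        n = len(coords)
        rotated = ring @ Rz.T
        permuted = np.concatenate([ring[((k + 1) % 7) * n:((k + 1) % 7 + 1) * n]
                                   for k in range(7)])
        assert np.abs(rotated - permuted).max() < 1e-9

    def test_lateral_sheet_restoration(self, geometry, subunit, map_ring_T):
        """Snapping the sheet back restores the reference contact exactly
        while barely changing the fit quality."""
        coords, masses = subunit
        spec = fm.subunit_rigid_spec(geometry, "two_body")
        perturbed = fm.apply_hinge_angles(coords, spec, {"hinge1": 4.0})
        # also nudge the sheet away from its reference pose
        ls = geometry.groups["lateral_sheet"]
        perturbed[ls] += np.array([0.8, -0.5, 0.3])
        ring, info = fm.rebuild_ring_c7(perturbed, geometry,
                                        restore_lateral_sheet=True)
        assert info["lateral_sheet_rmsd_A"] < 0.1
        cc_restored = fm.cc_score(ring, np.ones(len(ring)), map_ring_T,
                                  resolution_A=9.0)
        ring_raw, _ = fm.rebuild_ring_c7(perturbed, geometry)
        cc_raw = fm.cc_score(ring_raw, np.ones(len(ring_raw)), map_ring_T,
                             resolution_A=9.0)
        assert abs(cc_restored - cc_raw) < 0.01


def test_spec_validation(geometry):
    spec = fm.subunit_rigid_spec(geometry, "six_body")
    spec.validate(geometry.n_atoms)
    with pytest.raises(ValueError):
        fm.subunit_rigid_spec(geometry, "nonsense")
    bad = fm.subunit_rigid_spec(geometry, "two_body")
    bad.groups["equatorial"] = bad.groups["equatorial"][:-1]
    with pytest.raises(ValueError):
        bad.validate(geometry.n_atoms)
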