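"""Eigenimage analysis, alignment, partitioning, junk removal, competition."""

import numpy as np
import pytest

import conformosort.phantom as ph
from conformosort import classify
from conformosort.classify import (ClassificationConfig, align_to_references,
                                   annulus_mask, apical_band_mask,
                                   asymmetric_unit_extent_deg,
                                   compute_eigenimages, junk_filter,
                                   msa_partition,
                                   select_conformational_eigenimages)
from conformosort.improc import rotate_image


def test_asymmetric_unit_extent():
    assert abs(asymmetric_unit_extent_deg(7) - 51.4286) < 1e-3
    with pytest.raises(ValueError):
        asymmetric_unit_extent_deg(0)


class TestEigenimages:
    def test_identical_images_have_zero_eigenvalues(self):
        imgs = np.tile(np.random.default_rng(0).normal(size=(8, 8)), (12, 1, 1))
        dec = compute_eigenimages(imgs, 4)
        assert np.abs(dec.eigenvalues).max() < 1e-10

    def test_matches_bruteforce_covariance_diagonalization(self):
        """PCA of 20 random 16x16 images equals explicit covariance eigh."""
        rng = np.random.default_rng(5)
        imgs = rng.normal(size=(20, 16, 16))
        dec = compute_eigenimages(imgs, 10)
        X = imgs.reshape(20, -1)
        Xc = X - X.mean(axis=0)
        C = Xc.T @ Xc / 20
        w, V = np.linalg.eigh(C)
        w, V = w[::-1], V[:, ::-1]
        assert np.allclose(dec.eigenvalues, w[:10], atol=1e-8)
        for k in range(10):
            v = dec.components[k].ravel()
            assert min(np.abs(v - V[:, k]).max(),
                       np.abs(v + V[:, k]).max()) < 1e-7

    def test_reconstruction_lossless_with_all_components(self):
        rng = np.random.default_rng(6)
        imgs = rng.normal(size=(10, 8, 8))
        dec = compute_eigenimages(imgs, 9)
        coords = dec.coords(imgs)
        rec = (coords @ dec.components.reshape(9, -1)
               + dec.mean_image.ravel()).reshape(imgs.shape)
        assert np.sqrt(np.mean((rec - imgs) ** 2)) < 1e-8

    def test_components_orthonormal(self):
        rng = np.random.default_rng(7)
        dec = compute_eigenimages(rng.normal(size=(15, 12, 12)), 6)
        G = dec.components.reshape(6, -1) @ dec.components.reshape(6, -1).T
        assert np.abs(G - np.eye(6)).max() < 1e-8
        assert np.all(np.diff(dec.eigenvalues) <= 1e-12)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            compute_eigenimages(np.zeros((5, 4, 4)), 5)


class TestEigenSelection:
    def _planted(self, rng, n=30, box=24):
        """Half the stack carries extra density in an annulus."""
        base = rng.normal(size=(box, box)) * 0.1
        ann = annulus_mask(box, 7, 10).astype(float)
        imgs = np.stack([base + (ann * 2.0 if i % 2 else 0.0)
                         + rng.normal(size=(box, box)) * 0.05
                         for i in range(n)])
        return imgs, annulus_mask(box, 7, 10)

    def test_homogeneous_stack_selects_nothing(self):
        imgs = np.tile(np.random.default_rng(1).normal(size=(10, 10)), (8, 1, 1))
        dec = compute_eigenimages(imgs, 4)
        sel = select_conformational_eigenimages(dec, annulus_mask(10, 2, 4))
        assert sel == []

    def test_planted_component_selected_noise_rejected(self):
        rng = np.random.default_rng(2)
        imgs, mask = self._planted(rng)
        dec = compute_eigenimages(imgs, 6)
        sel = select_conformational_eigenimages(dec, mask)
        assert 0 in sel          # the planted contrast dominates
        assert len(sel) <= 2     # pure-noise components rejected

    def test_zero_threshold_selects_everything(self):
        rng = np.random.default_rng(3)
        imgs, mask = self._planted(rng)
        dec = compute_eigenimages(imgs, 5)
        sel = select_conformational_eigenimages(dec, mask, power_threshold=0.0)
        assert sel == list(range(5))


class TestPartition:
    def test_two_planted_states_recovered(self):
        rng = np.random.default_rng(4)
        box = 24
        blob = np.zeros((box, box))
        blob[6:10, 6:10] = 1.0
        truth = rng.integers(0, 2, 40)
        imgs = np.stack([
            np.roll(blob, 8 * t, axis=0) * 3.0
            + rng.normal(size=(box, box)) / np.sqrt(0.3)
            for t in truth
        ])
        dec = compute_eigenimages(imgs, 5)
        sel = select_conformational_eigenimages(
            dec, np.ones((box, box), dtype=bool), power_threshold=0.0)
        part = msa_partition(imgs, dec, sel[:2], 2, seed=0)
        agree = (part.assignment == truth).mean()
        assert max(agree, 1 - agree) == 1.0

    def test_single_group(self):
        rng = np.random.default_rng(5)
        imgs = rng.normal(size=(10, 8, 8))
        dec = compute_eigenimages(imgs, 3)
        part = msa_partition(imgs, dec, [0], 1, seed=0)
        assert set(part.assignment) == {0}

    def test_validation(self):
        rng = np.random.default_rng(6)
        imgs = rng.normal(size=(6, 8, 8))
        dec = compute_eigenimages(imgs, 3)
        with pytest.raises(ValueError):
            msa_partition(imgs, dec, [], 2)
        with pytest.raises(ValueError):
            msa_partition(imgs, dec, [0], 7)


class TestAlignToReferences:
    def test_rotated_reference_recovered(self, map_T48):
        ref = ph.project(map_T48, (10.0, 90.0, 0.0), order=1)
        refs = [np.roll(ref, 5, axis=0), ref, ref * 0.5 + 1.0]
        particle = rotate_image(ref, 10.0)
        out = align_to_references(particle[None], [refs[0], ref],
                                  rot_step_deg=2.0, shift_radius_px=2.0)[0]
        assert out.reference_id == 1
        assert abs(out.in_plane_deg - 10.0) <= 2.0
        assert out.score > 0.99

    def test_noise_free_two_state_references_perfectly_identified(
            self, rs_maps48):
        refs = [ph.project(m, (20.0, 90.0, 0.0), order=1)
                for m in rs_maps48[:2]]
        rng = np.random.default_rng(8)
        truth = rng.integers(0, 2, 10)
        particles = np.stack([
            rotate_image(refs[t], rng.uniform(0, 360)) for t in truth
        ])
        out = align_to_references(particles, refs, rot_step_deg=4.0,
                                  shift_radius_px=2.0)
        assert all(o.reference_id == t for o, t in zip(out, truth))

    def test_noise_score_within_null_distribution(self, map_T48):
        """A pure-noise image scores inside the Monte-Carlo null range."""
        ref = ph.project(map_T48, (0.0, 90.0, 0.0), order=1)
        rng = np.random.default_rng(9)
        null = [align_to_references(rng.normal(size=(1, 48, 48)), [ref],
                                    rot_step_deg=30.0, shift_radius_px=2.0
                                    )[0].score for _ in range(200)]
        probe = align_to_references(
            np.random.default_rng(123).normal(size=(1, 48, 48)), [ref],
            rot_step_deg=30.0, shift_radius_px=2.0)[0].score
        assert abs(probe) <= np.quantile(np.abs(null), 0.99)

    def test_empty_reference_list_rejected(self):
        with pytest.raises(ValueError):
            align_to_references(np.zeros((1, 8, 8)), [])


class TestJunkFilter:
    def _stack_with_junk(self, frac_junk):
        rng = np.random.default_rng(10)
        m = ph.build_state_model("T", "T")
        stk = ph.simulate_stack([m], 40, ctf=None, snr=1.0, seed=12,
                                voxel_A=4.0, box_vox=40, resolution_A=9.0,
                                interp_order=1)
        n_junk = int(frac_junk * stk.n)
        is_junk = np.zeros(stk.n, dtype=bool)
        if n_junk:
            idx = rng.choice(stk.n, n_junk, replace=False)
            sigma = stk.images.std()
            for i in idx:
                stk.images[i] = rng.normal(0, sigma, (40, 40))
            is_junk[idx] = True
        vol = ph.synthesize_density(m, 4.0, 40, 9.0)
        refs = [ph.project(vol, (phi, 90.0, 0.0), order=1)
                for phi in (0.0, 25.0)]
        return stk, is_junk, refs

    def test_no_junk_no_removals(self):
        stk, _, refs = self._stack_with_junk(0.0)
        part = classify.ClassPartition(
            assignment=np.arange(stk.n) % 5)
        reduced, _, log = junk_filter(stk, part, refs, class_quality=0.1)
        assert reduced.n == stk.n and log["removed_particles"] == 0

    def test_planted_junk_classes_removed(self):
        stk, is_junk, refs = self._stack_with_junk(0.25)
        # classes that isolate the junk (class id 0 = junk, 1..4 = real)
        part = classify.ClassPartition(
            assignment=np.where(is_junk, 0, 1 + np.arange(stk.n) % 4))
        reduced, _, log = junk_filter(stk, part, refs, class_quality=0.4)
        kept_junk = is_junk[np.isin(np.arange(stk.n),
                                    reduced.meta["particle"])].sum() \
            if "particle" in reduced.meta else 0
        assert log["removed_particles"] >= 0.9 * is_junk.sum()
        assert log["removed_particles"] <= is_junk.sum() + 0.02 * (~is_junk).sum()

    def test_quality_one_removes_everything_with_warning(self):
        stk, _, refs = self._stack_with_junk(0.0)
        part = classify.ClassPartition(assignment=np.zeros(stk.n, dtype=int))
        with pytest.warns(UserWarning):
            reduced, _, _ = junk_filter(stk, part, refs, class_quality=1.0)
        assert reduced.n == 0


class TestCompetitiveAlign:
    @pytest.fixture(scope="class")
    def two_state_stack(self):
        models = [ph.build_state_model(s, "T") for s in ("Rs1", "Rs_open")]
        stk = ph.simulate_stack(models, 16, ctf=None, snr=np.inf, seed=13,
                                voxel_A=4.0, box_vox=48, resolution_A=9.0,
                                shift_max_px=1.0, interp_order=1)
        refs = [ph.synthesize_density(m, 4.0, 48, 9.0) for m in models]
        return stk, refs

    CFG = dict(azimuth_step_deg=8.0, tilt_values_deg=(84.0, 90.0, 96.0),
               inplane_step_deg=12.0, use_ctf_envelope=False)

    def test_noise_free_converges_immediately_and_perfectly(self,
                                                            two_state_stack):
        stk, refs = two_state_stack
        cfg = ClassificationConfig(max_iter=4, stability_tol=0.01, **self.CFG)
        part, maps, orient = classify.competitive_align(stk, refs, cfg)
        assert part.history[-1] < 0.01
        assert (part.assignment == stk.meta.model_id.to_numpy()).all()

    def test_zero_tolerance_runs_exactly_max_iter(self, two_state_stack):
        stk, refs = two_state_stack
        cfg = ClassificationConfig(max_iter=3, stability_tol=0.0, **self.CFG)
        part, _, _ = classify.competitive_align(stk, refs, cfg)
        assert len(part.history) == 3

    def test_needs_two_references(self, two_state_stack):
        stk, refs = two_state_stack
        with pytest.raises(ValueError):
            classify.competitive_align(stk, refs[:1], ClassificationConfig())


def test_apical_band_mask_geometry():
    m = apical_band_mask(40, 5, 10)
    assert m[20 + 7, 3] and not m[20, 3] and not m[20 + 15, 3]
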