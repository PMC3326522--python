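"""C7 Fourier reconstruction, FSC resolution estimation, amplitude filtering."""

import numpy as np
import pytest

import conformosort.phantom as ph
from conformosort.geometry import rotation_about_axis
from conformosort.improc import FilterSpec
from conformosort.maps import DensityMap, normalized_cc, rotate_map
from conformosort.reconstruct import (FSCCurve, final_filter, fsc,
                                      reconstruct_c7, resolution_at_threshold,
                                      soft_spherical_mask, split_half_fsc)


@pytest.fixture(scope="module")
def map_T64(model_T):
    # enough box margin that Fourier-domain interpolation stays accurate
    return ph.synthesize_density(model_T, 4.0, 64, 9.0)


@pytest.fixture(scope="module")
def projections_T(map_T64):
    rng = np.random.default_rng(0)
    n = 300
    phis = rng.uniform(0, 360, n)
    thetas = rng.uniform(80, 100, n)
    psis = rng.uniform(0, 360, n)
    proj = ph.Projector(map_T64, order=1)
    imgs = np.stack([proj((a, b, c)) for a, b, c in zip(phis, thetas, psis)])
    ori = {"phi_deg": phis, "theta_deg": thetas, "psi_deg": psis}
    return imgs, ori


class TestReconstruction:
    @staticmethod
    def _bandlimit(dmap):
        # compare at the ~2-pixel band limit: gridding legitimately
        # attenuates the last shells before Nyquist
        return final_filter(dmap, FilterSpec(1e6, 9.0, 1.0))

    def test_round_trip_recovers_the_map(self, map_T64, projections_T):
        imgs, ori = projections_T
        rec = self._bandlimit(reconstruct_c7(imgs, ori, voxel_A=4.0))
        ref = self._bandlimit(map_T64)
        mask = soft_spherical_mask(64) > 0.5
        assert normalized_cc(rec.grid, ref.grid, mask) >= 0.95

    def test_round_trip_with_recorded_shifts(self, map_T64, projections_T):
        imgs, ori = projections_T
        rng = np.random.default_rng(1)
        sh = rng.uniform(-3, 3, (len(imgs), 2))
        shifted = np.stack([ph.fourier_shift(im, s)
                            for im, s in zip(imgs, sh)])
        ori2 = dict(ori)
        ori2["shift_x_px"], ori2["shift_y_px"] = sh[:, 0], sh[:, 1]
        rec = self._bandlimit(reconstruct_c7(shifted, ori2, voxel_A=4.0))
        ref = self._bandlimit(map_T64)
        mask = soft_spherical_mask(64) > 0.5
        assert normalized_cc(rec.grid, ref.grid, mask) >= 0.95

    def test_zero_images_give_zero_map(self):
        imgs = np.zeros((20, 32, 32))
        ori = {"phi_deg": np.linspace(0, 350, 20),
               "theta_deg": np.full(20, 90.0),
               "psi_deg": np.zeros(20)}
        rec = reconstruct_c7(imgs, ori, voxel_A=4.0)
        assert np.abs(rec.grid).max() == 0.0

    def test_linearity(self, projections_T):
        imgs, ori = projections_T
        a = reconstruct_c7(imgs[:40], {k: np.asarray(v)[:40]
                                       for k, v in ori.items()}, voxel_A=4.0)
        b = reconstruct_c7(2.0 * imgs[:40], {k: np.asarray(v)[:40]
                                             for k, v in ori.items()},
                           voxel_A=4.0)
        assert np.allclose(b.grid, 2.0 * a.grid, atol=1e-9)

    def test_symmetrized_map_is_c7_invariant(self, projections_T):
        """Rotating the symmetrized map by 360/7 changes it only at the
        interpolation level (a grid map cannot be exactly invariant under a
        rotation that is not a grid symmetry)."""
        imgs, ori = projections_T
        rec = reconstruct_c7(imgs[:60], {k: np.asarray(v)[:60]
                                         for k, v in ori.items()},
                             voxel_A=4.0, impose_symmetry=True)
        R = rotation_about_axis(np.array([0, 0, 1.0]), 360.0 / 7)
        rot = rotate_map(rec, R, order=3)
        mask = soft_spherical_mask(64, radius_frac=0.4) > 0.9
        num = np.sqrt(np.mean((rot.grid[mask] - rec.grid[mask]) ** 2))
        assert num / rec.grid[mask].std() < 0.12

    def test_underdetermined_warns(self):
        with pytest.warns(UserWarning):
            reconstruct_c7(np.zeros((3, 16, 16)),
                           {"phi_deg": [0, 1, 2], "theta_deg": [90] * 3,
                            "psi_deg": [0] * 3}, voxel_A=4.0)


class TestFSC:
    def test_identical_half_maps_give_unit_fsc(self, projections_T):
        imgs, ori = projections_T
        dup = np.repeat(imgs[:30], 2, axis=0)
        ori2 = {k: np.repeat(np.asarray(v)[:30], 2) for k, v in ori.items()}
        curve = split_half_fsc(dup, ori2, voxel_A=4.0)
        assert np.all(np.abs(curve.correlation - 1.0) < 1e-9)

    def test_symmetric_in_arguments_and_unit_self_fsc(self, map_T48):
        rng = np.random.default_rng(2)
        other = DensityMap(rng.normal(size=(48, 48, 48)), 4.0,
                           map_T48.origin_A)
        ab = fsc(map_T48, other).correlation
        ba = fsc(other, map_T48).correlation
        assert np.allclose(ab, ba, atol=1e-12)
        self_c = fsc(map_T48, map_T48).correlation
        assert np.all(np.abs(self_c - 1.0) < 1e-9)

    def test_independent_noise_decorrelates(self):
        rng = np.random.default_rng(3)
        n = 32
        a = DensityMap.centered(n, 4.0).with_grid(rng.normal(size=(n,) * 3))
        b = DensityMap.centered(n, 4.0).with_grid(rng.normal(size=(n,) * 3))
        curve = fsc(a, b)
        beyond = curve.shell_freq > 0.25 * (0.5 / 4.0)
        assert np.mean(np.abs(curve.correlation[beyond])) < 0.1

    def test_planted_bandlimited_signal_crosses_at_its_band(self):
        """A 12 A band-limited signal + noise yields a 0.5-crossing at
        12 +/- 1 A."""
        rng = np.random.default_rng(4)
        n, vox = 48, 2.0
        f1 = np.fft.fftfreq(n, d=vox)
        freqs = np.sqrt(f1[:, None, None] ** 2 + f1[None, :, None] ** 2
                        + f1[None, None, :] ** 2)
        signal = np.real(np.fft.ifftn(
            np.fft.fftn(rng.normal(size=(n,) * 3))
            * np.exp(-(freqs / (1 / 12.0)) ** 8)))
        signal /= signal.std()
        # noise tuned so the correlated fraction crosses 1/2 near the band edge
        halves = [DensityMap.centered(n, vox).with_grid(
            signal + 1.05 * rng.normal(size=(n,) * 3)) for _ in range(2)]
        curve = fsc(halves[0], halves[1])
        res = resolution_at_threshold(curve, 0.5)
        assert abs(res - 12.0) <= 1.0

    def test_threshold_crossing_linear_interpolation(self):
        curve = FSCCurve(shell_freq=np.array([0.0, 0.1, 0.2]),
                         correlation=np.array([1.0, 0.7, 0.3]))
        # crossing between shells 1 and 2: 0.7 -> 0.3 crosses 0.5 midway
        assert abs(resolution_at_threshold(curve, 0.5) - 1.0 / 0.15) < 1e-9

    def test_too_few_particles_rejected(self):
        with pytest.raises(ValueError):
            split_half_fsc(np.zeros((3, 8, 8)), {"phi_deg": [0, 0, 0]},
                           voxel_A=4.0)


class TestFinalFilter:
    def _sinusoid_map(self, wavelength_A, n=64, vox=2.0):
        cycles = round(n * vox / wavelength_A)
        x = np.arange(n)
        grid = np.sin(2 * np.pi * cycles * x / n)[:, None, None] \
            * np.ones((1, n, n))
        return DensityMap.centered(n, vox).with_grid(grid), n * vox / cycles

    @pytest.mark.parametrize("wavelength,lo,hi", [
        (12.0, 0.98, 1.02),   # band interior untouched
        (40.0, 0.08, 0.12),   # low frequencies reduced to 10%
    ])
    def test_sinusoid_gains(self, wavelength, lo, hi):
        dmap, actual = self._sinusoid_map(wavelength)
        out = final_filter(dmap, FilterSpec(20.0, 8.5, 0.1))
        gain = out.grid.std() / dmap.grid.std()
        assert lo <= gain <= hi

    def test_trivial_spec_is_identity(self):
        rng = np.random.default_rng(5)
        dmap = DensityMap.centered(32, 4.0).with_grid(
            rng.normal(size=(32, 32, 32)))
        out = final_filter(dmap, FilterSpec(20.0, 8.0, 1.0))
        assert np.abs(out.grid - dmap.grid).max() < 1e-8

    def test_invalid_spec_rejected(self):
        dmap = DensityMap.centered(16, 4.0)
        with pytest.raises(ValueError):
            final_filter(dmap, FilterSpec(8.5, 20.0, 0.1))
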