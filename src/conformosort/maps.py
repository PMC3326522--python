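"""3D density grids and the shared Gaussian density kernel.

A :class:`DensityMap` is the unit of reconstruction, fitting and filtering:
a cubic scalar grid with a physical voxel size and an origin.  Grids are
indexed ``(ix, iy, iz)`` so that axis 0 is x, axis 1 is y and axis 2 is z,
with the physical coordinate of voxel ``(i, j, k)`` being
``origin_A + voxel_A * (i, j, k)``.

The Gaussian atom kernel defined here is deliberately the *single* density
model used everywhere: phantom volumes, simulated projections and the
model-to-map cross-correlation of the fitting stage all share it, so a model
scored against a map synthesized from itself is exactly self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class DensityMap:
    grid: np.ndarray  # (n, n, n) float
    voxel_A: float
    origin_A: np.ndarray  # physical coordinate of voxel (0, 0, 0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3 or len(set(self.grid.shape)) != 1:
            raise ValueError("DensityMap grid must be cubic")
        if self.voxel_A <= 0:
            raise ValueError("voxel size must be positive")
        self.origin_A = np.asarray(self.origin_A, dtype=float)

    @property
    def n(self) -> int:
        return self.grid.shape[0]

    @property
    def center_A(self) -> np.ndarray:
        """Physical coordinate of the grid center (the rotation center)."""
        return self.origin_A + self.voxel_A * (self.n / 2.0)

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel_A, self.origin_A.copy())

    def with_grid(self, grid: np.ndarray) -> "DensityMap":
        return DensityMap(grid, self.voxel_A, self.origin_A.copy())

    @classmethod
    def centered(cls, n: int, voxel_A: float) -> "DensityMap":
        """Empty cubic map whose center voxel n/2 sits at the physical origin."""
        origin = -voxel_A * (n / 2.0) * np.ones(3)
        return cls(np.zeros((n, n, n)), voxel_A, origin)


def kernel_sigma_A(resolution_A: float) -> float:
    """Gaussian width whose Fourier amplitude falls to 1/e at 1/resolution.

    The 3D Gaussian exp(-r^2 / 2 sigma^2) has transform exp(-2 pi^2 sigma^2 k^2);
    setting the exponent to 1 at k = 1/resolution gives sigma below.
    """
    return resolution_A / (np.pi * np.sqrt(2.0))


def splat_atoms(
    coords_A: np.ndarray,
    masses: np.ndarray,
    out: DensityMap,
    resolution_A: float,
) -> DensityMap:
    """Accumulate mass-weighted Gaussian atoms into ``out`` (modified in place).

    Each atom integrates to its mass weight: amplitudes are normalized by
    (2 pi)^{3/2} sigma^3 and multiplied by the voxel volume, so the sum of the
    grid times voxel_A^3 equals the total mass up to edge truncation.
    """
    sigma = kernel_sigma_A(resolution_A)
    if resolution_A < 2.0 * out.voxel_A:
        raise ValueError(
            f"resolution {resolution_A} below Nyquist for voxel {out.voxel_A}"
        )
    n = out.n
    vox = out.voxel_A
    half = int(np.ceil(4.0 * sigma / vox))
    amp = vox**3 / ((2.0 * np.pi) ** 1.5 * sigma**3)
    grid = out.grid
    rel = np.arange(-half, half + 1)
    for xyz, m in zip(np.atleast_2d(coords_A), np.atleast_1d(masses)):
        ijk = (xyz - out.origin_A) / vox
        c = np.round(ijk).astype(int)
        if np.any(c - half < 0) or np.any(c + half >= n):
            raise ValueError("atom extends beyond the density box")
        ax = [np.exp(-((rel + c[d] - ijk[d]) * vox) ** 2 / (2 * sigma**2)) for d in range(3)]
        block = m * amp * ax[0][:, None, None] * ax[1][None, :, None] * ax[2][None, None, :]
        grid[
            c[0] - half : c[0] + half + 1,
            c[1] - half : c[1] + half + 1,
            c[2] - half : c[2] + half + 1,
        ] += block
    return out


def rotate_map(dmap: DensityMap, R: np.ndarray, order: int = 1) -> DensityMap:
    """Map resampled at rotated coordinates: output(u) = input(R u), about the center."""
    n = dmap.n
    c = (n / 2.0) * np.ones(3)
    out = ndimage.affine_transform(
        dmap.grid, R, offset=c - R @ c, order=order, mode="constant", cval=0.0,
        prefilter=(order > 1),
    )
    return DensityMap(out, dmap.voxel_A, dmap.origin_A.copy())


def flip_map_x180(dmap: DensityMap) -> DensityMap:
    """Rotate a map by exactly 180 degrees about the x axis through its center.

    A 180-degree rotation maps grid indices onto grid indices, so this is
    exact (no interpolation): (x, y, z) -> (x, -y, -z).
    """
    g = np.roll(dmap.grid[:, ::-1, ::-1], 1, axis=(1, 2))
    return dmap.with_grid(g)


def symmetrize_cn(dmap: DensityMap, n_fold: int, order: int = 1) -> DensityMap:
    """Average a map over the n-fold rotation group about the Z axis."""
    from .geometry import rotation_about_axis

    acc = np.zeros_like(dmap.grid)
    for k in range(n_fold):
        R = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 360.0 * k / n_fold)
        acc += rotate_map(dmap, R, order=order).grid
    return DensityMap(acc / n_fold, dmap.voxel_A, dmap.origin_A.copy())


def normalized_cc(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Plain normalized cross-correlation of two arrays over an optional mask."""
    x = np.asarray(a, dtype=float).ravel()
    y = np.asarray(b, dtype=float).ravel()
    if mask is not None:
        sel = np.asarray(mask).ravel().astype(bool)
        x = x[sel]
        y = y[sel]
    x = x - x.mean()
    y = y - y.mean()
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return 0.0
    return float(np.dot(x, y) / (nx * ny))
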