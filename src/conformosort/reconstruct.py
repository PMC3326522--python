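"""3D reconstruction from side views with C7 symmetry, FSC, and filtering.

Reconstruction is direct Fourier inversion: each particle image's 2D
transform is a central slice of the molecule's 3D transform, oriented by the
particle's Euler angles.  Slices are gridded into the 3D transform with a
separable Kaiser-Bessel-style kernel (width 3 Fourier voxels) alongside a
weight volume; voxels are normalized by their accumulated weight and voxels
never touched by any slice are left at zero.  With side views only
(tilt 80-100 degrees) the slice normals stay near the equatorial plane, but
because every slice plane contains the polar axis the coverage hole is
small; C7 symmetrization (averaging data and weights over the 7 rotations
about Z before normalization) further evens out the azimuthal coverage.

Resolution is estimated by the split-half Fourier shell correlation: the
stack is split even/odd, reconstructed separately, soft-edge masked, and
correlated shell by shell; the resolution is quoted where the curve crosses
0.5 (linear interpolation between shells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import i0

from .geometry import euler_zyz_matrix, rotation_about_axis
from .improc import FilterSpec, raised_cosine_gain
from .maps import DensityMap  # re-exported: the package's 3D grid type

__all__ = [
    "DensityMap", "FSCCurve", "reconstruct_c7", "split_half_fsc", "fsc",
    "final_filter", "resolution_at_threshold", "soft_spherical_mask",
]

N_FOLD = 7


@dataclass
class FSCCurve:
    shell_freq: np.ndarray   # 1/A at each shell center
    correlation: np.ndarray  # in [-1, 1]
    threshold: float = 0.5


# --------------------------------------------------------------------------
# gridding kernel
# --------------------------------------------------------------------------

_KB_BETA = 4.0
_KB_HALF = 1.5  # kernel support half-width in Fourier voxels (width 3)


def _kb_weight(u: np.ndarray) -> np.ndarray:
    """Separable Kaiser-Bessel-style interpolation window on [-1.5, 1.5]."""
    t = np.clip(1.0 - (u / _KB_HALF) ** 2, 0.0, None)
    return np.where(np.abs(u) <= _KB_HALF, i0(_KB_BETA * np.sqrt(t)) / i0(_KB_BETA), 0.0)


def _insert_slices(
    images: np.ndarray,
    rotations: np.ndarray,   # (n, 3, 3)
    shifts: np.ndarray,      # (n, 2) pixels (axis0, axis1 of the image)
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Grid particle transforms into a 3D Fourier volume + weight volume.

    What is gridded is the transform of the *centered* object,
    rho_c(q) = (-1)^(k1+k2) * F2[image](k), which is smooth across Fourier
    voxels (no center-phase oscillation), so a compact interpolation kernel
    is accurate.  The caller restores the corner-origin phase afterwards.
    """
    from itertools import product

    data_r = np.zeros(n**3)
    data_i = np.zeros(n**3)
    weight = np.zeros(n**3)
    k1 = np.fft.fftfreq(n) * n  # integer frequency units
    kx, ky = np.meshgrid(k1, k1, indexing="ij")
    plane = np.stack([kx.ravel(), ky.ravel(), np.zeros(n * n)])  # (3, n*n)
    checker = 1.0 - 2.0 * ((np.abs(kx) + np.abs(ky)).astype(int) % 2)
    fx = kx / n
    fy = ky / n

    chunk = max(1, 2**23 // (n * n))
    for lo in range(0, len(images), chunk):
        imgs = images[lo : lo + chunk]
        R = rotations[lo : lo + chunk]
        s = shifts[lo : lo + chunk]
        F = np.fft.fft2(imgs)
        phase = np.exp(2j * np.pi * (fx[None] * s[:, 0, None, None]
                                     + fy[None] * s[:, 1, None, None]))
        F = F * phase * checker[None]
        q = np.einsum("bij,jk->bik", R, plane)  # (B, 3, n*n)
        base = np.floor(q).astype(int)
        frac = q - base
        vals = F.reshape(len(imgs), -1)
        for dx, dy, dz in product((-1, 0, 1), repeat=3):
            w = (_kb_weight(frac[:, 0] - dx) * _kb_weight(frac[:, 1] - dy)
                 * _kb_weight(frac[:, 2] - dz)).ravel()
            flat = ((((base[:, 0] + dx) % n) * n + (base[:, 1] + dy) % n) * n
                    + (base[:, 2] + dz) % n).ravel()
            weight += np.bincount(flat, w, minlength=n**3)
            data_r += np.bincount(flat, w * vals.real.ravel(), minlength=n**3)
            data_i += np.bincount(flat, w * vals.imag.ravel(), minlength=n**3)
    return (data_r + 1j * data_i).reshape(n, n, n), weight.reshape(n, n, n)


def _symmetrize_fourier(data: np.ndarray, weight: np.ndarray,
                        n_fold: int) -> tuple[np.ndarray, np.ndarray]:
    """Average data and weight volumes over the Cn rotations about kz."""
    from scipy import ndimage

    n = data.shape[0]
    c = (n / 2.0) * np.ones(3)
    ds = np.fft.fftshift(data)
    ws = np.fft.fftshift(weight)
    acc_r = np.zeros_like(ds.real)
    acc_i = np.zeros_like(ds.real)
    acc_w = np.zeros_like(ws)
    for k in range(n_fold):
        R = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 360.0 * k / n_fold)
        if k == 0:
            acc_r += ds.real
            acc_i += ds.imag
            acc_w += ws
            continue
        off = c - R @ c
        args = dict(offset=off, order=1, mode="constant", cval=0.0, prefilter=False)
        acc_r += ndimage.affine_transform(ds.real, R, **args)
        acc_i += ndimage.affine_transform(ds.imag, R, **args)
        acc_w += ndimage.affine_transform(ws, R, **args)
    return (np.fft.ifftshift(acc_r + 1j * acc_i) / n_fold,
            np.fft.ifftshift(acc_w) / n_fold)


def reconstruct_c7(
    images: np.ndarray,
    orientations,
    voxel_A: float,
    box_vox: int | None = None,
    impose_symmetry: bool = True,
    n_fold: int = N_FOLD,
    weight_floor: float = 0.2,
) -> DensityMap:
    """Direct Fourier inversion of a stack of oriented side views.

    ``orientations`` is a table (DataFrame or dict of arrays) with columns
    phi_deg, theta_deg, psi_deg (intrinsic ZYZ) and optional shift_x_px,
    shift_y_px (the shifts that were *applied* to the particles; they are
    undone during insertion).  The result is linear in the images; with
    ``impose_symmetry`` the Fourier volume is averaged over the C7 rotations
    before normalization, which is idempotent on already-symmetric data.
    """
    images = np.asarray(images)
    n = images.shape[1] if box_vox is None else box_vox
    if images.shape[1] != n:
        raise ValueError("box_vox must match the image size")
    if len(images) < 2 * n_fold:
        warnings.warn(
            f"only {len(images)} particles: reconstruction under-determined")

    def col(name, default=0.0):
        try:
            return np.asarray(orientations[name], dtype=float)
        except (KeyError, IndexError):
            return np.full(len(images), default)

    phi, theta, psi = col("phi_deg"), col("theta_deg"), col("psi_deg")
    s0, s1 = col("shift_x_px"), col("shift_y_px")
    rots = np.stack([euler_zyz_matrix(p, t, ps)
                     for p, t, ps in zip(phi, theta, psi)])
    data, weight = _insert_slices(images, rots, np.stack([s0, s1], axis=1), n)
    if impose_symmetry:
        data, weight = _symmetrize_fourier(data, weight, n_fold)
    F = np.where(weight > weight_floor, data / np.maximum(weight, 1e-30), 0.0)
    # restore the corner-origin phase of the DFT (object was gridded centered)
    k1 = np.abs(np.fft.fftfreq(n) * n).astype(int)
    par = (k1[:, None, None] + k1[None, :, None] + k1[None, None, :]) % 2
    F *= 1.0 - 2.0 * par
    grid = np.real(np.fft.ifftn(F)) / voxel_A  # undo the line-integral scaling
    return DensityMap.centered(n, voxel_A).with_grid(grid)


# --------------------------------------------------------------------------
# FSC
# --------------------------------------------------------------------------

def soft_spherical_mask(n: int, radius_frac: float = 0.45,
                        edge_vox: float = 5.0) -> np.ndarray:
    """Spherical mask with a raised-cosine edge."""
    c = n / 2.0
    x = np.arange(n) - c
    r = np.sqrt(x[:, None, None] ** 2 + x[None, :, None] ** 2
                + x[None, None, :] ** 2)
    r0 = radius_frac * n
    t = np.clip((r - r0) / max(edge_vox, 1e-9), 0.0, 1.0)
    return 0.5 + 0.5 * np.cos(np.pi * t)


def fsc(map_a: DensityMap, map_b: DensityMap) -> FSCCurve:
    """Shell-wise normalized correlation of two maps' Fourier transforms."""
    if map_a.grid.shape != map_b.grid.shape:
        raise ValueError("maps must share a grid")
    n = map_a.n
    Fa = np.fft.fftn(map_a.grid)
    Fb = np.fft.fftn(map_b.grid)
    k1 = np.fft.fftfreq(n) * n
    kx, ky, kz = np.meshgrid(k1, k1, k1, indexing="ij")
    shell = np.round(np.sqrt(kx**2 + ky**2 + kz**2)).astype(int)
    nshell = n // 2 + 1
    sel = shell < nshell
    num = np.bincount(shell[sel], np.real(Fa * np.conj(Fb))[sel], nshell)
    da = np.bincount(shell[sel], np.abs(Fa[sel]) ** 2, nshell)
    db = np.bincount(shell[sel], np.abs(Fb[sel]) ** 2, nshell)
    denom = np.sqrt(da * db)
    corr = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
    freqs = np.arange(nshell) / (n * map_a.voxel_A)
    return FSCCurve(shell_freq=freqs, correlation=corr)


def resolution_at_threshold(curve: FSCCurve, threshold: float = 0.5) -> float:
    """Resolution (A) at the first crossing of the threshold.

    Linear interpolation between the shells bracketing the crossing.  If the
    curve never falls below the threshold the last shell's resolution is
    returned (the estimate is Nyquist-limited).
    """
    c = curve.correlation
    f = curve.shell_freq
    for i in range(1, len(c)):
        if c[i] < threshold <= c[i - 1]:
            t = (c[i - 1] - threshold) / (c[i - 1] - c[i])
            freq = f[i - 1] + t * (f[i] - f[i - 1])
            return float(1.0 / freq)
    return float(1.0 / f[-1])


def split_half_fsc(
    images: np.ndarray,
    orientations,
    voxel_A: float,
    masked: bool = True,
    impose_symmetry: bool = True,
) -> FSCCurve:
    """Even/odd split, two reconstructions, soft-edge mask, shell correlation."""
    import pandas as pd

    images = np.asarray(images)
    if len(images) < 4:
        raise ValueError("need at least 2 particles per half")
    ori = pd.DataFrame(orientations).reset_index(drop=True)
    halves = []
    for par in (0, 1):
        idx = np.arange(par, len(images), 2)
        halves.append(reconstruct_c7(images[idx], ori.iloc[idx],
                                     voxel_A=voxel_A,
                                     impose_symmetry=impose_symmetry))
    if masked:
        m = soft_spherical_mask(halves[0].n)
        for h in halves:
            h.grid = h.grid * m
    return fsc(halves[0], halves[1])


# --------------------------------------------------------------------------
# final amplitude filter
# --------------------------------------------------------------------------

def final_filter(dmap: DensityMap,
                 spec: FilterSpec = FilterSpec(20.0, 8.5, 0.1)) -> DensityMap:
    """Band filter correcting over-represented low frequencies.

    Amplitudes at wavelengths longer than ``low_A`` are reduced to
    ``low_freq_factor`` (10% by default) of their original value; the band
    interior is untouched; beyond ``high_A`` a raised-cosine rolls off the
    high-frequency noise.
    """
    spec.validate(dmap.voxel_A)
    n = dmap.n
    f1 = np.fft.fftfreq(n, d=dmap.voxel_A)
    freqs = np.sqrt(f1[:, None, None] ** 2 + f1[None, :, None] ** 2
                    + f1[None, None, :] ** 2)
    gain = raised_cosine_gain(freqs, spec, df=1.0 / (n * dmap.voxel_A),
                              nyquist=0.5 / dmap.voxel_A)
    grid = np.real(np.fft.ifftn(np.fft.fftn(dmap.grid) * gain))
    out = dmap.copy()
    out.grid = grid
    return out
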