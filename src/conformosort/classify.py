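"""Eigenimage-based statistical sorting of heterogeneous particle stacks.

The sorting strategy mirrors classical 2D multivariate statistical analysis:
particles are aligned to reference projections, decomposed into eigenimages
(principal components of the aligned stack), and the components that report
on conformational differences -- those whose variance concentrates where the
apical domains project, at the top and bottom layers of a side view -- are
used to subdivide the stack.  Junk classes are removed by their class
average's similarity to reference side views.  Final state separation is by
competitive alignment: particles are iteratively re-assigned to whichever
3D reference's reprojection matches best, each class is re-reconstructed,
and the loop stops when the fraction of particles changing class falls
below a stability tolerance.  The per-iteration movement history is always
returned, because over-iterating is a real hazard: classes can bleed into
each other while the nominal scores keep improving.

MSA is implemented as plain PCA on pixels, and eigenspace clustering as
seeded k-means; ties in competitive assignment go to the lowest reference
id, so every run is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .maps import DensityMap
from .phantom import ParticleStack, Projector, circular_mask, fourier_shift
from .improc import rotate_image

N_FOLD_DEFAULT = 7


def asymmetric_unit_extent_deg(n_fold: int = N_FOLD_DEFAULT) -> float:
    """Azimuthal extent of the rotational asymmetric unit (360/n)."""
    if n_fold < 1:
        raise ValueError("n_fold must be >= 1")
    return 360.0 / n_fold


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------

@dataclass
class AlignmentParams:
    in_plane_deg: float
    shift_x_px: float
    shift_y_px: float
    reference_id: int
    score: float


@dataclass
class EigenDecomposition:
    mean_image: np.ndarray
    components: np.ndarray  # (k, box, box), unit norm, orthogonal
    eigenvalues: np.ndarray  # non-negative, non-increasing

    def coords(self, images: np.ndarray) -> np.ndarray:
        """Projection of images onto the components (after mean removal)."""
        x = images.reshape(len(images), -1) - self.mean_image.ravel()
        return x @ self.components.reshape(len(self.components), -1).T


@dataclass
class ClassPartition:
    assignment: np.ndarray            # particle -> class id (-1 = junk)
    history: list[float] = field(default_factory=list)

    @property
    def class_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.assignment, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


@dataclass
class ClassificationConfig:
    images_per_msa_class: tuple[int, int] = (6, 10)
    n_subgroups: int = 10
    stability_tol: float = 0.01       # "reasonably stable": <1% moved
    max_iter: int = 9
    eigen_select_mask: np.ndarray | None = None
    # coarse template grid
    azimuth_step_deg: float = 6.0     # over the 51.4 deg asymmetric unit
    tilt_values_deg: tuple = (82.0, 90.0, 98.0)
    inplane_step_deg: float = 10.0
    shift_radius_px: float = 4.0
    topk_refine: int = 24
    coarse_lowpass_nyq: float = 0.5   # Gaussian low-pass (fraction of Nyquist)
                                      # for the shift-free coarse scan; wider
                                      # correlation peaks tolerate residual
                                      # shifts of a few pixels
    # local fine refinement around the coarse optimum
    fine_refine: bool = True
    fine_az_step_deg: float = 2.57
    fine_tilt_step_deg: float = 2.5
    tilt_range_deg: tuple = (80.0, 100.0)
    fine_inplane_offsets: tuple = (-6.0, -3.0, 0.0, 3.0, 6.0)
    fine_neighborhood: int = 2        # +/- fine grid steps searched
    fine_topk: int = 6
    fine_lowpass_nyq: float = 0.7     # milder low-pass for the fine scan
    use_ctf_envelope: bool = True
    # warm-started re-alignment in later competitive iterations: seeded from
    # the previous cycle's orientations, so a narrower search suffices
    warm_neighborhood: int = 1
    warm_inplane_offsets: tuple = (-3.0, 0.0, 3.0)
    # damped reference updates: the rebuilt class map is blended with the
    # previous reference (fraction = damping kept from the old one), which
    # keeps references distinct and suppresses the class-bleeding feedback
    # that full replacement shows at desk-scale particle counts
    reference_damping: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.images_per_msa_class[0] < 2:
            raise ValueError("images_per_msa_class must be >= 2")
        if not (0.0 <= self.stability_tol < 0.5):
            raise ValueError("stability_tol must be in [0, 0.5)")


# --------------------------------------------------------------------------
# masks for eigenimage selection
# --------------------------------------------------------------------------

def annulus_mask(box: int, r_in_px: float, r_out_px: float) -> np.ndarray:
    if r_out_px > box:
        raise ValueError("annulus extends beyond the image")
    c = box / 2.0
    x = np.arange(box) - c
    r2 = x[:, None] ** 2 + x[None, :] ** 2
    return (r2 >= r_in_px**2) & (r2 <= r_out_px**2)


def apical_band_mask(box: int, inner_px: float, outer_px: float) -> np.ndarray:
    """Bands at the top and bottom layers of a side view.

    In this package's projection convention the symmetry axis of a side view
    lies along image axis 0, so the apical layers project to two bands at
    |x - center| between ``inner_px`` and ``outer_px``.
    """
    c = box / 2.0
    d = np.abs(np.arange(box) - c)
    band = (d >= inner_px) & (d <= outer_px)
    return np.repeat(band[:, None], box, axis=1)


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------

def _zero_mean_norm(img: np.ndarray) -> tuple[np.ndarray, float]:
    x = img - img.mean()
    return x, float(np.linalg.norm(x))


def _shift_window(box: int, radius_px: float) -> np.ndarray:
    """Boolean window over the circular-correlation array for small shifts."""
    d = np.minimum(np.arange(box), box - np.arange(box)).astype(float)
    return (d[:, None] ** 2 + d[None, :] ** 2) <= radius_px**2


def _peak_shift(cc: np.ndarray, window: np.ndarray) -> tuple[float, int, int]:
    masked = np.where(window, cc, -np.inf)
    idx = int(np.argmax(masked))
    i, j = divmod(idx, cc.shape[1])
    n = cc.shape[0]
    return masked[i, j], (i if i <= n // 2 else i - n), (j if j <= n // 2 else j - n)


def _parabolic_1d(y0: float, y1: float, y2: float) -> tuple[float, float]:
    """Offset in [-0.5, 0.5] and value of the parabola through 3 samples."""
    d = y0 - 2.0 * y1 + y2
    if d >= 0:
        return 0.0, y1
    off = 0.5 * (y0 - y2) / d
    off = float(np.clip(off, -0.5, 0.5))
    return off, y1 - 0.25 * (y0 - y2) * off


def _subpixel_peak(cc: np.ndarray, window: np.ndarray) -> tuple[float, float, float]:
    """Correlation peak with separable parabolic sub-pixel interpolation."""
    val, i, j = _peak_shift(cc, window)
    n = cc.shape[0]
    di, vi = _parabolic_1d(cc[(i - 1) % n, j % n], val, cc[(i + 1) % n, j % n])
    dj, vj = _parabolic_1d(cc[i % n, (j - 1) % n], val, cc[i % n, (j + 1) % n])
    return max(vi, vj), i + di, j + dj


def _cc_at_subpixel(fx: np.ndarray, T_conj: np.ndarray, sy: float, sx: float,
                    freq1: np.ndarray) -> float:
    """Cross-correlation value at a non-integer shift (Fourier phase dot)."""
    n = len(freq1)
    phase = np.exp(2j * np.pi * (freq1[:, None] * sy + freq1[None, :] * sx))
    return float(np.real(np.sum(fx * T_conj * phase)) / (n * n))


def _mirror_orientation(phi: float, theta: float, psi: float):
    """ZYZ angles of the same view composed with a 180-degree flip about x."""
    from scipy.spatial.transform import Rotation

    from .geometry import euler_zyz_matrix, rotation_about_axis

    S = rotation_about_axis(np.array([1.0, 0.0, 0.0]), 180.0)
    a, b, c = Rotation.from_matrix(
        S @ euler_zyz_matrix(phi, theta, psi)).as_euler("ZYZ", degrees=True)
    return a % 360.0, b, c % 360.0


def align_to_references(
    images: np.ndarray,
    references: list[np.ndarray],
    rot_step_deg: float = 1.0,
    shift_radius_px: float = 3.0,
) -> list[AlignmentParams]:
    """Exhaustive rotation/shift/reference search maximizing normalized CC.

    The recovered parameters satisfy: particle is approximately
    ``shift(rotate(reference[id], in_plane_deg), (sx, sy))``.  The search is
    exhaustive over the discrete grid (no local-search traps); ties go to
    the lowest reference id and smallest rotation.
    """
    if len(references) == 0:
        raise ValueError("empty reference list")
    box = images.shape[1]
    window = _shift_window(box, shift_radius_px)
    rotations = np.arange(0.0, 360.0, rot_step_deg)

    tmpl_ffts = []
    for rid, ref in enumerate(references):
        for rot in rotations:
            t, tn = _zero_mean_norm(rotate_image(ref, rot))
            tmpl_ffts.append((rid, rot, np.conj(np.fft.fft2(t)), tn))

    out = []
    for img in images:
        x, xn = _zero_mean_norm(img)
        fx = np.fft.fft2(x)
        best = None
        for rid, rot, ctf_, tn in tmpl_ffts:
            if tn == 0 or xn == 0:
                continue
            cc = np.real(np.fft.ifft2(fx * ctf_))
            score, sy_, sx_ = _peak_shift(cc, window)
            # cc indices are (axis0 shift, axis1 shift) of template -> particle
            score /= xn * tn
            key = (score, -rid, -rot)
            if best is None or key > best[0]:
                best = (key, AlignmentParams(rot, float(sy_), float(sx_), rid,
                                             float(score)))
        out.append(best[1] if best else AlignmentParams(0, 0, 0, -1, 0.0))
    return out


def center_to_reference(
    images: np.ndarray, reference: np.ndarray, max_shift_px: float = 6.0
) -> tuple[np.ndarray, np.ndarray]:
    """Translation-only centering against a (rotationally symmetrized) reference.

    Returns the re-centered images and the applied shifts (n, 2).  Centering
    against the rotational average of a side-view template removes the bulk
    of the random extraction offsets without committing to an orientation.
    """
    box = images.shape[1]
    window = _shift_window(box, max_shift_px)
    t, tn = _zero_mean_norm(reference)
    ctf_ = np.conj(np.fft.fft2(t))
    centered = np.empty_like(images)
    shifts = np.zeros((len(images), 2))
    for i, img in enumerate(images):
        x, xn = _zero_mean_norm(img)
        cc = np.real(np.fft.ifft2(np.fft.fft2(x) * ctf_))
        _, s0, s1 = _peak_shift(cc, window)
        centered[i] = fourier_shift(img, (-s0, -s1))
        shifts[i] = (s0, s1)
    return centered, shifts


# --------------------------------------------------------------------------
# eigenimages (MSA as PCA)
# --------------------------------------------------------------------------

def compute_eigenimages(images: np.ndarray, n_components: int) -> EigenDecomposition:
    """Principal components of an aligned stack ("eigenimages").

    Eigenvalues are those of the pixel covariance matrix
    C = X^T X / n (mean-subtracted); reconstruction from all components is
    lossless because the data lie in their span.
    """
    n = len(images)
    if n_components >= n:
        raise ValueError("n_components must be < number of images")
    X = images.reshape(n, -1).astype(float)
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the data matrix; right singular vectors are the eigenimages
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = (s**2) / n
    box = images.shape[1]
    return EigenDecomposition(
        mean_image=mean.reshape(box, box),
        components=Vt[:n_components].reshape(n_components, box, box),
        eigenvalues=eigvals[:n_components],
    )


def select_conformational_eigenimages(
    decomp: EigenDecomposition,
    mask: np.ndarray,
    power_threshold: float = 0.5,
    eigenvalue_floor: float = 1e-10,
) -> list[int]:
    """Components whose variance localizes inside the mask.

    The mask is where conformational differences are expected to project
    (the apical layers for side views).  A component is selected when the
    fraction of its power inside the mask reaches ``power_threshold``.
    Components with (relatively) zero eigenvalue are never selected, so a
    homogeneous stack yields an empty selection.
    """
    sel = []
    # absolute variance floor: relative to the stack's mean-image power, so
    # a numerically-zero spectrum (homogeneous stack) selects nothing
    floor = eigenvalue_floor * (np.sum(decomp.mean_image**2) + 1e-300)
    for i, comp in enumerate(decomp.components):
        if decomp.eigenvalues[i] <= floor:
            continue
        total = float(np.sum(comp**2))
        inside = float(np.sum(comp[mask] ** 2))
        if total > 0 and inside / total >= power_threshold:
            sel.append(i)
    return sel


def msa_partition(
    images: np.ndarray,
    decomp: EigenDecomposition,
    selected_ids: list[int],
    n_subgroups: int,
    seed: int = 0,
) -> ClassPartition:
    """K-means clustering on the selected eigenimage coordinates."""
    if len(selected_ids) == 0:
        raise ValueError("no eigenimages selected")
    if n_subgroups > len(images):
        raise ValueError("more subgroups than images")
    coords = decomp.coords(images)[:, selected_ids]
    km = KMeans(n_clusters=n_subgroups, random_state=seed, n_init=10)
    labels = km.fit_predict(coords)
    return ClassPartition(assignment=labels)


def junk_filter(
    stack: ParticleStack,
    partition: ClassPartition,
    references: list[np.ndarray],
    class_quality: float = 0.5,
    rot_step_deg: float = 10.0,
    shift_radius_px: float = 4.0,
) -> tuple[ParticleStack, ClassPartition, dict]:
    """Remove classes whose average does not resemble any reference side view.

    An automated surrogate for visual junk rejection: a class is kept only
    when its average reaches a normalized CC of ``class_quality`` against at
    least one reference projection (over a rotation/shift search).  Returns
    the reduced stack, the partition restricted to it, and a removal log.
    """
    ids = np.unique(partition.assignment)
    keep_classes = []
    log = {}
    for cid in ids:
        members = np.where(partition.assignment == cid)[0]
        avg = stack.images[members].mean(axis=0)
        params = align_to_references(avg[None], references, rot_step_deg,
                                     shift_radius_px)[0]
        log[int(cid)] = {"n": len(members), "best_cc": params.score}
        if params.score >= class_quality:
            keep_classes.append(cid)
        if class_quality >= 1.0:
            warnings.warn("class_quality >= 1 removes every class")
    keep_mask = np.isin(partition.assignment, keep_classes)
    kept_idx = np.where(keep_mask)[0]
    reduced = stack.subset(kept_idx)
    new_part = ClassPartition(assignment=partition.assignment[kept_idx],
                              history=list(partition.history))
    log["removed_particles"] = int((~keep_mask).sum())
    return reduced, new_part, log


# --------------------------------------------------------------------------
# competitive multi-reference alignment
# --------------------------------------------------------------------------

def reference_orientation_grid(config: ClassificationConfig,
                               n_fold: int = N_FOLD_DEFAULT) -> np.ndarray:
    """(phi, theta) side-view grid over one asymmetric unit of azimuth."""
    extent = asymmetric_unit_extent_deg(n_fold)
    azimuths = np.arange(0.0, extent, config.azimuth_step_deg)
    grid = [(phi, theta) for theta in config.tilt_values_deg for phi in azimuths]
    return np.array(grid)


def make_templates(
    references: list[DensityMap], config: ClassificationConfig
) -> tuple[np.ndarray, list[tuple[int, float, float]]]:
    """Reproject every reference over the side-view grid; unit-normalize."""
    from .phantom import project_many

    grid = reference_orientation_grid(config)
    templates, info = [], []
    for rid, ref in enumerate(references):
        projs = project_many(ref, [(phi, theta, 0.0) for phi, theta in grid])
        for (phi, theta), t in zip(grid, projs):
            t, tn = _zero_mean_norm(t)
            if tn > 0:
                t = t / tn
            templates.append(t)
            info.append((rid, phi, theta))
    return np.stack(templates), info


def _assign_to_templates(
    images: np.ndarray, templates: np.ndarray, config: ClassificationConfig,
    template_ref: np.ndarray | None = None,
    template_theta: np.ndarray | None = None,
) -> tuple[np.ndarray, ...]:
    """Best (template, in-plane rotation, small shift) per particle.

    Two-stage search: a fast low-passed zero-shift scan over every template
    at every in-plane rotation (particles are assumed roughly centered),
    then an exact shift search on the top-K candidates.  Returns
    (template_id, rotation, (sy, sx), score) packed as arrays; when
    ``template_ref`` maps templates to reference ids, per-reference bests
    with the same fields are returned as well (shape (n, n_refs, ...)), so
    each reference can later be refined from its own optimum.
    """
    box = images.shape[1]
    rotations = np.arange(0.0, 360.0, config.inplane_step_deg)
    n_t = len(templates)
    # rotated template bank
    bank = np.empty((n_t * len(rotations), box, box))
    for j, rot in enumerate(rotations):
        for i, t in enumerate(templates):
            tr = rotate_image(t, rot)
            tr -= tr.mean()
            nrm = np.linalg.norm(tr)
            bank[j * n_t + i] = tr / nrm if nrm > 0 else tr
    fbank = np.fft.rfft2(bank).reshape(len(bank), -1)
    # Parseval weights: rfft2 duplicates all columns except k=0 and Nyquist
    ncol = box // 2 + 1
    w = np.full(ncol, 2.0)
    w[0] = 1.0
    if box % 2 == 0:
        w[-1] = 1.0
    w2 = np.tile(w, (box, 1)).ravel() / (box * box)
    # Gaussian low-pass for the zero-shift scan (shift tolerance)
    fr = np.fft.fftfreq(box)
    fc = np.fft.rfftfreq(box)
    f2d = np.sqrt(fr[:, None] ** 2 + fc[None, :] ** 2).ravel()
    f0 = 0.5 * config.coarse_lowpass_nyq
    lp2 = np.exp(-(f2d / f0) ** 2)  # applied once to |X|^2-type products
    tnorm_lp = np.sqrt(np.maximum(
        np.sum(w2 * lp2 * np.abs(fbank) ** 2, axis=1), 1e-30))

    window = _shift_window(box, config.shift_radius_px)
    n_img = len(images)
    out_tmpl = np.zeros(n_img, dtype=int)
    out_rot = np.zeros(n_img)
    out_shift = np.zeros((n_img, 2))
    out_score = np.zeros(n_img)
    if template_ref is not None:
        n_ref = int(template_ref.max()) + 1
        if template_theta is None:
            raise ValueError("template_theta required with template_ref")
        tmpl_lobe = (np.asarray(template_theta) > 90.0).astype(int)
        cand_ref = np.asarray([template_ref[c % n_t] for c in range(len(bank))])
        cand_lobe = np.asarray([tmpl_lobe[c % n_t] for c in range(len(bank))])
        # two seeds per reference: one per tilt lobe (theta <= 90 / > 90),
        # because a top-bottom pseudo-symmetric particle has two competing
        # alignment lobes and local refinement cannot jump between them
        r_tmpl = np.zeros((n_img, n_ref, 2), dtype=int)
        r_rot = np.zeros((n_img, n_ref, 2))
        r_shift = np.zeros((n_img, n_ref, 2, 2))
        r_score = np.full((n_img, n_ref, 2), -np.inf)
    else:
        n_ref = 1

    chunk = max(1, 2**22 // (len(bank) + 1))
    for lo in range(0, n_img, chunk):
        imgs = images[lo : lo + chunk]
        X = imgs.reshape(len(imgs), -1)
        Xc = X - X.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Xc, axis=1)
        norms[norms == 0] = 1.0
        fX = np.fft.rfft2(Xc.reshape(imgs.shape)).reshape(len(imgs), -1)
        pnorm_lp = np.sqrt(np.maximum(
            np.sum(w2 * lp2 * np.abs(fX) ** 2, axis=1), 1e-30))
        scores0 = (np.real((fX * (w2 * lp2)) @ np.conj(fbank).T)
                   / pnorm_lp[:, None] / tnorm_lp[None, :])
        for ii in range(len(imgs)):
            # top-K per reference and tilt lobe so every reference competes
            # from its own best orientation on either lobe
            if template_ref is not None:
                k_each = max(2, config.topk_refine // (2 * n_ref))
                cand_list = []
                for rid in range(n_ref):
                    for lobe in range(2):
                        cols = np.where((cand_ref == rid)
                                        & (cand_lobe == lobe))[0]
                        if len(cols) == 0:
                            continue
                        kk = min(k_each, len(cols))
                        sub = cols[np.argpartition(-scores0[ii, cols],
                                                   kk - 1)[:kk]]
                        cand_list.extend(sub.tolist())
            else:
                k = min(config.topk_refine, scores0.shape[1])
                cand_list = np.argpartition(-scores0[ii], k - 1)[:k].tolist()
            fimg = np.fft.fft2(Xc[ii].reshape(box, box))
            best = (-np.inf, 0, 0.0, (0.0, 0.0))
            for cand in sorted(cand_list):
                t_id = cand % n_t
                rot = rotations[cand // n_t]
                cc = np.real(np.fft.ifft2(fimg * np.conj(np.fft.fft2(bank[cand]))))
                sc, s0, s1 = _peak_shift(cc, window)
                sc /= norms[ii]
                key = (sc, -t_id, -rot)
                if key > (best[0], -best[1], -best[2]):
                    best = (sc, t_id, rot, (float(s0), float(s1)))
                if template_ref is not None:
                    rid = template_ref[t_id]
                    lobe = tmpl_lobe[t_id]
                    if sc > r_score[lo + ii, rid, lobe]:
                        r_score[lo + ii, rid, lobe] = sc
                        r_tmpl[lo + ii, rid, lobe] = t_id
                        r_rot[lo + ii, rid, lobe] = rot
                        r_shift[lo + ii, rid, lobe] = (float(s0), float(s1))
            out_score[lo + ii] = best[0]
            out_tmpl[lo + ii] = best[1]
            out_rot[lo + ii] = best[2]
            out_shift[lo + ii] = best[3]
    if template_ref is not None:
        return (out_tmpl, out_rot, out_shift, out_score,
                r_tmpl, r_rot, r_shift, r_score)
    return out_tmpl, out_rot, out_shift, out_score


def _shell_index(box: int) -> np.ndarray:
    k = np.fft.fftfreq(box) * box
    return np.round(np.sqrt(k[:, None] ** 2 + k[None, :] ** 2)).astype(int)


def _ctf_envelope_profiles(stack: ParticleStack,
                           n_shells: int) -> np.ndarray | None:
    """|CTF| per particle on radial Fourier shells (None without defocus)."""
    from .improc import CTFParams, ctf_evaluate

    if "defocus_um" not in stack.meta or not np.isfinite(
            stack.meta["defocus_um"]).all():
        return None
    freqs = np.arange(n_shells) / (stack.box * stack.pixel_A)
    out = np.empty((stack.n, n_shells))
    for i, dz in enumerate(stack.meta["defocus_um"]):
        params = CTFParams(
            defocus_um=dz,
            voltage_kV=stack.attrs.get("voltage_kV", 120.0),
            cs_mm=stack.attrs.get("cs_mm", 2.0),
            amplitude_contrast=stack.attrs.get("amplitude_contrast", 0.07),
            pixel_A=stack.pixel_A)
        out[i] = np.abs(ctf_evaluate(params, freqs))
    return out


class FineBank:
    """Unrotated reference projections on a fine (azimuth, tilt) grid.

    Holds, per reference, the zero-mean projections, their spectra, and
    their radial shell power profiles (for CTF-weighted normalization).
    """

    def __init__(self, references: list[DensityMap],
                 config: ClassificationConfig, n_fold: int = N_FOLD_DEFAULT):
        self.azimuths = np.arange(0.0, asymmetric_unit_extent_deg(n_fold),
                                  config.fine_az_step_deg)
        t0, t1 = config.tilt_range_deg
        self.tilts = np.arange(t0, t1 + 1e-9, config.fine_tilt_step_deg)
        self.box = references[0].n
        shell = _shell_index(self.box)
        self.n_shells = self.box // 2 + 1
        keep = shell < self.n_shells
        self.shell2d = np.where(keep, shell, self.n_shells - 1)
        f0 = 0.5 * config.fine_lowpass_nyq
        self.lp_shell = np.exp(-((np.arange(self.n_shells) / self.box) / f0) ** 2)
        self.images = []   # (n_ref, n_az, n_tilt) -> image
        self.spectra = []  # full 2D FFTs (selection stage uses rfft half)
        self.rspectra = []
        self.shell_power = []
        from .phantom import project_many

        cells = [(az, tilt, 0.0) for az in self.azimuths for tilt in self.tilts]
        for ref in references:
            imgs = project_many(ref, cells).reshape(
                len(self.azimuths), len(self.tilts), self.box, self.box)
            imgs -= imgs.mean(axis=(-2, -1), keepdims=True)
            F = np.fft.fft2(imgs)
            pw = np.zeros((len(self.azimuths), len(self.tilts), self.n_shells))
            absF2 = np.abs(F) ** 2
            for s in range(self.n_shells):
                m = self.shell2d == s
                pw[..., s] = absF2[..., m].sum(axis=-1)
            self.images.append(imgs)
            self.spectra.append(F)
            self.rspectra.append(np.fft.rfft2(imgs))
            self.shell_power.append(pw)
        self.rshell2d = self.shell2d[:, : self.box // 2 + 1]

    def neighborhood(self, phi: float, theta: float, k: int):
        n_az = len(self.azimuths)
        ia0 = (int(np.round(phi / (self.azimuths[1] - self.azimuths[0])))
               % n_az if n_az > 1 else 0)
        it0 = int(np.clip(np.round((theta - self.tilts[0])
                                   / (self.tilts[1] - self.tilts[0])
                                   if len(self.tilts) > 1 else 0),
                          0, len(self.tilts) - 1))
        ias = [(ia0 + d) % n_az for d in range(-k, k + 1)]  # azimuth is periodic
        its = range(max(0, it0 - k), min(len(self.tilts), it0 + k + 1))
        return [(ia, it) for ia in sorted(set(ias)) for it in its]


def refine_assignments(
    stack: ParticleStack,
    references: list[DensityMap],
    seeds: dict,
    config: ClassificationConfig,
    bank: FineBank | None = None,
) -> "pd.DataFrame":
    """Per-reference local refinement of coarse orientation assignments.

    Each reference (and each tilt lobe of the pseudo-symmetric alignment
    ambiguity) is refined independently from its *own* coarse optimum: a
    fine local grid of (azimuth, tilt, in-plane) around the seed is scored
    with a full small-shift correlation and sub-pixel peak interpolation,
    with the reference spectra weighted by the particle's |CTF| envelope
    (matched filtering) when defocus metadata is available.  The state
    decision is then made by scoring every reference at the winning
    *common* orientation and sub-pixel shift, so noise overlapping the
    structure shared by all states cancels in the score differences and
    only the state-distinguishing density votes.  Returns the refined
    orientation table with the winning reference id as ``class_id``.
    """
    import pandas as pd

    if bank is None:
        bank = FineBank(references, config)
    box = stack.box
    window = _shift_window(box, config.shift_radius_px)
    win_flat = np.where(window.ravel())[0]
    envelopes = (_ctf_envelope_profiles(stack, bank.n_shells)
                 if config.use_ctf_envelope else None)
    az_wrap = asymmetric_unit_extent_deg()
    n_ref = len(references)
    n_lobe = seeds["phi_deg"].shape[2] if seeds["phi_deg"].ndim == 3 else 1
    freq1 = np.fft.fftfreq(box)

    rows = []
    for i in range(stack.n):
        img = stack.images[i]
        env = envelopes[i] if envelopes is not None else None
        env2d = env[bank.shell2d] if env is not None else None
        env_sq = env**2 if env is not None else None
        x = img - img.mean()
        xn = np.linalg.norm(x)
        fx = np.fft.fft2(x)
        if xn == 0:
            rows.append({"particle": i, "class_id": 0, "phi_deg": 0.0,
                         "theta_deg": 90.0, "psi_deg": 0.0,
                         "shift_x_px": 0.0, "shift_y_px": 0.0, "score": 0.0})
            continue

        # gather fine candidates for every (reference, lobe) seed, grouped
        # by in-plane angle (quantized to the offset step so seeds share
        # rotated copies of the particle); residual shifts are absorbed by
        # the correlation search window
        astep = max(abs(np.diff(config.fine_inplane_offsets)).min(), 1.0)
        by_alpha: dict[float, set] = {}
        for rid in range(n_ref):
            for lobe in range(n_lobe):
                if not np.isfinite(seeds["score"][i, rid, lobe]):
                    continue
                phi0 = seeds["phi_deg"][i, rid, lobe] % az_wrap
                theta0 = seeds["theta_deg"][i, rid, lobe]
                psi0 = seeds["psi_deg"][i, rid, lobe]
                a0 = astep * round(((-psi0) % 360.0) / astep)
                nb = bank.neighborhood(phi0, theta0, config.fine_neighborhood)
                for off in config.fine_inplane_offsets:
                    alpha = (a0 + off) % 360.0
                    entry = by_alpha.setdefault(alpha, set())
                    entry.update((rid, ia, it) for ia, it in nb)
        if not by_alpha:
            rows.append({"particle": i, "class_id": 0, "phi_deg": 0.0,
                         "theta_deg": 90.0, "psi_deg": 0.0,
                         "shift_x_px": 0.0, "shift_y_px": 0.0, "score": 0.0})
            continue
        cand_keys = []
        peak_list = []
        tns_list = []
        renv2d = env2d[:, : box // 2 + 1] if env2d is not None else None
        for alpha, rit_set in by_alpha.items():
            pr = rotate_image(img, -alpha)
            pr = pr - pr.mean()
            Pc = np.conj(np.fft.rfft2(pr))
            if renv2d is not None:
                Pc = Pc * renv2d
            for rid in range(n_ref):
                idx = [(ia, it) for r, ia, it in rit_set if r == rid]
                if not idx:
                    continue
                ias = np.array([a for a, _ in idx])
                its = np.array([t for _, t in idx])
                prods = bank.rspectra[rid][ias, its] * Pc[None]
                ccs = np.fft.irfft2(prods, s=(box, box)).reshape(len(idx), -1)
                peaks = ccs[:, win_flat].max(axis=1)
                pw = bank.shell_power[rid][ias, its]
                tns = (np.sqrt(pw @ env_sq) if env_sq is not None
                       else np.sqrt(pw.sum(axis=1))) / box
                peak_list.append(peaks)
                tns_list.append(tns)
                cand_keys.extend((rid, ia, it, alpha) for ia, it in idx)
        peak_vals = np.concatenate(peak_list)
        tns = np.concatenate(tns_list)
        approx = peak_vals / np.maximum(tns * xn, 1e-30)

        # exact sub-pixel re-scoring of the best candidate per reference and
        # tilt lobe, then a per-lobe common-orientation state decision
        def exact(rid, ia, it, alpha):
            t = rotate_image(bank.images[rid][ia, it], alpha)
            t = t - t.mean()
            T = np.fft.fft2(t)
            if env2d is not None:
                T = T * env2d
            tn = np.linalg.norm(np.fft.ifft2(T).real)
            if tn == 0:
                return None
            cc = np.real(np.fft.ifft2(fx * np.conj(T)))
            sc, sy, sx = _subpixel_peak(cc, window)
            return sc / (xn * tn), float(sy), float(sx)

        tilt_mid = 0.5 * (bank.tilts[0] + bank.tilts[-1])
        best = None
        best_rl = {}  # (rid, lobe) -> (score, ia, it, alpha, (sy, sx))
        order = np.argsort(-approx, kind="stable")
        for j in order:
            rid, ia, it, alpha = cand_keys[j]
            lobe = int(bank.tilts[it] > tilt_mid)
            if (rid, lobe) in best_rl:
                continue
            res = exact(rid, ia, it, alpha)
            if res is None:
                continue
            sc, sy, sx = res
            best_rl[(rid, lobe)] = (sc, ia, it, alpha, (sy, sx))
            key = (sc, -rid)
            if best is None or key > best[0]:
                best = (key, rid, ia, it, alpha, (sy, sx))
            if len(best_rl) == 2 * n_ref:
                break
        _, rid, ia, it, alpha, (sy, sx) = best

        # Resolve the top-bottom pseudo-symmetry with a *derived* mirror
        # test: compare the winner orientation against its exact flip
        # (rotation by pi about x composed in), snapped to the fine grid.
        # Unlike the lobe-vs-lobe maximum (two independently noise-maxed
        # searches), this is a clean two-template matched filter on the
        # large flipped-vs-unflipped density difference.
        phi_w = float(bank.azimuths[ia])
        th_w = float(bank.tilts[it])
        psi_w = (-alpha) % 360.0
        pm, tm, cm_ = _mirror_orientation(phi_w, th_w, psi_w)
        lobe_win = int(th_w > tilt_mid)
        if bank.tilts[0] - 1e-6 <= tm <= bank.tilts[-1] + 1e-6:
            nb_m = bank.neighborhood(pm % az_wrap, tm, 0)
            ia_m, it_m = nb_m[0]
            res_m = exact(rid, ia_m, it_m, (-cm_) % 360.0)
            if res_m is not None and res_m[0] > best[0][0]:
                lobe_win = int(bank.tilts[it_m] > tilt_mid)

        if n_ref > 1:
            # state decision at the winning lobe's best common orientation,
            # each reference with its own sub-pixel shift optimum: the
            # common orientation cancels the noise overlapping the shared
            # structure; the per-reference shift peak keeps the decision
            # robust to the ~1 px localization noise
            anchors = [v for k, v in best_rl.items() if k[1] == lobe_win]
            if not anchors:
                anchors = list(best_rl.values())
            a_val = max(anchors, key=lambda v: v[0])
            _, ia_l, it_l, alpha_l, _ = a_val
            common = {}
            for rid2 in range(n_ref):
                res = exact(rid2, ia_l, it_l, alpha_l)
                if res is not None:
                    common[rid2] = res[0]
            margin = 0.0
            if common:
                rid = min(common, key=lambda r: (-common[r], r))
                others = [v for r, v in common.items() if r != rid]
                if others:
                    margin = common[rid] - max(others)
                cands_rid = [v for k, v in best_rl.items()
                             if k[0] == rid and k[1] == lobe_win]
                if not cands_rid:
                    cands_rid = [v for k, v in best_rl.items() if k[0] == rid]
                if cands_rid:
                    _, ia, it, alpha, (sy, sx) = max(cands_rid,
                                                     key=lambda v: v[0])
        else:
            margin = 0.0
        final_score = max((v[0] for k, v in best_rl.items() if k[0] == rid),
                          default=float(best[0][0]))
        rows.append({
            "particle": i, "class_id": rid,
            "phi_deg": float(bank.azimuths[ia]),
            "theta_deg": float(bank.tilts[it]),
            "psi_deg": (-alpha) % 360.0,
            "shift_x_px": sy, "shift_y_px": sx,
            "score": float(final_score),
            "margin": float(margin),
        })
    return pd.DataFrame(rows)


def assign_orientations(
    stack: ParticleStack,
    references: list[DensityMap],
    config: ClassificationConfig,
) -> "pd.DataFrame":
    """Coarse template matching followed by per-reference fine refinement."""
    templates, info = make_templates(references, config)
    template_ref = np.array([rid for rid, _, _ in info])
    template_theta = np.array([theta for _, _, theta in info])
    res = _assign_to_templates(stack.images, templates, config,
                               template_ref=template_ref,
                               template_theta=template_theta)
    tmpl, rot, shift, score, r_tmpl, r_rot, r_shift, r_score = res
    orient = orientations_from_assignment(tmpl, rot, shift, info)
    orient["class_id"] = [info[t][0] for t in tmpl]
    orient["score"] = score
    if not config.fine_refine:
        return orient
    phis = np.array([info[t][1] for t in r_tmpl.ravel()]).reshape(r_tmpl.shape)
    thetas = np.array([info[t][2] for t in r_tmpl.ravel()]).reshape(r_tmpl.shape)
    seeds = {
        "phi_deg": phis,
        "theta_deg": thetas,
        "psi_deg": (-r_rot) % 360.0,
        "shift": r_shift,
        "score": r_score,
    }
    return refine_assignments(stack, references, seeds, config)


def orientations_from_assignment(
    tmpl_ids: np.ndarray, rots: np.ndarray, shifts: np.ndarray,
    info: list[tuple[int, float, float]],
) -> "pd.DataFrame":
    """Per-particle Euler angles and shifts implied by a template assignment.

    A particle matching template (phi, theta, 0) rotated in-plane by alpha
    and shifted by s was projected at (phi, theta, psi = -alpha) and shifted
    by s (see the projection convention check in the test suite).
    """
    import pandas as pd

    rows = []
    for i, (tid, rot) in enumerate(zip(tmpl_ids, rots)):
        rid, phi, theta = info[tid]
        rows.append({
            "particle": i, "class_id": rid, "phi_deg": phi, "theta_deg": theta,
            "psi_deg": (-rot) % 360.0,
            "shift_x_px": shifts[i, 0], "shift_y_px": shifts[i, 1],
        })
    return pd.DataFrame(rows)


def flip_orientations(orient: "pd.DataFrame", rows=None) -> "pd.DataFrame":
    """Compose selected particles' orientations with a 180-degree flip about x.

    A top-bottom symmetric reference cannot distinguish a view from "above"
    from the flipped view from "below"; composing with the flip moves an
    assignment to the other member of that pair.  Alignment shifts are
    zeroed for flipped rows (their frame changed; they are re-estimated by
    the next alignment pass).
    """
    from scipy.spatial.transform import Rotation

    from .geometry import euler_zyz_matrix, rotation_about_axis

    out = orient.copy()
    S = rotation_about_axis(np.array([1.0, 0.0, 0.0]), 180.0)
    idx = out.index if rows is None else rows
    for i in idx:
        R = euler_zyz_matrix(out.at[i, "phi_deg"], out.at[i, "theta_deg"],
                             out.at[i, "psi_deg"])
        a, b, c = Rotation.from_matrix(S @ R).as_euler("ZYZ", degrees=True)
        out.at[i, "phi_deg"] = a % 360.0
        out.at[i, "theta_deg"] = b
        out.at[i, "psi_deg"] = c % 360.0
        out.at[i, "shift_x_px"] = 0.0
        out.at[i, "shift_y_px"] = 0.0
    return out


def competitive_align(
    stack: ParticleStack,
    initial_references: list[DensityMap],
    config: ClassificationConfig | None = None,
) -> tuple[ClassPartition, list[DensityMap], "pd.DataFrame"]:
    """Iterative competitive alignment against evolving 3D references.

    Each cycle reprojects every reference over the side-view angular grid,
    assigns every particle to its best-matching reference/orientation, and
    reconstructs each class with C7 symmetry.  Iteration stops when the
    fraction of particles that changed class drops below
    ``config.stability_tol``, or at ``config.max_iter``.  The movement
    history is returned so over-iteration (class bleeding) can be detected
    by the caller.  An emptied class is reported by a warning and keeps its
    previous map.

    Returns (partition, final per-class maps, per-particle orientation table).
    """
    from .reconstruct import reconstruct_c7

    if len(initial_references) < 2:
        raise ValueError("competitive alignment needs >= 2 references")
    config = config or ClassificationConfig()
    refs = list(initial_references)
    voxel = refs[0].voxel_A

    orient = assign_orientations(stack, refs, config)
    assign = orient["class_id"].to_numpy()

    from dataclasses import replace as dc_replace

    warm_config = dc_replace(
        config,
        fine_neighborhood=config.warm_neighborhood,
        fine_inplane_offsets=config.warm_inplane_offsets)

    history: list[float] = []
    margins = orient["margin"].to_numpy() if "margin" in orient else None
    for _ in range(config.max_iter):
        # rebuild references from the current assignment; to resist class
        # bleeding (references blending together and then attracting each
        # other's particles), each class is reconstructed from its
        # highest-margin half -- the members most distinctly claimed by it
        for rid in range(len(refs)):
            members = np.where(assign == rid)[0]
            if len(members) == 0:
                warnings.warn(f"class {rid} emptied out (over-splitting?)")
                continue
            if margins is not None and len(members) >= 40:
                order = members[np.argsort(-margins[members])]
                members = np.sort(order[: max(20, len(members) // 2)])
            rec = reconstruct_c7(
                stack.images[members],
                orient.iloc[members].reset_index(drop=True), voxel_A=voxel)
            lam = 1.0 - config.reference_damping
            scale = refs[rid].grid.std() / max(rec.grid.std(), 1e-12)
            refs[rid] = refs[rid].with_grid(
                (1.0 - lam) * refs[rid].grid + lam * scale * rec.grid)
        # warm re-alignment: every reference searches the neighborhood of
        # the previous cycle's orientation estimate
        n_ref = len(refs)
        seeds = {
            "phi_deg": np.tile(orient["phi_deg"].to_numpy()[:, None, None],
                               (1, n_ref, 1)),
            "theta_deg": np.tile(orient["theta_deg"].to_numpy()[:, None, None],
                                 (1, n_ref, 1)),
            "psi_deg": np.tile(orient["psi_deg"].to_numpy()[:, None, None],
                               (1, n_ref, 1)),
            "shift": np.tile(
                orient[["shift_x_px", "shift_y_px"]].to_numpy()[:, None, None, :],
                (1, n_ref, 1, 1)),
            "score": np.zeros((stack.n, n_ref, 1)),
        }
        orient = refine_assignments(stack, refs, seeds, warm_config)
        margins = orient["margin"].to_numpy() if "margin" in orient else None
        new_assign = orient["class_id"].to_numpy()
        moved = float(np.mean(new_assign != assign))
        history.append(moved)
        assign = new_assign
        if moved < config.stability_tol:
            break

    return ClassPartition(assignment=assign, history=history), refs, orient
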