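"""Constrained multi-domain fitting of pseudo-atomic models into density maps.

The protocol is a deterministic stand-in for simulated-annealing flexible
fitting: a global 6-degree-of-freedom rigid docking, followed by cyclic
line-search over hinge angles.  The model is partitioned into named rigid
groups connected by hinges forming a tree rooted at the equatorial domain;
each sweep visits every hinge in tree order and golden-section-searches its
angle (within bounds) to maximize the real-space cross-correlation between
the map and a density simulated from the moved model.  Because a new angle
is accepted only when it improves the score, the cross-correlation is
monotone non-decreasing by construction, and connectivity is preserved
exactly: a child group's pivot rides with its parent.

The density kernel used for scoring is the same Gaussian kernel used to
synthesize phantom maps, so a model scored against a map generated from
itself is exactly self-consistent (cc -> 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize, minimize_scalar
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform, kabsch, rotation_about_axis
from .maps import DensityMap, normalized_cc, splat_atoms
from .phantom import DELTA_DEG, N_FOLD, SubunitGeometry, Z_AXIS


# --------------------------------------------------------------------------
# rigid group specification
# --------------------------------------------------------------------------

@dataclass
class Hinge:
    name: str
    pivot: np.ndarray          # reference-frame pivot point (A)
    axis: np.ndarray           # unit axis in the reference frame
    parent: str
    child: str
    bounds: tuple[float, float] = (-60.0, 60.0)
    kind: str = "rotation"     # or "slide": translation along the axis (A)


@dataclass
class RigidGroupSpec:
    """Named rigid groups + hinge tree rooted at the equatorial group."""

    groups: dict[str, np.ndarray]
    hinges: list[Hinge]
    root: str = "equatorial"

    def validate(self, n_atoms: int) -> None:
        idx = [v for v in self.groups.values() if len(v)]
        all_idx = np.concatenate(idx)
        if len(all_idx) != n_atoms or len(np.unique(all_idx)) != n_atoms:
            raise ValueError("groups must partition the atom set")
        if any(h.child == self.root for h in self.hinges):
            raise ValueError("root group cannot be a hinge child")
        names = [h.name for h in self.hinges]
        if len(set(names)) != len(names):
            raise ValueError("hinge names must be unique")
        for h in self.hinges:
            if h.parent not in self.groups or h.child not in self.groups:
                raise ValueError(f"hinge {h.name} references unknown group")

    def ordered_hinges(self) -> list[Hinge]:
        """Hinges in parent-before-child order.

        A child may carry several chained degrees of freedom (e.g. an
        elevation rotation followed by a radial slide); chained entries keep
        their list order.
        """
        done = {self.root}
        remaining = list(self.hinges)
        out = []
        while remaining:
            progressed = False
            for h in remaining:
                ok = (h.child in done if h.parent == h.child
                      else h.parent in done)
                if ok:
                    out.append(h)
                    done.add(h.child)
                    remaining.remove(h)
                    progressed = True
                    break
            if not progressed:
                raise ValueError("hinge graph is not a tree rooted at root")
        return out

    def descendants(self, group: str) -> list[str]:
        out = [group]
        for h in self.hinges:
            if h.parent == group:
                out.extend(self.descendants(h.child))
        return out


def subunit_rigid_spec(geo: SubunitGeometry, preset: str = "two_body") -> RigidGroupSpec:
    """Named rigid-group presets for one subunit.

    ``two_body``: equatorial | intermediate+apical about hinge 1 -- the
    first-stage schedule.  ``three_domain`` adds the apical/intermediate
    split about hinge 2.  ``six_body`` additionally frees helix I, helices
    K+L and the lateral-sheet edge on their own local pivots for the
    finer-grained second stage.
    """
    sl = geo.domain_slices
    eq = np.arange(sl["equatorial"].start, sl["equatorial"].stop)
    im = np.arange(sl["intermediate"].start, sl["intermediate"].stop)
    ap = np.arange(sl["apical"].start, sl["apical"].stop)
    h1 = Hinge("hinge1", geo.hinge1_point, geo.hinge1_axis,
               "equatorial", "intermediate+apical" if preset == "two_body"
               else "intermediate")
    if preset == "two_body":
        return RigidGroupSpec(
            groups={"equatorial": eq, "intermediate+apical": np.concatenate([im, ap])},
            hinges=[h1])
    h2 = Hinge("hinge2", geo.hinge2_point, geo.hinge2_axis,
               "intermediate", "apical")
    if preset == "three_domain":
        return RigidGroupSpec(
            groups={"equatorial": eq, "intermediate": im, "apical": ap},
            hinges=[h1, h2])
    if preset == "state_recovery":
        # the full conformational-state parameterization: equatorial pivot
        # about the inter-ring contact, en-bloc tilt about hinge 1 (anchored
        # in the reference frame, as in the generator), apical elevation
        # about the tilted hinge 2, and the radial slide of the apical
        # domain along its current local radial axis
        xhat = np.array([1.0, 0.0, 0.0])
        return RigidGroupSpec(
            groups={"base": np.array([], dtype=int), "equatorial": eq,
                    "intermediate": im, "apical": ap},
            hinges=[
                Hinge("eq_pivot", geo.eq_pivot_point, geo.eq_pivot_axis,
                      "base", "equatorial", bounds=(-30.0, 30.0)),
                Hinge("hinge1", geo.hinge1_point, geo.hinge1_axis,
                      "base", "intermediate"),
                Hinge("hinge2", geo.hinge2_point, geo.hinge2_axis,
                      "intermediate", "apical"),
                Hinge("radial", np.zeros(3), xhat, "apical", "apical",
                      bounds=(-10.0, 10.0), kind="slide"),
            ], root="base")
    if preset == "six_body":
        hi = geo.groups["helixI"]
        kl = geo.groups["helixKL"]
        ls = geo.groups["lateral_sheet"]
        ap_rest = np.setdiff1d(ap, np.concatenate([hi, kl]))
        eq_rest = np.setdiff1d(eq, ls)
        coords = np.concatenate([geo.equatorial_atoms, geo.intermediate_atoms,
                                 geo.apical_atoms])
        tang = np.array([0.0, 1.0, 0.0])
        return RigidGroupSpec(
            groups={"equatorial": eq_rest, "intermediate": im,
                    "apical": ap_rest, "helixI": hi, "helixKL": kl,
                    "lateral_sheet": ls},
            hinges=[
                Hinge("hinge1", geo.hinge1_point, geo.hinge1_axis,
                      "equatorial", "intermediate"),
                Hinge("hinge2", geo.hinge2_point, geo.hinge2_axis,
                      "intermediate", "apical"),
                Hinge("helixI", coords[hi[0]], tang, "apical", "helixI",
                      bounds=(-20.0, 20.0)),
                Hinge("helixKL", coords[kl[0]], tang, "apical", "helixKL",
                      bounds=(-20.0, 20.0)),
                Hinge("lateral_sheet", coords[ls[0]], tang,
                      "equatorial", "lateral_sheet", bounds=(-15.0, 15.0)),
            ])
    raise ValueError(f"unknown preset {preset!r}")


def apply_hinge_angles(
    coords0: np.ndarray,
    spec: RigidGroupSpec,
    angles: dict[str, float],
    base: RigidTransform | None = None,
) -> np.ndarray:
    """Pose reference coordinates with the given hinge angles and placement.

    Hinges are applied parent-first; a hinge's pivot and axis are carried
    along by every transform already applied to its parent, so group
    connectivity is exact.
    """
    base = base or RigidTransform.identity()
    T: dict[str, RigidTransform] = {spec.root: base}
    for h in spec.ordered_hinges():
        # a chained dof composes onto the child's transform so far
        ref = T[h.child] if (h.child in T and h.parent == h.child) \
            else T[h.parent]
        axis = ref.R @ h.axis
        axis = axis / np.linalg.norm(axis)
        val = angles.get(h.name, 0.0)
        if h.kind == "slide":
            op = RigidTransform.translation(val * axis)
        else:
            op = RigidTransform.about_point(axis, val, ref.apply(h.pivot))
        T[h.child] = op.compose(ref)
    out = np.empty_like(coords0)
    for g, idx in spec.groups.items():
        if len(idx):
            out[idx] = T[g].apply(coords0[idx])
    return out


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------

def model_mask(coords: np.ndarray, dmap: DensityMap, mask_radius_A: float) -> np.ndarray:
    """Boolean mask of voxels within ``mask_radius_A`` of any atom."""
    occ = np.zeros(dmap.grid.shape, dtype=bool)
    ijk = np.round((coords - dmap.origin_A) / dmap.voxel_A).astype(int)
    if np.any(ijk < 0) or np.any(ijk >= dmap.n):
        raise ValueError("model extends outside the map")
    occ[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
    r = int(np.ceil(mask_radius_A / dmap.voxel_A))
    ball = np.zeros((2 * r + 1,) * 3, dtype=bool)
    x = np.arange(-r, r + 1)
    ball[(x[:, None, None] ** 2 + x[None, :, None] ** 2
          + x[None, None, :] ** 2) <= r * r] = True
    return ndimage.binary_dilation(occ, structure=ball)


def simulate_model_density(coords, masses, like: DensityMap,
                           resolution_A: float) -> DensityMap:
    out = DensityMap(np.zeros_like(like.grid), like.voxel_A, like.origin_A.copy())
    splat_atoms(coords, masses, out, resolution_A)
    return out


def cc_score(
    coords: np.ndarray,
    masses: np.ndarray,
    dmap: DensityMap,
    resolution_A: float = 10.0,
    mask_radius_A: float = 6.0,
    mask: np.ndarray | None = None,
) -> float:
    """Normalized real-space CC between the map and the model's density.

    The correlation is evaluated over voxels within ``mask_radius_A`` of any
    atom (or an explicit precomputed ``mask``), so empty regions of the box
    do not dilute the score.
    """
    if mask is None:
        mask = model_mask(coords, dmap, mask_radius_A)
    sim = simulate_model_density(coords, masses, dmap, resolution_A)
    return normalized_cc(sim.grid, dmap.grid, mask)


# --------------------------------------------------------------------------
# rigid docking
# --------------------------------------------------------------------------

@dataclass
class RigidBodyFit:
    transform: RigidTransform
    hinge_angles: dict[str, float] = field(default_factory=dict)
    cc: float = -1.0
    iterations_used: int = 0
    cc_history: list[float] = field(default_factory=list)
    flagged: bool = False
    notes: list[str] = field(default_factory=list)


def rigid_dock(
    coords: np.ndarray,
    masses: np.ndarray,
    dmap: DensityMap,
    resolution_A: float = 10.0,
    z_start_step_deg: float = 10.0,
    local: bool = True,
) -> RigidBodyFit:
    """Global 6-DOF placement maximizing the masked cross-correlation.

    Deterministic: a coarse scan over Z rotations covering one asymmetric
    unit (the C7 symmetry makes a full turn redundant), each followed by a
    Powell refinement of (rotation vector, translation) about the model
    centroid.  A uniform (featureless) map is flagged as a failure.
    """
    if np.allclose(dmap.grid.std(), 0.0):
        return RigidBodyFit(RigidTransform.identity(), cc=0.0, flagged=True,
                            notes=["degenerate map: no density contrast"])
    centroid = coords.mean(axis=0)
    # fixed evaluation mask around the occupied region of the map
    mask = dmap.grid > 0.1 * dmap.grid.max()

    def pose(params):
        rv = params[:3]
        t = params[3:]
        R = Rotation.from_rotvec(rv).as_matrix()
        return coords @ R.T + (centroid - R @ centroid) + t

    def neg_cc(params):
        try:
            return -cc_score(pose(params), masses, dmap, resolution_A, mask=mask)
        except ValueError:
            return 1.0  # moved outside the box

    best = None
    for z0 in np.arange(0.0, DELTA_DEG, z_start_step_deg):
        x0 = np.concatenate([np.deg2rad(z0) * Z_AXIS, np.zeros(3)])
        if local:
            res = minimize(neg_cc, x0, method="Powell",
                           options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 2000})
            cand = (res.fun, res.x)
        else:
            cand = (neg_cc(x0), x0)
        if best is None or cand[0] < best[0]:
            best = cand
    cc = -best[0]
    rv, t = best[1][:3], best[1][3:]
    R = Rotation.from_rotvec(rv).as_matrix()
    T = RigidTransform(R, centroid - R @ centroid + t)
    return RigidBodyFit(T, cc=cc, flagged=cc <= 0.0,
                        notes=[] if cc > 0 else ["no placement with cc > 0"])


# --------------------------------------------------------------------------
# hinge refinement
# --------------------------------------------------------------------------

def hinge_refine(
    start: RigidBodyFit,
    spec: RigidGroupSpec,
    coords0: np.ndarray,
    masses: np.ndarray,
    dmap: DensityMap,
    n_iter: int = 10,
    resolution_A: float = 10.0,
    mask_radius_A: float = 6.0,
    angle_tol_deg: float = 0.02,
    symmetry_expand: int = 1,
    scan_points: int = 21,
    joint_scan: tuple[str, str] | None = None,
    context_coords: np.ndarray | None = None,
    context_masses: np.ndarray | None = None,
) -> RigidBodyFit:
    """Cyclic per-hinge line search maximizing the masked CC.

    Each sweep visits the hinges in tree order; each hinge angle is
    optimized by a coarse scan over its bounds followed by a bounded local
    search around the scan optimum (robust to secondary maxima in the CC
    landscape), with all descendant groups moved rigidly.  An update is
    accepted only if it improves the score, so the CC history is monotone
    non-decreasing, and connectivity is preserved exactly.  Angles ending
    at a bound are clamped and noted.

    With ``symmetry_expand`` = n the posed subunit is replicated about Z
    n-fold before scoring, coupling the hinge angles across all symmetry
    copies -- the right objective when fitting one subunit into an
    n-fold-symmetrized map.
    """
    spec.validate(len(coords0))
    angles = dict(start.hinge_angles)
    for h in spec.hinges:
        angles.setdefault(h.name, 0.0)

    sym_R = [rotation_about_axis(Z_AXIS, 360.0 * k / symmetry_expand)
             for k in range(symmetry_expand)]

    def expand(c):
        if symmetry_expand == 1:
            return c
        return np.concatenate([c @ R.T for R in sym_R])

    masses_x = np.tile(masses, symmetry_expand)
    if context_coords is not None:
        # static surroundings (e.g. the unliganded opposite ring) included
        # in the simulated density so interface voxels are modelled
        if context_masses is None:
            context_masses = np.ones(len(context_coords))
        masses_x = np.concatenate([masses_x, context_masses])

    def with_context(c):
        if context_coords is None:
            return c
        return np.concatenate([c, context_coords])

    mask = model_mask(
        with_context(expand(
            apply_hinge_angles(coords0, spec, angles, start.transform))),
        dmap, mask_radius_A + 2.0)

    def score(a: dict[str, float]) -> float:
        c = with_context(expand(apply_hinge_angles(coords0, spec, a,
                                                   start.transform)))
        return cc_score(c, masses_x, dmap, resolution_A, mask=mask)

    cc = score(angles)
    history = [cc]
    notes = list(start.notes)
    sweep = -1

    if joint_scan is not None:
        # coupled hinges (e.g. en-bloc tilt and apical elevation) create
        # mirror basins that one-hinge-at-a-time scans jump between; a
        # coarse joint grid locates the right basin first
        ha = next(h for h in spec.hinges if h.name == joint_scan[0])
        hb = next(h for h in spec.hinges if h.name == joint_scan[1])
        ga = np.linspace(ha.bounds[0], ha.bounds[1], 13)
        gb = np.linspace(hb.bounds[0], hb.bounds[1], 13)
        for va in ga:
            for vb in gb:
                trial = dict(angles)
                trial[ha.name] = float(va)
                trial[hb.name] = float(vb)
                sc = score(trial)
                if sc > cc:
                    angles = trial
                    cc = sc
        history.append(cc)

    for sweep in range(n_iter):
        improved = False
        for h in spec.ordered_hinges():
            def neg(angle):
                trial = dict(angles)
                trial[h.name] = angle
                return -score(trial)

            if sweep == 0:
                grid = np.linspace(h.bounds[0], h.bounds[1], scan_points)
                grid_scores = [neg(g) for g in grid]
                gbest = int(np.argmin(grid_scores))
                step = grid[1] - grid[0]
                lo = max(h.bounds[0], grid[gbest] - step)
                hi = min(h.bounds[1], grid[gbest] + step)
            else:
                lo, hi = (max(h.bounds[0], angles[h.name] - 5.0),
                          min(h.bounds[1], angles[h.name] + 5.0))
            res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                  options={"xatol": angle_tol_deg / 4})
            if -res.fun > cc + 1e-12:
                angles[h.name] = float(np.clip(res.x, *h.bounds))
                if abs(angles[h.name] - h.bounds[0]) < angle_tol_deg or \
                   abs(angles[h.name] - h.bounds[1]) < angle_tol_deg:
                    notes.append(f"hinge {h.name} at bound {angles[h.name]:.1f}")
                cc = -res.fun
                improved = True
        history.append(cc)
        if not improved:
            break

    # joint polish: cyclic (one-hinge-at-a-time) descent can stall on a
    # ridge where two hinges partially compensate; a short simultaneous
    # simplex search from the cyclic optimum removes that residue.  The
    # result is accepted only if it improves, so monotonicity holds.
    names = [h.name for h in spec.ordered_hinges()]
    if len(names) > 1:
        from scipy.optimize import minimize

        def neg_vec(v):
            trial = dict(angles)
            for nm, val in zip(names, v):
                lo, hi = next(h.bounds for h in spec.hinges if h.name == nm)
                trial[nm] = float(np.clip(val, lo, hi))
            return -score(trial)

        x0 = np.array([angles[nm] for nm in names])
        res = minimize(neg_vec, x0, method="Nelder-Mead",
                       options={"xatol": angle_tol_deg / 4,
                                "fatol": 1e-10, "maxiter": 400})
        if -res.fun > cc:
            for nm, val in zip(names, res.x):
                lo, hi = next(h.bounds for h in spec.hinges if h.name == nm)
                angles[nm] = float(np.clip(val, lo, hi))
            cc = -res.fun
            history.append(cc)
    return RigidBodyFit(start.transform, angles, cc, sweep + 1, history,
                        flagged=False, notes=notes)


def fitted_coords(fit: RigidBodyFit, spec: RigidGroupSpec,
                  coords0: np.ndarray) -> np.ndarray:
    return apply_hinge_angles(coords0, spec, fit.hinge_angles, fit.transform)


# --------------------------------------------------------------------------
# ring rebuild
# --------------------------------------------------------------------------

def rebuild_ring_c7(
    subunit_coords: np.ndarray,
    geo: SubunitGeometry,
    restore_lateral_sheet: bool = False,
    collision_floor_A: float = 1.0,
) -> tuple[np.ndarray, dict]:
    """Rebuild a full ring from one fitted subunit by C7 symmetry.

    With ``restore_lateral_sheet`` the lateral beta-sheet edge atoms are
    snapped back to their reference geometry expressed in the neighboring
    subunit's (fitted) equatorial frame, enforcing the correct intersubunit
    contact; the group moves rigidly as a whole.  The minimum inter-subunit
    atom distance is reported so steric collapse can be detected.
    """
    coords = subunit_coords.copy()
    info: dict = {}
    if restore_lateral_sheet:
        ls = geo.groups["lateral_sheet"]
        eq_sl = geo.domain_slices["equatorial"]
        ref = geo.all_coords()
        # fitted equatorial frame relative to the reference
        T_eq = kabsch(ref[eq_sl], coords[eq_sl])
        # the C7 rebuild puts the neighbor's equatorial frame at Rz(delta)*T_eq;
        # the sheet's reference pose in that frame is Rz(-delta)*L_ref
        Rz = RigidTransform(rotation_about_axis(Z_AXIS, DELTA_DEG), np.zeros(3))
        nb_frame = Rz.compose(T_eq)
        ls_ref_in_nb = Rz.inverse().apply(ref[ls])
        coords[ls] = nb_frame.apply(ls_ref_in_nb)
        rmsd = np.sqrt(np.mean(np.sum(
            (nb_frame.inverse().apply(coords[ls]) - ls_ref_in_nb) ** 2, axis=1)))
        info["lateral_sheet_rmsd_A"] = float(rmsd)
    ring = np.concatenate([
        RigidTransform(rotation_about_axis(Z_AXIS, k * DELTA_DEG),
                       np.zeros(3)).apply(coords)
        for k in range(N_FOLD)
    ])
    from scipy.spatial import cKDTree

    tree = cKDTree(ring[len(coords):2 * len(coords)])
    dmin = tree.query(coords)[0].min()
    info["min_intersubunit_distance_A"] = float(dmin)
    if dmin < collision_floor_A:
        warnings.warn(f"steric collapse: min inter-subunit distance {dmin:.2f} A")
        info["collision"] = True
    return ring, info
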