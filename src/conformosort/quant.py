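"""Quantification of domain motions and salt-bridge switching between states.

Domain motions are measured by least-squares rigid superposition of a
domain's pseudo-atoms between two (frame-aligned) models, reported as an
axis/angle plus the residual center-of-mass translation -- exact for
rigidly moved domains.  Before measuring, models are brought into a common
frame either by superposing the nucleotide-free (reference) rings or, when
no common free ring exists, by the single Z rotation that best aligns the
per-subunit centers of mass of the ring of interest.

Salt-bridge tables follow the density-bridge bookkeeping of the allosteric
trajectory: each contact is a designated marker-atom pair, measured for all
7 subunit pairings (the intersubunit partner is the next subunit
anticlockwise viewed from outside the top ring; inter-ring pairings are
nearest-neighbor across the staggered interface), averaged, and flagged
in-contact when the mean is within the 8 A cutoff.  Each conformational
state has a characteristic boolean contact signature; a measured table is
assigned to the nearest signature by Hamming distance, with exact ties
returned as a tied set rather than guessed (Rs1 and Rs2 share their
signature by design: they differ in apical elevation, not contacts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import RigidTransform, axis_angle_of, kabsch
from .phantom import PhantomModel


# --------------------------------------------------------------------------
# frame alignment
# --------------------------------------------------------------------------

def align_frames(
    model_a: PhantomModel,
    model_b: PhantomModel,
    mode: str = "superpose-free-ring",
    reference_ring: int = 1,
    com_ring: int = 0,
) -> tuple[PhantomModel, RigidTransform]:
    """Transform ``model_b`` into ``model_a``'s frame.

    ``superpose-free-ring``: least-squares superposition of the designated
    reference ring (default: the bottom, nucleotide-free ring).
    ``z-rotation-by-com``: the single rotation about Z minimizing the
    distances between per-subunit centers of mass of ``com_ring`` (closed
    form).  Returns the transformed model and the transform used.
    """
    if model_a.n_per_subunit != model_b.n_per_subunit:
        raise ValueError("models do not share subunit topology")
    if mode == "superpose-free-ring":
        idx = [model_a.subunit_slice(reference_ring, su) for su in range(model_a.n_fold)]
        P = np.concatenate([model_b.coords[s] for s in idx])
        Q = np.concatenate([model_a.coords[s] for s in idx])
        T = kabsch(P, Q)
    elif mode == "z-rotation-by-com":
        ca = np.stack([model_a.subunit_coords(com_ring, su).mean(axis=0)
                       for su in range(model_a.n_fold)])
        cb = np.stack([model_b.subunit_coords(com_ring, su).mean(axis=0)
                       for su in range(model_b.n_fold)])
        # gamma maximizing sum_i (a_i . Rz(gamma) b_i) in the xy plane
        num = np.sum(cb[:, 0] * ca[:, 1] - cb[:, 1] * ca[:, 0])
        den = np.sum(ca[:, 0] * cb[:, 0] + ca[:, 1] * cb[:, 1])
        gamma = np.rad2deg(np.arctan2(num, den))
        T = RigidTransform.about_point(np.array([0.0, 0.0, 1.0]), gamma,
                                       np.zeros(3))
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")
    return model_b.with_coords(T.apply(model_b.coords)), T


# --------------------------------------------------------------------------
# domain motion
# --------------------------------------------------------------------------

@dataclass
class DomainMotion:
    domain: str
    angle_deg: float
    axis: np.ndarray
    translation_A: np.ndarray     # residual COM shift after rotation about COM
    com_displacement_A: float


def measure_domain_motion(
    model_a: PhantomModel,
    model_b: PhantomModel,
    domain: str,
    ring: int = 0,
    su: int = 0,
) -> DomainMotion:
    """Axis/angle/translation of a domain's motion from ``model_a`` to ``model_b``.

    Least-squares superposition (Kabsch) of the domain's atoms; exact for
    rigidly moved domains.  The models are assumed frame-aligned.
    """
    P = model_a.domain_coords(ring, su, domain)
    Q = model_b.domain_coords(ring, su, domain)
    if len(P) < 3:
        raise ValueError("need at least 3 non-collinear atoms")
    T = kabsch(P, Q)
    axis, angle = axis_angle_of(T.R)
    com_a = P.mean(axis=0)
    com_b = Q.mean(axis=0)
    return DomainMotion(
        domain=domain,
        angle_deg=angle,
        axis=axis,
        translation_A=com_b - com_a,
        com_displacement_A=float(np.linalg.norm(com_b - com_a)),
    )


def motion_rotation(model_a: PhantomModel, model_b: PhantomModel, domain: str,
                    ring: int = 0, su: int = 0) -> np.ndarray:
    """The 3x3 rotation superposing a domain of A onto B (for composition tests)."""
    P = model_a.domain_coords(ring, su, domain)
    Q = model_b.domain_coords(ring, su, domain)
    return kabsch(P, Q).R


# --------------------------------------------------------------------------
# contacts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactDefinition:
    residue_a: str
    residue_b: str
    kind: str = "salt-bridge"            # or "van-der-Waals"
    scope: str = "intersubunit"          # intersubunit | inter-ring | intrasubunit


# the tracked contact set: intersubunit salt bridges that fingerprint the
# allosteric states, the inter-ring contacts, and the intrasubunit D83-K327
STANDARD_CONTACTS = [
    ContactDefinition("R197", "E386"),
    ContactDefinition("K80", "E386"),
    ContactDefinition("E255", "K207"),
    ContactDefinition("E255", "K245"),
    ContactDefinition("E257", "K245"),
    ContactDefinition("E257", "K242"),
    ContactDefinition("D83", "K327", scope="intrasubunit"),
    ContactDefinition("A109", "A109", kind="van-der-Waals", scope="inter-ring"),
    ContactDefinition("R452", "E461", scope="inter-ring"),
    ContactDefinition("V464", "V464", kind="van-der-Waals", scope="inter-ring"),
]

INTERSUBUNIT_CONTACTS = [c for c in STANDARD_CONTACTS if c.scope == "intersubunit"]
INTERRING_CONTACTS = [c for c in STANDARD_CONTACTS if c.scope == "inter-ring"]

CONTACT_CUTOFF_A = 8.0  # contacts farther than this are "grayed out" (broken)


def _pair_distances(model: PhantomModel, c: ContactDefinition,
                    ring: int) -> np.ndarray:
    """Per-subunit distances for one contact definition."""
    a = model.marker_coords(c.residue_a, ring)
    if c.scope == "intrasubunit":
        b = model.marker_coords(c.residue_b, ring)
        return np.linalg.norm(a - b, axis=1)
    if c.scope == "intersubunit":
        # partner is the next subunit anticlockwise (increasing azimuth)
        b = model.marker_coords(c.residue_b, ring)
        b_next = np.roll(b, -1, axis=0)
        return np.linalg.norm(a - b_next, axis=1)
    if c.scope == "inter-ring":
        b = model.marker_coords(c.residue_b, 1 - ring)
        return np.array([np.min(np.linalg.norm(b - ai, axis=1)) for ai in a])
    raise ValueError(f"unknown scope {c.scope}")


def contact_distances(
    model: PhantomModel,
    contacts: list[ContactDefinition] = STANDARD_CONTACTS,
    contact_cutoff_A: float = CONTACT_CUTOFF_A,
    ring: int = 0,
) -> pd.DataFrame:
    """Mean/std of each contact distance over the 7 subunit pairings.

    ``in_contact`` is True when the subunit-averaged distance is within the
    cutoff.  For an exactly C7-symmetric model the per-subunit std is zero.
    """
    rows = []
    for c in contacts:
        for lbl in (c.residue_a, c.residue_b):
            if lbl not in model.geometry.marker_residues:
                raise KeyError(f"marker {lbl} missing from the model")
        d = _pair_distances(model, c, ring)
        rows.append({
            "contact": f"{c.residue_a}-{c.residue_b}",
            "kind": c.kind, "scope": c.scope,
            "mean_A": float(d.mean()), "std_A": float(d.std()),
            "in_contact": bool(d.mean() <= contact_cutoff_A),
        })
    return pd.DataFrame(rows)


def interring_metrics(model_a: PhantomModel, model_b: PhantomModel,
                      ring: int = 0) -> pd.DataFrame:
    """Inter-ring contact lengths in each model and their change (B - A)."""
    rows = []
    for c in INTERRING_CONTACTS:
        da = _pair_distances(model_a, c, ring).mean()
        db = _pair_distances(model_b, c, ring).mean()
        rows.append({
            "contact": f"{c.residue_a}-{c.residue_b}",
            "a_A": float(da), "b_A": float(db), "change_A": float(db - da),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# state assignment from contact signatures
# --------------------------------------------------------------------------

_SIG_ORDER = ["R197-E386", "K80-E386", "E255-K207", "E255-K245",
              "E257-K245", "E257-K242"]

# per-state boolean signatures over the tracked intersubunit set
STATE_SIGNATURES: dict[str, tuple[int, ...]] = {
    "T":       (1, 0, 1, 0, 0, 0),
    "Rs1":     (0, 1, 0, 1, 0, 0),
    "Rs2":     (0, 1, 0, 1, 0, 0),   # distinguished from Rs1 by elevation, not contacts
    "Rd1":     (0, 0, 0, 1, 0, 0),
    "Rd2":     (0, 0, 0, 1, 1, 0),
    "Rd3":     (0, 0, 0, 1, 1, 0),
    "Rd4":     (0, 0, 0, 1, 1, 1),
    "Rd5":     (0, 0, 0, 1, 1, 1),
    "R-open":  (0, 0, 0, 0, 0, 0),   # all apical intersubunit contacts broken
}


def contact_vector(table: pd.DataFrame) -> tuple[int, ...]:
    """The boolean in_contact vector over the tracked intersubunit set."""
    lut = dict(zip(table["contact"], table["in_contact"]))
    try:
        return tuple(int(lut[name]) for name in _SIG_ORDER)
    except KeyError as e:
        raise KeyError(f"contact table does not cover {e}") from None


def assign_state_from_contacts(
    table: pd.DataFrame,
) -> tuple[list[str], int]:
    """Nearest-signature state assignment with a Hamming-margin confidence.

    Returns (labels, margin): all states at the minimum Hamming distance
    from the measured contact vector, and the margin to the runner-up
    distance.  States sharing a signature (Rs1/Rs2; Rd2/Rd3; Rd4/Rd5) are
    returned together -- they are distinguished by domain elevation, not by
    contacts -- and a zero margin returns the full tied set rather than a
    guess.
    """
    v = np.array(contact_vector(table))
    dists = {s: int(np.sum(v != np.array(sig)))
             for s, sig in STATE_SIGNATURES.items()}
    dmin = min(dists.values())
    winners = sorted([s for s, d in dists.items() if d == dmin])
    rest = [d for d in dists.values() if d > dmin]
    margin = (min(rest) - dmin) if rest else 0
    return winners, margin
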