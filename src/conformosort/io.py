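"""File I/O: MRC volumes and image stacks (via gemmi), PDB models, TSV tables.

Volumes are written as CCP4/MRC mode-2 maps with the voxel size carried in
the unit-cell header; particle stacks use the MRC image-stack convention
(ISPG = 0, nz = number of images) with the stack metadata in a sibling
tab-separated table.  Pseudo-atomic models are written as PDB with one
chain per subunit (A-G top ring, H-N bottom ring) and the rigid-group name
in the segment id.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .maps import DensityMap
from .phantom import ParticleStack, PhantomModel


# --------------------------------------------------------------------------
# MRC
# --------------------------------------------------------------------------

def write_mrc(dmap: DensityMap, path) -> None:
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.grid, dtype=np.float32))
    a = dmap.voxel_A * dmap.n
    m.grid.unit_cell = gemmi.UnitCell(a, a, a, 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path) -> DensityMap:
    m = gemmi.read_ccp4_map(str(path))
    grid = np.array(m.grid, copy=True).astype(np.float64)
    voxel = m.grid.unit_cell.a / grid.shape[0]
    return DensityMap.centered(grid.shape[0], voxel).with_grid(grid)


def write_mrc_stack(stack: ParticleStack, path, meta_path=None) -> None:
    """MRC image stack (ISPG=0) + tab-separated per-particle metadata."""
    m = gemmi.Ccp4Map()
    # gemmi grids are indexed (nx, ny, nz); store images along the last axis
    arr = np.ascontiguousarray(
        np.moveaxis(stack.images, 0, -1).astype(np.float32))
    m.grid = gemmi.FloatGrid(arr)
    b = stack.pixel_A
    m.grid.unit_cell = gemmi.UnitCell(
        b * arr.shape[0], b * arr.shape[1], b * arr.shape[2], 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.set_header_i32(23, 0)  # ISPG 0: image stack
    m.write_ccp4_map(str(path))
    if meta_path is None:
        meta_path = Path(str(path)).with_suffix(".tsv")
    write_table(stack.meta, meta_path)


def read_mrc_stack(path, meta_path=None, pixel_A=None) -> ParticleStack:
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=True).astype(np.float64)
    images = np.moveaxis(arr, -1, 0)
    if pixel_A is None:
        pixel_A = m.grid.unit_cell.a / arr.shape[0]
    if meta_path is None:
        meta_path = Path(str(path)).with_suffix(".tsv")
    meta = (read_table(meta_path) if Path(meta_path).exists()
            else pd.DataFrame({"particle": np.arange(len(images))}))
    return ParticleStack(images, pixel_A, meta)


# --------------------------------------------------------------------------
# tables
# --------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --------------------------------------------------------------------------
# PDB
# --------------------------------------------------------------------------

_CHAIN_IDS = "ABCDEFGHIJKLMN"
_DOMAIN_SEG = {"equatorial": "EQU", "intermediate": "INT", "apical": "API"}


def write_model_pdb(model: PhantomModel, path) -> None:
    """One chain per subunit; domain encoded in the segment id; markers named.

    Pseudo-atoms are written as CA atoms of consecutive glycine residues;
    marker pseudo-atoms carry their residue label's number (e.g. 197) offset
    by 1000 so they are easy to find and cannot collide with the filler
    numbering.
    """
    geo = model.geometry
    dom_of = np.empty(geo.n_atoms, dtype=object)
    for dom, sl in geo.domain_slices.items():
        dom_of[sl] = dom
    marker_at = {idx: lbl for lbl, idx in geo.marker_residues.items()}

    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(500, 500, 500, 90, 90, 90)
    mo = gemmi.Model("1")
    for ring in range(2):
        for su in range(model.n_fold):
            ch = gemmi.Chain(_CHAIN_IDS[ring * model.n_fold + su])
            coords = model.subunit_coords(ring, su)
            for i, xyz in enumerate(coords):
                res = gemmi.Residue()
                res.name = "GLY"
                lbl = marker_at.get(i)
                num = (1000 + int("".join(c for c in lbl if c.isdigit()))
                       if lbl else i + 1)
                res.seqid = gemmi.SeqId(num, " ")
                res.segment = _DOMAIN_SEG[dom_of[i]]
                at = gemmi.Atom()
                at.name = "CA"
                at.element = gemmi.Element("C")
                at.occ = 1.0
                at.b_iso = float(model.masses[model.subunit_slice(ring, su)][i])
                at.pos = gemmi.Position(*xyz)
                res.add_atom(at)
                ch.add_residue(res)
            mo.add_chain(ch)
    st.add_model(mo)
    st.setup_entities()
    st.write_pdb(str(path))


def read_pdb_coords(path, chain: str | None = None,
                    ca_only: bool = True) -> np.ndarray:
    """Coordinates (optionally CA-only, one chain) from any PDB file."""
    st = gemmi.read_structure(str(path))
    out = []
    for ch in st[0]:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            for at in res:
                if ca_only and at.name != "CA":
                    continue
                out.append([at.pos.x, at.pos.y, at.pos.z])
    return np.asarray(out)


def ca_separation(path, resnum_a: int, resnum_b: int,
                  chain: str = "A") -> float:
    """Calpha-Calpha distance between two residues of one chain (A)."""
    st = gemmi.read_structure(str(path))
    pos = {}
    for ch in st[0]:
        if ch.name != chain:
            continue
        for res in ch:
            if res.seqid.num in (resnum_a, resnum_b):
                for at in res:
                    if at.name == "CA":
                        pos[res.seqid.num] = np.array(
                            [at.pos.x, at.pos.y, at.pos.z])
    if resnum_a not in pos or resnum_b not in pos:
        raise KeyError(
            f"residues {resnum_a}/{resnum_b} (CA) not found in chain {chain}")
    return float(np.linalg.norm(pos[resnum_a] - pos[resnum_b]))
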