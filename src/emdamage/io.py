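"""Reading and writing MRC/CCP4 volumes and PDB coordinate files.

Backed by `gemmi`; everything is normalized into the package's own
containers (:class:`~emdamage.model.DensityMap`,
:class:`~emdamage.model.AtomicModel`) on the way in.

Canonical map convention: after reading, the grid is reordered so that
array axis 0/1/2 is crystallographic X/Y/Z (``MAPC,MAPR,MAPS = 1,2,3``),
and the physical coordinate of voxel ``(i, j, k)`` is
``origin + (i, j, k) * voxel_size``.  The origin is taken from the MRC
``ORIGIN`` header words when any is nonzero, otherwise from the
``NXSTART/NYSTART/NZSTART`` words times the voxel size.  Only orthogonal
unit cells are accepted (single-particle maps are orthogonal by
construction).
"""

from __future__ import annotations

import os
import re

import gemmi
import numpy as np

from .model import METAL_ELEMENTS, Atom, AtomicModel, DensityMap

__all__ = [
    "read_map",
    "write_map",
    "read_model",
    "write_model",
    "MapFormatError",
    "ModelFormatError",
    "water_count",
    "selection_mean_adp",
]


class MapFormatError(ValueError):
    """Unsupported or inconsistent volume header."""


class ModelFormatError(ValueError):
    """Malformed coordinate file."""


def read_map(path: str | os.PathLike) -> DensityMap:
    """Read an MRC/CCP4 volume, normalizing axis order to X, Y, Z.

    Raises ``IOError`` if the file is unreadable and
    :class:`MapFormatError` for unsupported modes or non-orthogonal cells.
    """
    if not os.path.exists(path):
        raise IOError(f"map file not found: {path}")
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        msg = str(exc)
        if "mode" in msg.lower():
            raise MapFormatError(f"unsupported MRC MODE field in {path}: {msg}")
        raise MapFormatError(f"cannot parse map {path}: {msg}") from exc
    mapc = ccp4.header_i32(17)
    mapr = ccp4.header_i32(18)
    maps = ccp4.header_i32(19)
    if sorted((mapc, mapr, maps)) != [1, 2, 3]:
        raise MapFormatError(
            f"invalid MAPC/MAPR/MAPS axis fields ({mapc},{mapr},{maps}) in {path}"
        )
    # normalize axis order to X, Y, Z without touching values
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    cell = ccp4.grid.unit_cell
    if not (
        abs(cell.alpha - 90) < 1e-3
        and abs(cell.beta - 90) < 1e-3
        and abs(cell.gamma - 90) < 1e-3
    ):
        raise MapFormatError(
            f"non-orthogonal unit cell (angles {cell.alpha},{cell.beta},"
            f"{cell.gamma}) in {path}; only orthogonal maps are supported"
        )
    grid = np.array(ccp4.grid, copy=True).astype(np.float64)
    voxel = np.array(
        [cell.a / grid.shape[0], cell.b / grid.shape[1], cell.c / grid.shape[2]]
    )
    origin_words = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
    if np.any(origin_words != 0):
        origin = origin_words
    else:
        nstart = np.array([ccp4.header_i32(w) for w in (5, 6, 7)], dtype=float)
        origin = nstart * voxel
    return DensityMap(grid, voxel, origin)


def write_map(dmap: DensityMap, path: str | os.PathLike) -> str:
    """Write *dmap* as a CCP4-2014 mode-2 (float32) volume. Returns *path*."""
    g = gemmi.FloatGrid(*dmap.shape)
    np.asarray(g)[:] = dmap.grid.astype(np.float32)
    nx, ny, nz = dmap.shape
    vx, vy, vz = dmap.voxel_size
    g.set_unit_cell(gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = g
    ccp4.update_ccp4_header()
    for w, v in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(w, float(v))
    try:
        ccp4.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write map to {path}: {exc}") from exc
    return str(path)


_COORD_RE = re.compile(r"^(ATOM|HETATM)")


def _prevalidate_pdb(path: str | os.PathLike) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not _COORD_RE.match(line):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ModelFormatError(
                    f"{path}:{lineno}: coordinate line too short"
                )
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                raise ModelFormatError(
                    f"{path}:{lineno}: missing element column (77-78)"
                )
            for lo, hi, what in (
                (30, 38, "x"),
                (38, 46, "y"),
                (46, 54, "z"),
                (54, 60, "occupancy"),
                (60, 66, "B-factor"),
            ):
                fieldtext = line[lo:hi].strip()
                if fieldtext == "" and what in ("occupancy", "B-factor"):
                    continue  # gemmi defaults these
                try:
                    float(fieldtext)
                except ValueError:
                    raise ModelFormatError(
                        f"{path}:{lineno}: malformed {what} field {fieldtext!r}"
                    ) from None


def _derive_label(element: str, name: str, resname: str, resseq: int) -> str:
    """Pipeline label for an atom: Mn1/Ca for metals, W3 for waters,
    the atom name for cluster oxygens, otherwise resseq:name."""
    if element in METAL_ELEMENTS:
        sym = element.capitalize()
        digits = "".join(ch for ch in name if ch.isdigit())
        return sym + digits
    if resname == "HOH":
        return f"W{resseq}"
    if element == "S" and name == "SG":
        return f"SG{resseq}"
    if element == "O" and name.startswith("O") and name != "O":
        return name
    return f"{resseq}:{name}"


def read_model(path: str | os.PathLike) -> AtomicModel:
    """Read a PDB-format coordinate file into an :class:`AtomicModel`.

    Atoms are kept in file order; waters are detected by residue name
    ``HOH`` and metals by element.  Malformed coordinate lines raise
    :class:`ModelFormatError` with the offending line number.
    """
    if not os.path.exists(path):
        raise IOError(f"model file not found: {path}")
    _prevalidate_pdb(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    atoms: list[Atom] = []
    if len(st) == 0:
        return AtomicModel([])
    for chain in st[0]:
        for res in chain:
            for at in res:
                el = at.element.name.upper()
                atoms.append(
                    Atom(
                        element=el,
                        label=_derive_label(el, at.name, res.name, res.seqid.num),
                        name=at.name,
                        resname=res.name,
                        chain=chain.name,
                        resseq=res.seqid.num,
                        xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occ=float(at.occ),
                        adp=float(at.b_iso),
                        altloc=at.altloc if at.altloc != "\x00" else "",
                        icode=res.seqid.icode.strip(),
                    )
                )
    return AtomicModel(atoms)


def write_model(model: AtomicModel, path: str | os.PathLike) -> str:
    """Write *model* as fixed-column PDB text. Returns *path*.

    Raises ``ValueError`` if any coordinate exceeds the fixed-width
    ``%8.3f`` field of the format.
    """
    for a in model:
        if np.any(np.abs(a.xyz) >= 10000) or np.any(a.xyz <= -1000):
            raise ValueError(
                f"coordinate {a.xyz} of {a.label} exceeds PDB fixed-width field"
            )
    # group atoms by chain and residue in file order; gemmi's add_* methods
    # copy their argument, so the hierarchy is assembled bottom-up
    chain_order: list[str] = []
    residues: dict[str, list[tuple[tuple, list]]] = {}
    for a in model:
        if a.chain not in residues:
            residues[a.chain] = []
            chain_order.append(a.chain)
        key = (a.resseq, a.resname, a.icode)
        if not residues[a.chain] or residues[a.chain][-1][0] != key:
            residues[a.chain].append((key, []))
        residues[a.chain][-1][1].append(a)

    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(1, 1, 1, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    gmodel = gemmi.Model("1")
    for chain_name in chain_order:
        chain = gemmi.Chain(chain_name)
        for (resseq, resname, icode), atoms in residues[chain_name]:
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resseq, icode or " ")
            res.het_flag = "H" if resname in ("HOH", "OEC", "OEX") else "A"
            for a in atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element.capitalize())
                at.pos = gemmi.Position(*a.xyz)
                at.occ = a.occ
                at.b_iso = a.adp
                if a.altloc:
                    at.altloc = a.altloc
                res.add_atom(at)
            chain.add_residue(res)
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write model to {path}: {exc}") from exc
    return str(path)


def water_count(model: AtomicModel) -> int:
    """Number of water (``HOH``) oxygen records in *model*."""
    return sum(1 for a in model if a.resname == "HOH" and a.element == "O")


def selection_mean_adp(model: AtomicModel, selection: str) -> float:
    """Mean ADP (Å²) over a named selection, e.g. the cluster atoms."""
    idx = model.selection(selection)
    if not idx:
        raise ValueError(f"selection {selection!r} is empty")
    return float(np.mean([model[i].adp for i in idx]))
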