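"""Coordinate data model, PDB I/O and crystal-packing expansion.

The model is deliberately small: chains of residues of atoms, Cartesian
coordinates in Å throughout, with the crystal cell and (for triclinic P1
crystals) lattice translations available for packing expansion.  Author
residue numbering is preserved as deposited; no renumbering is ever done.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "CrystalCell",
    "StructureModel",
    "PDBFormatError",
    "VDW_RADII",
    "read_pdb",
    "write_pdb",
    "cell_volume",
    "matthews_solvent",
    "expand_packing",
]

#: Bondi-style van der Waals radii (Å) used for clash detection and SASA.
#: Overridable via the ``radii`` argument of :func:`read_pdb`.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "CU": 1.40,
}
_DEFAULT_RADIUS = 1.70

#: The 20 standard amino acids plus the MTSSL-labelled cysteine residue.
STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Residue name used for the R1 (MTSSL-cysteine) side chain in PDB output.
R1_RESIDUE_NAME = "R1A"

WATER_NAMES = {"HOH", "WAT", "DOD"}
CRYO_NAMES = {"GOL", "EDO", "PEG", "PG4", "MPD"}
METAL_NAMES = {"CU", "ZN", "NA", "MG", "K", "CA", "FE", "MN", "NI", "CO", "CD"}


class PDBFormatError(ValueError):
    """Raised for malformed PDB records; carries the offending line number."""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    vdw_radius: float = _DEFAULT_RADIUS
    altloc: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: position must be 3 finite numbers")
        if not self.element:
            raise ValueError(f"atom {self.name}: element symbol is empty")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name}: vdW radius must be positive")

    def copy(self) -> "Atom":
        return replace(self, pos=self.pos.copy())


@dataclass
class Residue:
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""
    het: bool = False

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name} {self.number}{self.icode}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coords(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.atom(n).pos for n in names])

    def copy(self) -> "Residue":
        return Residue(self.number, self.name, [a.copy() for a in self.atoms],
                       self.icode, self.het)


@dataclass
class Chain:
    cid: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        raise KeyError(f"chain {self.cid}: no residue {number}{icode}")

    def atoms(self) -> Iterator[Atom]:
        for r in self.residues:
            yield from r.atoms

    def copy(self) -> "Chain":
        return Chain(self.cid, [r.copy() for r in self.residues])


@dataclass(frozen=True)
class CrystalCell:
    """Unit-cell lengths (Å) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.discriminant() <= 0:
            raise ValueError("degenerate cell: volume discriminant not positive")

    def discriminant(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg

    def orthogonalization_matrix(self) -> np.ndarray:
        """Matrix M with cartesian = M @ fractional (PDB convention)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(self.discriminant())
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])


@dataclass
class StructureModel:
    chains: list[Chain] = field(default_factory=list)
    cell: CrystalCell | None = None
    #: fractional-space symmetry operators (rotation matrix, translation).
    symmetry_ops: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def chain(self, cid: str) -> Chain:
        for c in self.chains:
            if c.cid == cid:
                return c
        raise KeyError(f"no chain {cid!r}")

    def has_chain(self, cid: str) -> bool:
        return any(c.cid == cid for c in self.chains)

    def atoms(self) -> Iterator[Atom]:
        for c in self.chains:
            yield from c.atoms()

    def coords(self) -> np.ndarray:
        pts = [a.pos for a in self.atoms()]
        return np.array(pts) if pts else np.empty((0, 3))

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def copy(self) -> "StructureModel":
        ops = [(r.copy(), t.copy()) for r, t in self.symmetry_ops]
        return StructureModel([c.copy() for c in self.chains], self.cell, ops)

    def heavy_atoms(self) -> Iterator[Atom]:
        for a in self.atoms():
            if a.element != "H":
                yield a


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column ATOM/HETATM/CRYST1/TER/END)

def _infer_element(name: str, resname: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "C"
    if resname.strip().upper() in METAL_NAMES:
        return resname.strip().upper()
    two = stripped[:2].upper()
    if two in ("CU", "ZN", "FE", "MG", "MN", "NI", "CO", "CD", "CL", "BR"):
        return two
    return stripped[0].upper()


def read_pdb(path, radii: dict | None = None) -> StructureModel:
    """Read a fixed-column PDB file into a :class:`StructureModel`.

    Altloc policy: within a residue, duplicate atom names keep the
    highest-occupancy altloc; ties go to altloc 'A' (alphabetically first).
    Raises :class:`PDBFormatError` naming the line number on malformed
    ATOM/HETATM records.  A missing CRYST1 yields ``model.cell is None``.
    """
    with open(path) as fh:
        lines = fh.readlines()
    return _parse_pdb(lines, radii, str(path))


def read_models(path, radii: dict | None = None) -> list[StructureModel]:
    """Read a multi-MODEL PDB file (e.g. an ensemble) as one model per MODEL."""
    with open(path) as fh:
        lines = fh.readlines()
    blocks: list[list[str]] = []
    current: list[str] | None = None
    header = [ln for ln in lines if ln.startswith("CRYST1")]
    for ln in lines:
        if ln.startswith("MODEL"):
            current = list(header)
        elif ln.startswith("ENDMDL"):
            if current is not None:
                blocks.append(current)
            current = None
        elif current is not None:
            current.append(ln)
    if not blocks:
        return [_parse_pdb(lines, radii, str(path))]
    return [_parse_pdb(b, radii, str(path)) for b in blocks]


def _parse_pdb(lines: Iterable[str], radii: dict | None, origin: str) -> StructureModel:
    radii = {**VDW_RADII, **(radii or {})}
    cell = None
    chains: dict[str, Chain] = {}
    n_records = 0
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec == "CRYST1":
            try:
                cell = CrystalCell(
                    float(line[6:15]), float(line[15:24]), float(line[24:33]),
                    float(line[33:40]), float(line[40:47]), float(line[47:54]))
            except (ValueError, IndexError) as exc:
                raise PDBFormatError(f"line {lineno}: bad CRYST1 record: {exc}") from exc
        elif rec in ("ATOM  ", "HETATM"):
            if len(line.rstrip("\n")) < 54:
                raise PDBFormatError(f"line {lineno}: truncated {rec.strip()} record")
            try:
                name = line[12:16].strip()
                altloc = line[16].strip()
                resname = line[17:20].strip()
                cid = line[21].strip() or " "
                resnum = int(line[22:26])
                icode = line[26].strip()
                pos = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                occ = float(line[54:60]) if line[54:60].strip() else 1.0
                bfac = float(line[60:66]) if line[60:66].strip() else 0.0
            except ValueError as exc:
                raise PDBFormatError(
                    f"line {lineno}: malformed {rec.strip()} record: {exc}") from exc
            element = line[76:78].strip().upper() or _infer_element(name, resname)
            atom = Atom(name, element, np.array(pos), occ, bfac,
                        radii.get(element, _DEFAULT_RADIUS), altloc)
            chain = chains.setdefault(cid, Chain(cid))
            res = None
            for r in reversed(chain.residues):
                if r.number == resnum and r.icode == icode:
                    res = r
                    break
            if res is None:
                res = Residue(resnum, resname, [], icode, rec == "HETATM")
                chain.residues.append(res)
            # altloc resolution: keep highest occupancy, tie -> 'A'
            existing = next((a for a in res.atoms if a.name == name), None)
            if existing is None:
                res.atoms.append(atom)
            elif (atom.occupancy, -ord(atom.altloc or "~")) > (
                    existing.occupancy, -ord(existing.altloc or "~")):
                res.atoms[res.atoms.index(existing)] = atom
            n_records += 1
    if n_records == 0:
        raise PDBFormatError(f"{origin}: no ATOM/HETATM records found")
    model = StructureModel(list(chains.values()), cell)
    if cell is not None:
        model.symmetry_ops = [(np.eye(3), np.zeros(3))]
    return model


def _format_atom_name(name: str, element: str) -> str:
    if len(name) > 4:
        raise ValueError(f"atom name {name!r} exceeds 4 characters")
    if len(element) == 1 and len(name) < 4:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(model: StructureModel, path) -> None:
    """Write fixed-column PDB. The R1 label is emitted as HETATM/R1A."""
    if not model.chains or all(not c.residues for c in model.chains):
        raise ValueError("cannot write an empty model")
    # PDB chain ids are single characters; longer ids (packing images) are
    # deterministically remapped.
    pool = list("ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789")
    used = {c.cid for c in model.chains if len(c.cid) == 1}
    mapping = {}
    for c in model.chains:
        if len(c.cid) == 1:
            mapping[c.cid] = c.cid
        else:
            nxt = next(x for x in pool if x not in used)
            used.add(nxt)
            mapping[c.cid] = nxt
    lines = []
    if model.cell is not None:
        cc = model.cell
        lines.append(
            f"CRYST1{cc.a:9.3f}{cc.b:9.3f}{cc.c:9.3f}"
            f"{cc.alpha:7.2f}{cc.beta:7.2f}{cc.gamma:7.2f} P 1           1")
    serial = 1
    for chain in model.chains:
        cid = mapping[chain.cid]
        last_was_protein = False
        for res in chain.residues:
            het = res.het or (res.name not in STANDARD_RESIDUES)
            rec = "HETATM" if het else "ATOM  "
            for a in res.atoms:
                nm = _format_atom_name(a.name, a.element)
                x, y, z = a.pos
                lines.append(
                    f"{rec}{serial % 100000:5d} {nm}{'':1s}{res.name:<3s} {cid}"
                    f"{res.number:4d}{res.icode or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
                    f"          {a.element:>2s}")
                serial += 1
            last_was_protein = not het
        if last_was_protein:
            lines.append(f"TER   {serial % 100000:5d}")
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Crystal-cell mathematics

def cell_volume(cell: CrystalCell) -> float:
    """Triclinic cell volume V = abc·sqrt(1 − Σcos² + 2·cosα·cosβ·cosγ) in Å³."""
    disc = cell.discriminant()
    if disc <= 0:
        raise ValueError("degenerate cell: non-positive volume discriminant")
    return cell.a * cell.b * cell.c * math.sqrt(disc)


def matthews_solvent(vm: float) -> float:
    """Solvent content (%) from the Matthews coefficient V_M (Å³/Da).

    Uses the standard relation 100·(1 − 1.23/V_M); V_M below 1.23 would imply
    a protein denser than the physical limit and is rejected.
    """
    if vm < 1.23:
        raise ValueError(f"Matthews coefficient {vm} below the physical limit 1.23")
    return 100.0 * (1.0 - 1.23 / vm)


# ---------------------------------------------------------------------------
# Crystal-packing expansion

def _image_chain(chain: Chain, rot: np.ndarray, tvec: np.ndarray,
                 M: np.ndarray, Minv: np.ndarray, suffix: str) -> Chain:
    out = chain.copy()
    out.cid = chain.cid + suffix
    for a in out.atoms():
        frac = Minv @ a.pos
        a.pos = M @ (rot @ frac + tvec)
    return out


def expand_packing(model: StructureModel, center_chain: str, cutoff: float) -> StructureModel:
    """Add symmetry/lattice images with any atom within ``cutoff`` of the center chain.

    For P1 (the only space group required) the operators are the identity plus
    integer lattice translations; general fractional operators stored on the
    model are honoured too.  Image chains get identifiers like ``A@1-0-1``.
    ``cutoff <= 0`` returns a copy of the input unchanged.
    """
    out = model.copy()
    if cutoff <= 0:
        return out
    if model.cell is None:
        raise ValueError("packing expansion requires a crystal cell; supply a CRYST1 record")
    center = model.chain(center_chain)
    M = model.cell.orthogonalization_matrix()
    Minv = np.linalg.inv(M)
    ops = model.symmetry_ops or [(np.eye(3), np.zeros(3))]

    center_xyz = np.array([a.pos for a in center.atoms()])
    tree = cKDTree(center_xyz)
    all_xyz = model.coords()
    frac_all = (Minv @ all_xyz.T).T

    # conservative fractional search range: model extent plus cutoff expressed
    # in interplanar spacings d_i = 1/|row_i(M^-1)|
    d = 1.0 / np.linalg.norm(Minv, axis=1)
    span = frac_all.max(axis=0) - frac_all.min(axis=0)
    nmax = np.ceil(span + cutoff / d).astype(int) + 1

    for k, (rot, tvec) in enumerate(ops):
        for n1 in range(-nmax[0], nmax[0] + 1):
            for n2 in range(-nmax[1], nmax[1] + 1):
                for n3 in range(-nmax[2], nmax[2] + 1):
                    shift = tvec + np.array([n1, n2, n3], dtype=float)
                    identity = (k == 0 and np.allclose(rot, np.eye(3))
                                and np.allclose(shift, 0.0))
                    if identity:
                        continue
                    img_xyz = (M @ (rot @ frac_all.T + shift[:, None])).T
                    dist, _ = tree.query(img_xyz, k=1,
                                         distance_upper_bound=cutoff)
                    if not np.any(np.isfinite(dist)):
                        continue
                    hit = np.flatnonzero(np.isfinite(dist))
                    # map hit atoms back to their chains; add every chain with a hit
                    idx = 0
                    suffix = f"@{k}:{n1},{n2},{n3}"
                    for chain in model.chains:
                        n = sum(1 for _ in chain.atoms())
                        if np.any((hit >= idx) & (hit < idx + n)):
                            out.chains.append(
                                _image_chain(chain, rot, shift, M, Minv, suffix))
                        idx += n
    return out
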