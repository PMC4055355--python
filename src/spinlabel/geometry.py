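"""R1 (MTSSL-cysteine) side-chain geometry.

Internal-coordinate template for the label, Cartesian construction of
conformers from the five linker dihedrals χ1–χ5 (NERF-style placement),
measurement of χ angles from coordinates, circular-angle arithmetic and
Kabsch superposition.

Sign convention for dihedrals is the IUPAC one: cis = 0°, trans = 180°,
positive clockwise when looking from the second to the third atom; all
angles are reported in (−180, 180].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .structure import Residue

__all__ = [
    "LabelTopology",
    "Conformer",
    "dihedral",
    "build_label",
    "measure_chi",
    "superpose_rmsd",
    "circular_difference",
    "default_topology",
    "R1_SIDECHAIN_ATOMS",
    "R1_ELEMENTS",
]

#: Heavy side-chain atoms of the R1 residue, in conventional order.
R1_SIDECHAIN_ATOMS = ("CB", "SG", "SD", "CE", "C3", "C4", "C5",
                      "C6", "C7", "C8", "C9", "N1", "O1")

R1_ELEMENTS = {
    "CB": "C", "SG": "S", "SD": "S", "CE": "C", "C3": "C", "C4": "C",
    "C5": "C", "C6": "C", "C7": "C", "C8": "C", "C9": "C", "N1": "N",
    "O1": "O",
}


def _wrap_angle(deg):
    """Map angle(s) in degrees onto (−180, 180]."""
    out = np.asarray(deg, dtype=float)
    out = -((-out + 180.0) % 360.0 - 180.0)
    return out if out.shape else float(out)


def circular_difference(a, b):
    """Minimal signed circular difference a − b in (−180, 180] degrees."""
    return _wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) of four points, IUPAC convention."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if min(np.linalg.norm(b1), np.linalg.norm(b2), np.linalg.norm(b3)) < 1e-9:
        raise ValueError("dihedral undefined: consecutive points coincide")
    c1 = np.cross(b1, b2)
    c2 = np.cross(b2, b3)
    if min(np.linalg.norm(c1), np.linalg.norm(c2)) < 1e-9:
        raise ValueError("dihedral undefined: collinear atom triple")
    y = np.dot(np.cross(c1, c2), b2 / np.linalg.norm(b2))
    x = np.dot(c1, c2)
    return float(_wrap_angle(math.degrees(math.atan2(y, x))))


def place_atoms(a, b, c, bond, angle, torsion):
    """NERF placement of point(s) D given reference frames (A, B, C).

    All arguments broadcast over a leading batch dimension; ``angle`` is the
    B–C–D bond angle and ``torsion`` the A–B–C–D dihedral, both in degrees.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    ang = np.radians(np.asarray(angle, dtype=float))
    tor = np.radians(np.asarray(torsion, dtype=float))
    bond = np.asarray(bond, dtype=float)
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    d0 = -bond * np.cos(ang)
    d1 = bond * np.sin(ang) * np.cos(tor)
    d2 = bond * np.sin(ang) * np.sin(tor)
    return c + d0[..., None] * bc + d1[..., None] * m + d2[..., None] * n


@dataclass(frozen=True)
class _TemplateAtom:
    name: str
    parent: str
    grand: str
    ggrand: str
    bond: float
    angle: float
    dihedral: float | str  # number or 'chiN'


@dataclass
class LabelTopology:
    """Internal-coordinate template of the R1 side chain.

    Atoms are placed in file order; each atom's position is defined by a bond
    length to its parent, a bond angle with its grandparent and a dihedral
    with its great-grandparent, the latter either fixed or one of χ1–χ5.
    """

    atoms: list[_TemplateAtom]
    chi_definitions: list[tuple[str, str, str, str]]
    spin_atoms: tuple[str, str] = ("N1", "O1")
    chi5_fourth_atom: str = "C4"

    def __post_init__(self) -> None:
        if len(self.chi_definitions) != 5:
            raise ValueError("topology must define exactly five chi angles")
        known = {"N", "CA", "CB"} | {a.name for a in self.atoms}
        for quad in self.chi_definitions:
            for nm in quad:
                if nm not in known:
                    raise ValueError(f"chi definition references unknown atom {nm!r}")
        for a in self.atoms:
            if not 1.0 < a.bond < 2.2:
                raise ValueError(f"template bond {a.name}: {a.bond} Å outside (1.0, 2.2)")

    @property
    def atom_names(self) -> tuple[str, ...]:
        return ("CB",) + tuple(a.name for a in self.atoms)

    def with_chi5_atom(self, fourth: str) -> "LabelTopology":
        defs = list(self.chi_definitions)
        defs[4] = defs[4][:3] + (fourth,)
        return LabelTopology(self.atoms, defs, self.spin_atoms, fourth)


def load_topology(path=None) -> LabelTopology:
    """Load a topology template from its plain-text serialization."""
    if path is None:
        text = (resources.files("spinlabel") / "data/r1_topology.txt").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    atoms: list[_TemplateAtom] = []
    chis: dict[int, tuple[str, str, str, str]] = {}
    spin = ("N1", "O1")
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "atom":
            name, parent, grand, ggrand = parts[1:5]
            bond, angle = float(parts[5]), float(parts[6])
            dih = parts[7] if parts[7].startswith("chi") else float(parts[7])
            atoms.append(_TemplateAtom(name, parent, grand, ggrand, bond, angle, dih))
        elif parts[0] == "chi":
            chis[int(parts[1])] = tuple(parts[2:6])
        elif parts[0] == "spin_center":
            spin = (parts[1], parts[2])
    return LabelTopology(atoms, [chis[i] for i in range(1, 6)], spin)


_DEFAULT_TOPOLOGY: LabelTopology | None = None


def default_topology() -> LabelTopology:
    global _DEFAULT_TOPOLOGY
    if _DEFAULT_TOPOLOGY is None:
        _DEFAULT_TOPOLOGY = load_topology()
    return _DEFAULT_TOPOLOGY


@dataclass
class Conformer:
    """One realized R1 conformation: χ angles plus Cartesian label atoms."""

    chi: np.ndarray
    atoms: dict[str, np.ndarray]
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.chi = _wrap_angle(np.asarray(self.chi, dtype=float))
        if self.chi.shape != (5,):
            raise ValueError("a conformer carries exactly five chi angles")
        if not 0.0 <= self.weight <= 1.0 + 1e-12:
            raise ValueError("conformer weight must lie in [0, 1]")

    def coords(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = names if names is not None else list(self.atoms)
        return np.array([self.atoms[n] for n in names])

    @property
    def mobile_atom_names(self) -> list[str]:
        """Label atoms that move with χ (everything beyond the fixed N/CA/CB)."""
        return [n for n in self.atoms if n not in ("N", "CA", "CB")]


def build_label_batch(backbone: Mapping[str, np.ndarray], chis: np.ndarray,
                      topo: LabelTopology | None = None) -> np.ndarray:
    """Build Cartesian coordinates for a batch of χ tuples.

    Returns an array of shape (n_batch, 1 + n_template_atoms, 3) whose first
    slot is CB (copied from the backbone) followed by the template atoms in
    topology order.
    """
    topo = topo or default_topology()
    for nm in ("N", "CA", "CB"):
        if nm not in backbone:
            raise ValueError(f"missing backbone atom {nm!r}")
    chis = np.atleast_2d(np.asarray(chis, dtype=float))
    nb = chis.shape[0]
    placed: dict[str, np.ndarray] = {
        nm: np.broadcast_to(np.asarray(backbone[nm], dtype=float), (nb, 3)).copy()
        for nm in ("N", "CA", "CB")
    }
    v1 = placed["CA"][0] - placed["N"][0]
    v2 = placed["CB"][0] - placed["CA"][0]
    if np.linalg.norm(np.cross(v1, v2)) < 1e-9:
        raise ValueError("degenerate backbone: N, CA, CB are collinear")
    for ta in topo.atoms:
        if isinstance(ta.dihedral, str):
            tor = chis[:, int(ta.dihedral[3:]) - 1]
        else:
            tor = np.full(nb, ta.dihedral)
        placed[ta.name] = place_atoms(placed[ta.ggrand], placed[ta.grand],
                                      placed[ta.parent], ta.bond, ta.angle, tor)
    return np.stack([placed[nm] for nm in topo.atom_names], axis=1)


def build_label(backbone: Mapping[str, np.ndarray], chi: Sequence[float],
                topo: LabelTopology | None = None, weight: float = 1.0) -> Conformer:
    """Construct one R1 conformer from backbone N/CA/CB and χ1–χ5 (degrees)."""
    topo = topo or default_topology()
    coords = build_label_batch(backbone, np.asarray(chi, dtype=float)[None, :], topo)[0]
    atoms = {"N": np.asarray(backbone["N"], dtype=float),
             "CA": np.asarray(backbone["CA"], dtype=float)}
    atoms.update({nm: coords[i] for i, nm in enumerate(topo.atom_names)})
    return Conformer(np.asarray(chi, dtype=float), atoms, weight)


def measure_chi(residue, topo: LabelTopology | None = None) -> np.ndarray:
    """Measure χ1–χ5 (degrees) of a labelled residue or atom-coordinate map."""
    topo = topo or default_topology()
    if isinstance(residue, Residue):
        coords = {a.name: a.pos for a in residue.atoms}
    elif isinstance(residue, Conformer):
        coords = dict(residue.atoms)
    else:
        coords = {k: np.asarray(v, dtype=float) for k, v in residue.items()}
    missing = sorted({nm for quad in topo.chi_definitions for nm in quad} - set(coords))
    if missing:
        raise ValueError(f"cannot measure chi: missing atoms {', '.join(missing)}")
    return np.array([dihedral(*(coords[nm] for nm in quad))
                     for quad in topo.chi_definitions])


def superpose_rmsd(ref, mov, pairing: Sequence[tuple[int, int]] | None = None):
    """Least-squares rigid superposition (Kabsch) of mov onto ref.

    Returns ``(rmsd, (rotation, translation))`` with a proper rotation
    enforced; ``pairing`` maps ref indices to mov indices (default: identity).
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if pairing is not None:
        ri, mi = zip(*pairing)
        ref, mov = ref[list(ri)], mov[list(mi)]
    if len(ref) != len(mov):
        raise ValueError("point sets must pair one-to-one")
    if len(ref) < 3:
        raise ValueError("superposition requires at least 3 paired points")
    rc, mc = ref.mean(axis=0), mov.mean(axis=0)
    P, Q = ref - rc, mov - mc
    if np.linalg.matrix_rank(np.vstack([P, Q]), tol=1e-8) < 2:
        raise ValueError("superposition undefined: all points collinear")
    H = Q.T @ P
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    moved = (R @ mov.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rmsd, (R, t)
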