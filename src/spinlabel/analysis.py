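"""Comparison metrics for label ensembles and their environments.

Covers the quantities used to confront predicted label ensembles with an
experimentally observed conformation: occupancy-weighted mean spin positions,
inter-ensemble distances and distance distributions, angular deviation of
distance vectors, χ-angle deviation from a rotamer library, solvent
accessible / buried surface area (deterministic Shrake–Rupley), and
Ligplot-style distance-based contact listing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Conformer, circular_difference
from .prediction import LabelEnsemble, RotamerLibrary
from .structure import Atom, Residue, StructureModel

__all__ = [
    "SurfaceReport",
    "DistanceComparison",
    "Contact",
    "spin_center",
    "mean_spin_position",
    "ensemble_distance",
    "vector_angle_deviation",
    "sasa",
    "buried_sasa",
    "chi_deviation",
    "contacts",
    "bounding_box_volume",
]

SPIN_CENTER_RULES = ("N1", "NO_midpoint")


def spin_center(conformer, rule: str = "N1") -> np.ndarray:
    """Spin-center point of a conformer: the N1 atom or the N1–O1 midpoint."""
    if rule not in SPIN_CENTER_RULES:
        raise ValueError(f"unknown spin-center rule {rule!r}; use one of {SPIN_CENTER_RULES}")
    atoms = conformer.atoms if isinstance(conformer, Conformer) else {
        a.name: a.pos for a in conformer.atoms}
    if "N1" not in atoms:
        raise ValueError("conformer lacks nitroxide atom N1")
    if rule == "N1":
        return np.asarray(atoms["N1"], dtype=float)
    if "O1" not in atoms:
        raise ValueError("NO_midpoint rule requires atom O1")
    return 0.5 * (np.asarray(atoms["N1"], dtype=float)
                  + np.asarray(atoms["O1"], dtype=float))


def mean_spin_position(ensemble: LabelEnsemble, rule: str = "N1") -> np.ndarray:
    """Occupancy-weighted geometric average of the ensemble's spin centers."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble has no mean spin position")
    centers = np.array([spin_center(c, rule) for c in ensemble.conformers])
    return ensemble.weights @ centers


def ensemble_distance(a: LabelEnsemble, b: LabelEnsemble, rule: str = "N1"):
    """Distance between two label ensembles.

    Returns ``(mean_position_distance, (pair_distances, pair_weights))`` where
    the distance between the two occupancy-weighted mean positions is the
    single-number prediction and the weighted set of all inter-conformer
    spin-center distances is the PELDOR-like distance distribution
    (weights w_i·w_j).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("ensemble_distance requires two non-empty ensembles")
    mean_dist = float(np.linalg.norm(mean_spin_position(a, rule)
                                     - mean_spin_position(b, rule)))
    ca = np.array([spin_center(c, rule) for c in a.conformers])
    cb = np.array([spin_center(c, rule) for c in b.conformers])
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1).ravel()
    w = np.outer(a.weights, b.weights).ravel()
    return mean_dist, (d, w)


def vector_angle_deviation(experimental: tuple, predicted: tuple) -> float:
    """Angle (degrees, in [0, 180]) between two site-pair distance vectors."""
    va = np.asarray(experimental[1], float) - np.asarray(experimental[0], float)
    vb = np.asarray(predicted[1], float) - np.asarray(predicted[0], float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("zero-length distance vector")
    cosang = np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# Solvent accessible surface area (Shrake–Rupley, deterministic golden spiral)

@dataclass
class SurfaceReport:
    total_asa: float                    # Å²
    buried_asa: float = 0.0             # Å²
    per_atom: dict = field(default_factory=dict)
    probe: float = 1.4
    n_points: int = 960

    def __post_init__(self) -> None:
        if self.per_atom and abs(sum(self.per_atom.values()) - self.total_asa) > 0.1:
            raise ValueError("per-atom areas do not sum to the total ASA")
        if not -1e-9 <= self.buried_asa <= self.total_asa + 1e-9:
            raise ValueError("buried area outside [0, total]")


def _golden_spiral(n: int) -> np.ndarray:
    """n deterministic, near-uniform points on the unit sphere."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_list(obj) -> list[Atom]:
    from .structure import Chain
    if isinstance(obj, (StructureModel, Chain)):
        return [a for a in obj.atoms() if a.element != "H"]
    if isinstance(obj, Residue):
        return [a for a in obj.atoms if a.element != "H"]
    return [a for a in obj if a.element != "H"]


def sasa(atom_set, context, probe: float = 1.4, n_points: int = 960) -> SurfaceReport:
    """Shrake–Rupley solvent-accessible surface area of ``atom_set``.

    ``context`` supplies the occluding heavy atoms (it may, but need not,
    contain the atom set itself; the set always occludes its own members).
    Sphere quadrature uses a deterministic golden-spiral point set, so areas
    are exactly reproducible.
    """
    atoms = _atom_list(atom_set)
    if not atoms:
        raise ValueError("empty atom set")
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 100:
        raise ValueError("need at least 100 quadrature points per atom")
    occluders = _atom_list(context)
    ids = {id(a) for a in occluders}
    occluders.extend(a for a in atoms if id(a) not in ids)
    occ_xyz = np.array([a.pos for a in occluders])
    occ_r = np.array([a.vdw_radius + probe for a in occluders])
    tree = cKDTree(occ_xyz)
    rmax = occ_r.max()
    sphere = _golden_spiral(n_points)

    per_atom: dict = {}
    total = 0.0
    for a in atoms:
        ra = a.vdw_radius + probe
        pts = a.pos + ra * sphere
        neigh = [j for j in tree.query_ball_point(a.pos, ra + rmax)
                 if occluders[j] is not a]
        if neigh:
            dif = pts[:, None, :] - occ_xyz[neigh][None, :, :]
            inside = (np.einsum("ijk,ijk->ij", dif, dif)
                      < (occ_r[neigh] ** 2)[None, :]).any(axis=1)
            n_acc = int((~inside).sum())
        else:
            n_acc = n_points
        area = 4.0 * math.pi * ra * ra * n_acc / n_points
        per_atom[a.name] = per_atom.get(a.name, 0.0) + area
        total += area
    return SurfaceReport(total_asa=total, per_atom=per_atom,
                         probe=probe, n_points=n_points)


def buried_sasa(atom_set, own_context, full_context,
                probe: float = 1.4, n_points: int = 960) -> SurfaceReport:
    """ASA of a set in its full context plus the area buried by the rest.

    The reported total is the ASA the set has in its own chain's context
    alone; the buried area is the part of that total lost in the full
    context (the PISA-style interface bookkeeping).
    """
    alone = sasa(atom_set, own_context, probe, n_points)
    full = sasa(atom_set, full_context, probe, n_points)
    return SurfaceReport(total_asa=alone.total_asa,
                         buried_asa=max(0.0, alone.total_asa - full.total_asa),
                         per_atom=alone.per_atom, probe=probe, n_points=n_points)


# ---------------------------------------------------------------------------
# χ-distribution comparison

def chi_deviation(observed, library: RotamerLibrary,
                  convention: str = "C4"):
    """Nearest library entry under the max-over-angles circular metric.

    Returns ``(index, signed_deltas, max_abs_delta)`` where ``signed_deltas``
    are the five minimal signed circular differences observed − entry for the
    nearest entry.  χ5 conventions of the measurement and the library must
    match.
    """
    if convention != library.chi5_convention:
        raise ValueError(
            f"chi5 convention mismatch: observed uses {convention!r}, "
            f"library uses {library.chi5_convention!r}")
    observed = np.asarray(observed, dtype=float)
    deltas = circular_difference(observed[None, :], library.chis)
    maxima = np.abs(deltas).max(axis=1)
    idx = int(np.argmin(maxima))
    return idx, deltas[idx], float(maxima[idx])


# ---------------------------------------------------------------------------
# Contact listing

@dataclass(frozen=True)
class Contact:
    kind: str                 # 'polar' | 'vdw'
    atom: str
    partner_atom: str
    partner_residue: str      # e.g. 'THR 126'
    partner_chain: str
    same_chain: bool
    distance: float


def contacts(residue: Residue, model: StructureModel, *, chain_id: str | None = None,
             vdw_slack: float = 0.5, polar_cutoff: float = 3.5) -> list[Contact]:
    """Distance-based contact classification for one residue.

    A pair is polar iff both atoms are N/O and closer than ``polar_cutoff``;
    otherwise it is a vdW contact iff closer than r_i + r_j + ``vdw_slack``.
    Peptide-bond partners (backbone C/N of adjacent residues in the same
    chain) are excluded as covalent.
    """
    out: list[Contact] = []
    own = [a for a in residue.atoms if a.element != "H"]
    for chain in model.chains:
        for res in chain.residues:
            if res is residue:
                continue
            adjacent = (chain_id is not None and chain.cid == chain_id
                        and res.icode == residue.icode
                        and abs(res.number - residue.number) == 1)
            for b in res.atoms:
                if b.element == "H":
                    continue
                for a in own:
                    if adjacent and {a.name, b.name} == {"C", "N"}:
                        continue
                    d = float(np.linalg.norm(a.pos - b.pos))
                    if a.element in ("N", "O") and b.element in ("N", "O") \
                            and d < polar_cutoff:
                        kind = "polar"
                    elif d < a.vdw_radius + b.vdw_radius + vdw_slack:
                        kind = "vdw"
                    else:
                        continue
                    out.append(Contact(kind, a.name, b.name,
                                       f"{res.name} {res.number}{res.icode}",
                                       chain.cid,
                                       chain_id is not None and chain.cid == chain_id,
                                       d))
    out.sort(key=lambda c: (c.partner_chain, c.partner_residue, c.atom, c.partner_atom))
    return out


def bounding_box_volume(points: np.ndarray) -> float:
    """Axis-aligned bounding-box volume of a point cloud (Å³)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    ext = pts.max(axis=0) - pts.min(axis=0)
    return float(np.prod(ext))
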