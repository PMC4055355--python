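"""Synthetic labelling fixtures with planted ground truth.

Emulates the two regimes a spin label meets in a protein crystal: an
idealized solvent-exposed ("open") helix site, and the same site occluded by
a second, deterministically placed helix that mimics a crystal contact
("tight").  Every fixture carries a planted R1 conformation with known
χ1–χ5, guaranteed clash-free at construction, so the whole pipeline can be
exercised without any downloaded structure.  A von Mises mixture generator
provides synthetic rotamer libraries with the canonical χ well structure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (Conformer, R1_ELEMENTS, build_label, circular_difference,
                       default_topology, place_atoms)
from .prediction import ClashEngine, RotamerLibrary, clash_count, site_environment
from .structure import (Atom, Chain, Residue, StructureModel, VDW_RADII,
                        R1_RESIDUE_NAME)

__all__ = [
    "SyntheticSite",
    "make_helix",
    "make_open_site",
    "make_tight_site",
    "make_synthetic_library",
    "plant_label",
    "write_fixture",
]

#: default planted conformation: canonical wells, clash-free on the ideal helix
DEFAULT_PLANTED_CHI = (180.0, -60.0, -90.0, 180.0, 10.0)

# ideal backbone internal coordinates (Engh-Huber-style values)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_N_CA_CB = 120.8, 110.5
_T_CB = -120.0          # dihedral(C, N, CA, CB) for an L-amino acid


@dataclass
class SyntheticSite:
    """A generated model with one labelling site and its planted truth."""

    model: StructureModel
    site: tuple[str, int]
    planted_chi: tuple[float, ...] | None
    regime: str                       # 'open' | 'tight'
    occluder_chain: str | None = None
    seed: int = 0
    params: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "site": list(self.site),
            "planted_chi": list(self.planted_chi) if self.planted_chi else None,
            "regime": self.regime,
            "occluder_chain": self.occluder_chain,
            "seed": self.seed,
            "params": self.params,
        }


def _mk_atom(name: str, pos, element: str | None = None) -> Atom:
    el = element or name[0]
    return Atom(name, el, np.asarray(pos, float),
                vdw_radius=VDW_RADII.get(el, 1.70))


def make_helix(n_res: int = 18, phi: float = -57.0, psi: float = -47.0,
               chain_id: str = "A") -> StructureModel:
    """Ideal poly-alanine fragment at fixed (φ, ψ); default is α-helical.

    Backbone geometry is exactly repetitive, so consecutive Cα–Cα distances
    are equal and (at the default angles) the i→i+4 carbonyl-O…N spacing
    falls in the hydrogen-bonding range.
    """
    if n_res < 5:
        raise ValueError("a helix fragment needs at least 5 residues")
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - _A_N_CA_C)
    c = ca + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    chain = Chain(chain_id)
    for i in range(1, n_res + 1):
        if i > 1:
            prev = chain.residues[-1]
            prev_n, prev_ca, prev_c = (prev.atom(nm).pos for nm in ("N", "CA", "C"))
            n = place_atoms(prev_n, prev_ca, prev_c, _B_C_N, _A_CA_C_N, psi)
            ca = place_atoms(prev_ca, prev_c, n, _B_N_CA, _A_C_N_CA, 180.0)  # omega trans
            c = place_atoms(prev_c, n, ca, _B_CA_C, _A_N_CA_C, phi)
        o = place_atoms(n, ca, c, _B_C_O, _A_CA_C_O, psi + 180.0)
        cb = place_atoms(c, n, ca, _B_CA_CB, _A_N_CA_CB, _T_CB)
        res = Residue(i, "ALA", [
            _mk_atom("N", n, "N"), _mk_atom("CA", ca, "C"),
            _mk_atom("C", c, "C"), _mk_atom("O", o, "O"),
            _mk_atom("CB", cb, "C")])
        chain.residues.append(res)
    return StructureModel([chain])


def plant_label(model: StructureModel, site: tuple[str, int],
                chi, topo=None) -> Conformer:
    """Replace a residue by an R1 side chain built at the given χ1–χ5.

    The residue keeps its backbone (N, CA, C, O, CB) and gains the label
    atoms; its name becomes the R1 residue name so written files round-trip.
    Returns the planted conformer.
    """
    topo = topo or default_topology()
    cid, resnum = site
    res = model.chain(cid).residue(resnum)
    backbone = {nm: res.atom(nm).pos for nm in ("N", "CA", "CB")}
    conf = build_label(backbone, chi, topo)
    res.name = R1_RESIDUE_NAME
    res.het = True
    res.atoms = [a for a in res.atoms if a.name in ("N", "CA", "C", "O", "CB")]
    for nm in topo.atom_names[1:]:
        el = R1_ELEMENTS.get(nm, nm[0])
        res.atoms.append(_mk_atom(nm, conf.atoms[nm], el))
    return conf


def make_open_site(n_res: int = 18, site_number: int | None = None,
                   planted_chi=DEFAULT_PLANTED_CHI, seed: int = 0) -> SyntheticSite:
    """Helix with a surface R1 site; the planted conformer is clash-free."""
    site_number = site_number or (n_res // 2 + 1)
    if not 2 <= site_number <= n_res - 1:
        raise ValueError("labelling site must be interior to the chain")
    model = make_helix(n_res)
    site = ("A", site_number)
    conf = plant_label(model, site, planted_chi)
    n_clash = clash_count(conf, site_environment(model, site), scale=0.9)
    if n_clash > 0:
        raise ValueError(
            f"planted chi {tuple(planted_chi)} clashes with the helix backbone "
            f"({n_clash} overlaps at scale 0.9); choose different chi")
    return SyntheticSite(model, site, tuple(planted_chi), "open", None, seed,
                         params={"n_res": n_res})


def _principal_axis(xyz: np.ndarray) -> np.ndarray:
    centered = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    return axis if axis[0] >= 0 else -axis


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector u onto unit vector v."""
    w = np.cross(u, v)
    s, c = np.linalg.norm(w), float(np.dot(u, v))
    if s < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(u, u)
    K = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + K + K @ K * ((1 - c) / (s * s))


def _decoy_chis(planted) -> list[np.ndarray]:
    """Probe conformations used to score how much χ space an occluder blocks:
    single-angle shifts of the planted χ plus the χ1/χ2 double shifts."""
    decoys = []
    for i in range(5):
        for shift in (60.0, 120.0, 180.0, -120.0, -60.0):
            chi = np.array(planted, dtype=float)
            chi[i] = circular_difference(chi[i] + shift, 0.0)
            decoys.append(chi)
    for s1 in (-120.0, 120.0):
        for s2 in (-120.0, 120.0):
            chi = np.array(planted, dtype=float)
            chi[0] = circular_difference(chi[0] + s1, 0.0)
            chi[1] = circular_difference(chi[1] + s2, 0.0)
            decoys.append(chi)
    return decoys


def make_tight_site(n_res: int = 18, site_number: int | None = None,
                    planted_chi=DEFAULT_PLANTED_CHI, occluder_gap: float = 4.0,
                    seed: int = 0) -> SyntheticSite:
    """Open site plus a second helix emulating a crystal contact.

    The occluder helix is placed by a deterministic grid search over lateral
    directions around the label: among placements whose nearest approach to
    the planted conformer lies just outside ``occluder_gap`` (so the planted
    conformation stays clash-free) the one blocking the most decoy
    conformations (χ shifted by ±120°) is kept.
    """
    if occluder_gap < 3.5:
        raise ValueError("occluder_gap below 3.5 Å would clash with the planted label")
    base = make_open_site(n_res, site_number, planted_chi, seed)
    model, site = base.model, base.site
    res = model.chain("A").residue(site[1])
    backbone = {nm: res.atom(nm).pos for nm in ("N", "CA", "CB")}
    planted = build_label(backbone, planted_chi)
    label_xyz = planted.coords(planted.mobile_atom_names)

    helix_xyz = np.array([r.atom("CA").pos for r in model.chain("A").residues])
    axis = _principal_axis(helix_xyz)
    ca, cb = res.atom("CA").pos, res.atom("CB").pos
    u = cb - (ca + np.dot(cb - ca, axis) * axis)
    u = u / np.linalg.norm(u)
    w = np.cross(axis, u)

    occ0 = make_helix(n_res, chain_id="B")
    occ_xyz0 = np.array([a.pos for a in occ0.chain("B").atoms()])
    occ_axis = _principal_axis(np.array([r.atom("CA").pos
                                         for r in occ0.chain("B").residues]))
    helix_all = np.array([a.pos for a in model.chain("A").atoms()])
    decoys = [build_label(backbone, chi).coords(planted.mobile_atom_names)
              for chi in _decoy_chis(planted_chi)]
    label_radii = np.full(label_xyz.shape[0], 1.70)

    def place(orient: np.ndarray, direction: np.ndarray):
        # slide the occluder centroid out from CB along `direction` until it
        # clears both the planted label (by the gap) and the host helix
        rot = _rotation_between(occ_axis, orient)
        occ_c = (occ_xyz0 - occ_xyz0.mean(axis=0)) @ rot.T

        def clearance(t: float) -> float:
            xyz = occ_c + cb + t * direction
            dl = np.min(np.linalg.norm(xyz[:, None, :] - label_xyz[None, :, :],
                                       axis=-1))
            dh = np.min(np.linalg.norm(xyz[:, None, :] - helix_all[None, :, :],
                                       axis=-1))
            return min(dl - occluder_gap, dh - 3.4)

        lo, hi = 0.0, 60.0
        if clearance(hi) < 0:
            return None, -1, []
        for _ in range(48):
            mid = 0.5 * (lo + hi)
            if clearance(mid) < 0:
                lo = mid
            else:
                hi = mid
        xyz = occ_c + cb + hi * direction
        engine = ClashEngine([_mk_atom("X", p, "C") for p in xyz])
        blocked = [engine.count(d, label_radii, 0.9) > 0 for d in decoys]
        return xyz, sum(blocked), blocked

    orients = [axis, w, (axis + w) / math.sqrt(2.0), (axis - w) / math.sqrt(2.0)]
    # the chi2+120 probe is the canonical failure-mode conformation and must
    # be blocked by any acceptable placement
    chi2_probe = 5 * 1 + 1
    best, best_score = None, 0
    for orient in orients:
        for theta in range(-90, 91, 15):
            t = math.radians(theta)
            direction = math.cos(t) * u + math.sin(t) * w
            xyz, score, blocked = place(orient, direction)
            if xyz is not None and blocked[chi2_probe] and score > best_score:
                best, best_score = xyz, score
    if best is None:
        raise ValueError("could not place an occluder helix satisfying the "
                         "gap constraint while blocking any decoy conformer")

    occluder = occ0.chain("B")
    i = 0
    for r in occluder.residues:
        for a in r.atoms:
            a.pos = best[i]
            i += 1
    model.chains.append(occluder)
    # construction guarantee: the planted conformer stays clash-free
    n_clash = clash_count(planted, site_environment(model, site), scale=0.9)
    if n_clash > 0:
        raise ValueError("internal error: occluder placement clashes with the "
                         "planted conformer")
    return SyntheticSite(model, site, tuple(planted_chi), "tight", "B", seed,
                         params={"n_res": n_res, "occluder_gap": occluder_gap,
                                 "decoys_blocked": int(best_score)})


#: canonical χ well centers of the synthetic library generator (degrees)
LIBRARY_CENTERS = {
    "chi1": (-60.0, 60.0, 180.0),
    "chi2": (-60.0, 60.0, 180.0),
    "chi3": (-90.0, 90.0),
    "chi4": (-75.0, 75.0, 180.0),
    "chi5": (-90.0, 90.0),
}


def make_synthetic_library(n_entries: int = 216, concentration: float = 16.0,
                           seed: int = 0) -> RotamerLibrary:
    """Synthetic MTSSL-like rotamer library from von Mises mixtures.

    χ1–χ3 cluster at the canonical staggered/disulfide minima; χ4 and χ5 use
    broader mixtures (half and quarter concentration), echoing the soft outer
    dihedrals of MD-derived libraries.  Priors are Dirichlet-uniform.  With
    ``concentration=inf`` every angle sits exactly at a mixture center.
    """
    if n_entries < 3:
        raise ValueError("a library needs at least 3 entries")
    rng = np.random.default_rng(seed)
    kappas = [concentration, concentration, concentration,
              concentration / 2.0, concentration / 4.0]
    chis = np.empty((n_entries, 5))
    for j, key in enumerate(LIBRARY_CENTERS):
        centers = np.asarray(LIBRARY_CENTERS[key])
        pick = rng.integers(0, len(centers), size=n_entries)
        mu = centers[pick]
        if math.isinf(concentration):
            chis[:, j] = mu
        else:
            draw = rng.vonmises(np.radians(mu), kappas[j])
            chis[:, j] = np.degrees(draw)
    priors = rng.dirichlet(np.ones(n_entries))
    lib = RotamerLibrary(chis, priors, name=f"synthetic-vm-{seed}",
                         chi5_convention="C4")
    lib.metadata.update({
        "generator": "von Mises mixture",
        "centers": {k: list(v) for k, v in LIBRARY_CENTERS.items()},
        "concentration": concentration,
        "kappas": kappas,
        "seed": seed,
    })
    return lib


def write_fixture(synthetic_site: SyntheticSite, outdir, library=None) -> dict:
    """Write fixture PDB + manifest (+ optional library) for the CLI."""
    import pathlib

    from .prediction import save_library
    from .structure import write_pdb

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"pdb": str(outdir / f"{synthetic_site.regime}_site.pdb"),
             "manifest": str(outdir / "manifest.json")}
    write_pdb(synthetic_site.model, paths["pdb"])
    if library is not None:
        paths["library"] = str(outdir / "library.txt")
        save_library(library, paths["library"])
    manifest = synthetic_site.manifest()
    manifest["files"] = paths
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
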