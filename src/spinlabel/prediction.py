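"""Label-ensemble prediction: accessible-volume sampling and the rotamer approach.

Two paradigms are implemented behind one :class:`LabelEnsemble` container:

* accessible volume — χ1–χ5 drawn uniformly at random, conformers kept iff
  they pass a hard clash criterion, all survivors weighted equally;
* rotamer library — every entry of a precomputed χ library is built at the
  site and reweighted by a Boltzmann factor of a soft clash-overlap energy,
  yielding per-rotamer occupancies and a partition function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (Conformer, LabelTopology, build_label, build_label_batch,
                       default_topology)
from .structure import Atom, StructureModel, VDW_RADII

__all__ = [
    "RotamerLibrary",
    "LabelEnsemble",
    "ClashEngine",
    "clash_count",
    "sample_accessible_volume",
    "place_rotamers",
    "boltzmann_occupancies",
    "load_library",
    "save_library",
    "site_environment",
]

#: Default distance-scale applied to vdW radius sums in the hard clash test.
DEFAULT_SCALE = 0.75
DEFAULT_MAX_CLASHES = 5
DEFAULT_N_CONFORMERS = 200
DEFAULT_MAX_TRIALS = 50_000


@dataclass
class RotamerLibrary:
    """Discrete χ tuples with prior occupancies (normalized on construction)."""

    chis: np.ndarray                   # (n, 5) degrees
    priors: np.ndarray                 # (n,) sums to 1
    name: str = "unnamed"
    chi5_convention: str = "C4"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chis = np.atleast_2d(np.asarray(self.chis, dtype=float))
        self.priors = np.asarray(self.priors, dtype=float)
        if len(self.chis) == 0:
            raise ValueError("rotamer library needs at least one entry")
        if self.chis.shape[1] != 5 or self.priors.shape != (len(self.chis),):
            raise ValueError("library shape mismatch: need (n,5) chis and (n,) priors")
        if np.any(self.priors < 0):
            raise ValueError("prior weights must be non-negative")
        total = self.priors.sum()
        if total <= 0:
            raise ValueError("prior weights sum to zero")
        self.priors = self.priors / total

    def __len__(self) -> int:
        return len(self.chis)


@dataclass
class LabelEnsemble:
    """Weighted conformer set predicted at one site by one method."""

    site: tuple[str, int]
    method: str                        # 'accessible_volume' | 'rotamer'
    conformers: list[Conformer]
    partition_function: float
    n_trials: int = 0
    acceptance_fraction: float | None = None
    seed: int | None = None
    params: dict = field(default_factory=dict)
    diagnostic: str = ""

    def __post_init__(self) -> None:
        if self.conformers:
            w = sum(c.weight for c in self.conformers)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"ensemble weights sum to {w}, expected 1")

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.conformers])

    def chi_matrix(self) -> np.ndarray:
        return np.array([c.chi for c in self.conformers])

    def with_equal_weights(self) -> "LabelEnsemble":
        """Same conformers, occupancies forced equal (the free-occupancy limit)."""
        n = len(self.conformers)
        if n == 0:
            return self
        conf = [Conformer(c.chi, dict(c.atoms), 1.0 / n) for c in self.conformers]
        return LabelEnsemble(self.site, self.method, conf, self.partition_function,
                             self.n_trials, self.acceptance_fraction, self.seed,
                             dict(self.params), self.diagnostic)


class ClashEngine:
    """kd-tree backed steric overlap checks against a fixed environment."""

    def __init__(self, environment_atoms: Sequence[Atom]):
        self.atoms = [a for a in environment_atoms if a.element != "H"]
        self.xyz = (np.array([a.pos for a in self.atoms])
                    if self.atoms else np.empty((0, 3)))
        self.radii = np.array([a.vdw_radius for a in self.atoms])
        self.tree = cKDTree(self.xyz) if len(self.atoms) else None
        self._rmax = float(self.radii.max()) if len(self.atoms) else 0.0

    def count(self, coords: np.ndarray, label_radii: np.ndarray,
              scale: float) -> int:
        """Number of label/environment pairs with d < scale·(r_i + r_j)."""
        if self.tree is None:
            return 0
        n = 0
        search = scale * (label_radii + self._rmax)
        for p, r, s in zip(coords, label_radii, search):
            for j in self.tree.query_ball_point(p, s):
                if np.linalg.norm(p - self.xyz[j]) < scale * (r + self.radii[j]):
                    n += 1
        return n

    def soft_energy(self, coords: np.ndarray, label_radii: np.ndarray,
                    scale: float) -> float:
        """Quartic soft-overlap penalty Σ max(0, scale·(r_i+r_j) − d)⁴ (kT/Å⁴)."""
        if self.tree is None:
            return 0.0
        e = 0.0
        search = scale * (label_radii + self._rmax)
        for p, r, s in zip(coords, label_radii, search):
            for j in self.tree.query_ball_point(p, s):
                d = np.linalg.norm(p - self.xyz[j])
                overlap = scale * (r + self.radii[j]) - d
                if overlap > 0:
                    e += overlap ** 4
        return e


def clash_count(conformer: Conformer, environment, scale: float = DEFAULT_SCALE) -> int:
    """Count label/environment atom pairs closer than ``scale`` times the vdW sum.

    Only the mobile label atoms (SG onward) are tested: N/CA/CB are shared
    with the host residue and would register covalent neighbours as clashes.
    The caller must already have excluded the labelled residue itself from
    ``environment`` (a :class:`StructureModel` or sequence of atoms).
    """
    if not conformer.atoms:
        raise ValueError("empty conformer")
    if not 0.0 < scale <= 1.5:
        raise ValueError("scale must lie in (0, 1.5]")
    engine = environment if isinstance(environment, ClashEngine) else ClashEngine(
        list(environment.heavy_atoms()) if isinstance(environment, StructureModel)
        else list(environment))
    names = conformer.mobile_atom_names
    coords = conformer.coords(names)
    radii = np.array([VDW_RADII.get(_element_of(nm), 1.70) for nm in names])
    return engine.count(coords, radii, scale)


def _element_of(atom_name: str) -> str:
    from .geometry import R1_ELEMENTS
    return R1_ELEMENTS.get(atom_name, atom_name[0])


def site_environment(model: StructureModel, site: tuple[str, int],
                     include_solvent: bool = False) -> ClashEngine:
    """Clash environment for a site: every heavy atom except the site residue.

    Waters and cryoprotectant molecules are excluded by default, mirroring
    the convention of published labelling programs; pass
    ``include_solvent=True`` to keep them.
    """
    from .structure import CRYO_NAMES, WATER_NAMES
    cid, resnum = site
    atoms: list[Atom] = []
    for chain in model.chains:
        for res in chain.residues:
            if chain.cid == cid and res.number == resnum:
                continue
            if not include_solvent and res.name in (WATER_NAMES | CRYO_NAMES):
                continue
            atoms.extend(a for a in res.atoms if a.element != "H")
    return ClashEngine(atoms)


def _site_backbone(model: StructureModel, site: tuple[str, int]) -> dict:
    cid, resnum = site
    res = model.chain(cid).residue(resnum)
    missing = [nm for nm in ("N", "CA", "CB") if not res.has_atom(nm)]
    if missing:
        raise ValueError(
            f"site {cid}:{resnum} lacks backbone atom(s) {', '.join(missing)}; "
            "a CB (mutate-to-CYS geometry) is required")
    return {nm: res.atom(nm).pos for nm in ("N", "CA", "CB")}


def _label_radii(topo: LabelTopology) -> np.ndarray:
    # mobile template atoms (topology order, CB excluded)
    return np.array([VDW_RADII.get(_element_of(nm), 1.70)
                     for nm in topo.atom_names[1:]])


def sample_accessible_volume(site, model: StructureModel, *,
                             n_conformers: int = DEFAULT_N_CONFORMERS,
                             max_trials: int = DEFAULT_MAX_TRIALS,
                             scale: float = DEFAULT_SCALE,
                             max_clashes: int = DEFAULT_MAX_CLASHES,
                             seed: int = 0,
                             topo: LabelTopology | None = None,
                             environment: ClashEngine | None = None,
                             include_solvent: bool = False) -> LabelEnsemble:
    """Accessible-volume prediction: uniform random χ, hard clash filter.

    χ tuples are drawn uniformly on (−180, 180]⁵; a conformer is accepted iff
    its clash count at ``scale`` does not exceed ``max_clashes``.  Sampling
    stops after ``n_conformers`` acceptances or ``max_trials`` attempts; all
    accepted conformers carry equal weight.
    """
    topo = topo or default_topology()
    backbone = _site_backbone(model, site)
    engine = environment or site_environment(model, site, include_solvent)
    radii = _label_radii(topo)
    rng = np.random.default_rng(seed)
    params = dict(n_conformers=n_conformers, max_trials=max_trials,
                  scale=scale, max_clashes=max_clashes)

    accepted: list[np.ndarray] = []
    trials = 0
    batch = 128
    while trials < max_trials and len(accepted) < n_conformers:
        nb = min(batch, max_trials - trials)
        chis = rng.uniform(-180.0, 180.0, size=(nb, 5))
        coords = build_label_batch(backbone, chis, topo)
        for k in range(nb):
            trials += 1
            if engine.count(coords[k, 1:], radii, scale) <= max_clashes:
                accepted.append(chis[k])
                if len(accepted) >= n_conformers:
                    break
    if not accepted:
        return LabelEnsemble(site, "accessible_volume", [], 0.0, trials, 0.0,
                             seed, params,
                             diagnostic="no sterically allowed conformer found; "
                                        "site appears fully buried")
    w = 1.0 / len(accepted)
    conformers = [build_label(backbone, chi, topo, weight=w) for chi in accepted]
    return LabelEnsemble(site, "accessible_volume", conformers,
                         partition_function=float(len(accepted)),
                         n_trials=trials,
                         acceptance_fraction=len(accepted) / trials,
                         seed=seed, params=params)


def boltzmann_occupancies(priors: np.ndarray, energies: np.ndarray,
                          kt: float = 1.0) -> tuple[np.ndarray, float]:
    """Occupancies w_i ∝ prior_i·exp(−E_i/kT) and the partition function Σw.

    In the limit kT → 0 all weight concentrates on the minimum-energy entries.
    """
    priors = np.asarray(priors, dtype=float)
    energies = np.asarray(energies, dtype=float)
    if kt <= 0:
        w = np.where(energies == energies.min(), priors, 0.0)
        return w / w.sum(), float(w.sum())
    # subtract the minimum before exponentiating only inside the normalized
    # weights; the partition function itself uses the raw energies
    raw = priors * np.exp(-energies / kt)
    q = float(raw.sum())
    shifted = priors * np.exp(-(energies - energies.min()) / kt)
    return shifted / shifted.sum(), q


def place_rotamers(site, model: StructureModel, library: RotamerLibrary, *,
                   scale: float = 1.0,
                   temperature_factor: float = 1.0,
                   hard_max_clashes: int = DEFAULT_MAX_CLASHES,
                   hard_scale: float = DEFAULT_SCALE,
                   topo: LabelTopology | None = None,
                   environment: ClashEngine | None = None,
                   include_solvent: bool = False) -> LabelEnsemble:
    """Rotamer-approach prediction: build every library entry, Boltzmann-reweight.

    Each entry i receives unnormalized weight prior_i·exp(−E_i/kT) with E_i
    the quartic soft-overlap energy evaluated at ``scale`` (full vdW radii by
    default).  Entries with more than ``hard_max_clashes`` hard clashes
    (counted at ``hard_scale``) are discarded before normalization; the
    partition function is the sum of unnormalized weights over survivors.
    """
    topo = topo or default_topology()
    backbone = _site_backbone(model, site)
    engine = environment or site_environment(model, site, include_solvent)
    radii = _label_radii(topo)
    kt = temperature_factor  # kT_eff in arbitrary energy units

    coords = build_label_batch(backbone, library.chis, topo)
    keep, energies = [], []
    for k in range(len(library)):
        if engine.count(coords[k, 1:], radii, hard_scale) > hard_max_clashes:
            continue
        keep.append(k)
        energies.append(engine.soft_energy(coords[k, 1:], radii, scale))
    params = dict(scale=scale, temperature_factor=temperature_factor,
                  hard_max_clashes=hard_max_clashes, hard_scale=hard_scale,
                  library=library.name)
    if not keep:
        return LabelEnsemble(site, "rotamer", [], 0.0, len(library), None,
                             None, params,
                             diagnostic="every library rotamer clashes; site "
                                        "appears inaccessible to this library")
    weights, q = boltzmann_occupancies(library.priors[keep], np.array(energies), kt)
    conformers = [build_label(backbone, library.chis[k], topo, weight=w)
                  for k, w in zip(keep, weights)]
    return LabelEnsemble(site, "rotamer", conformers, partition_function=q,
                         n_trials=len(library), params=params)


def write_ensemble_pdb(ensemble: LabelEnsemble, path) -> None:
    """Write an ensemble as a multi-MODEL PDB (one MODEL per conformer).

    Each model holds one R1A residue; the conformer's occupancy is stored in
    the B-factor column of the nitroxide N1/O1 atoms so occupancies survive
    the round trip through the file.
    """
    if not ensemble.conformers:
        raise ValueError("cannot write an empty ensemble")
    cid, resnum = ensemble.site
    pdb_cid = cid[0] if cid else "A"
    lines = []
    for m, conf in enumerate(ensemble.conformers, start=1):
        lines.append(f"MODEL     {m:4d}")
        serial = 1
        for nm, pos in conf.atoms.items():
            el = _element_of(nm)
            bfac = conf.weight * 100.0 if nm in ("N1", "O1") else 0.0
            name = f" {nm:<3s}" if len(el) == 1 and len(nm) < 4 else f"{nm:<4s}"
            x, y, z = pos
            lines.append(
                f"HETATM{serial:5d} {name} R1A {pdb_cid}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{bfac:6.2f}"
                f"          {el:>2s}")
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Library file format: one row per rotamer, 'chi1 chi2 chi3 chi4 chi5 weight'

def save_library(library: RotamerLibrary, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# rotamer library: {library.name}\n")
        fh.write(f"# chi5_convention: {library.chi5_convention}\n")
        fh.write("# chi1 chi2 chi3 chi4 chi5 weight\n")
        for chi, w in zip(library.chis, library.priors):
            fh.write(" ".join(f"{x:12.6f}" for x in chi) + f" {w:.9e}\n")


def load_library(path, name: str | None = None) -> RotamerLibrary:
    chis, priors = [], []
    convention = "C4"
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                if "chi5_convention:" in line:
                    convention = line.split("chi5_convention:")[1].strip()
                continue
            if not line:
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 numeric fields, got {len(parts)}")
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric field") from exc
            chis.append(vals[:5])
            priors.append(vals[5])
    if not chis:
        raise ValueError(f"{path}: empty rotamer library")
    return RotamerLibrary(np.array(chis), np.array(priors),
                          name=name or str(path), chi5_convention=convention)
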