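# Methods

## The R1 side-chain model

The label is the side chain formed by reacting MTSSL with a cysteine: a
CB–SG–SD–CE disulfide linker carrying a five-membered nitroxide ring. It is
modelled as a rigid-geometry / flexible-dihedral object: all bond lengths
and bond angles are frozen template values and only the five linker
dihedrals χ1–χ5 vary, matching the treatment used by both prediction
paradigms the package implements. The template
(`src/spinlabel/data/r1_topology.txt`) lists, per atom, a parent triplet and
(bond, angle, dihedral) internal coordinates; conformers are built by
NERF-style sequential placement, which makes construction and measurement
exact mutual inverses (round-trip error < 1e-6°, enforced by tests).

Heavy-atom naming follows the 13-atom convention commonly used for
deposited R1 residues (CB, SG, SD, CE, ring C3/C4/C5/C9 + N1/O1, methyls
C6/C7/C8). With this atom set the ring carries three methyl carbons rather
than the four of the real 2,2,5,5-tetramethyl ring; for clash and surface
purposes the difference is one carbon sphere and does not change any
qualitative behaviour. The ring is built planar with torsions of 0/180°
about the ring bonds; the closing C9–C3 bond is implied by geometry rather
than placed, so only template-defined internal coordinates are guaranteed
exactly.

χ definitions: χ1 = N-CA-CB-SG, χ2 = CA-CB-SG-SD, χ3 = CB-SG-SD-CE
(disulfide), χ4 = SG-SD-CE-C3, χ5 = SD-CE-C3-C4. The fourth atom of χ5 is
convention-dependent across programs and libraries, so it is configurable
(`LabelTopology.with_chi5_atom`) and every library/report carries a
convention tag; comparing χ sets under mismatched tags raises an error.
Angle arithmetic is circular throughout: differences are minimal signed
circular differences in (−180°, 180°], and dihedrals follow the IUPAC sign
convention (cis = 0). A torsion angle is invariant under reversal of the
four-point chain and negates under mirror reflection; both properties are
regression-tested.

## Ensemble prediction

**Accessible volume.** χ tuples are drawn uniformly on (−180, 180]⁵ from a
single seeded generator owned by the call; a conformer is accepted iff its
hard clash count does not exceed `max_clashes`. A clash is a label/
environment heavy-atom pair closer than `scale · (r_i + r_j)` with Bondi-
style radii (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, Cu 1.40 Å). Defaults —
`scale = 0.75`, `max_clashes = 5`, `n_conformers = 200`,
`max_trials = 50 000` — mirror published accessible-volume practice; all are
configurable. Accepted conformers carry equal weights; the acceptance
fraction is recorded as a measure of steric freedom at the site.

**Rotamer approach.** Every library entry is built at the site. Entries
whose hard clash count (at `hard_scale = 0.75`) exceeds `hard_max_clashes`
are discarded; survivors get unnormalized weights
`w_i = prior_i · exp(−E_i / kT_eff)` with the soft quartic overlap energy
`E = Σ_pairs max(0, scale·(r_i + r_j) − d)⁴` evaluated at full radii
(`scale = 1.0`). The quartic form is a pragmatic choice — smooth, monotone
in overlap, cheap; no particular functional form is canonical. Energies are
in units of `kT_eff` (default 1): occupancies are relative, so an absolute
thermal calibration is out of scope. The partition function is the sum of
unnormalized weights over survivors and shrinks monotonically as environment
atoms are added; with no environment the prediction reproduces the library
priors exactly and Q = 1 (the free-label limit).

Clash environments exclude the labelled residue itself, and the clash test
covers only the mobile label atoms (SG onward): N/CA/CB are shared with the
host residue, and including them would count covalent 1-2/1-3 neighbour
pairs as clashes at scales ≥ 0.9. Waters and cryoprotectant molecules are
excluded from the environment by default (the convention of the established
labelling programs), toggleable with `include_solvent=True`.

## Comparison metrics

The spin center is either the nitroxide N1 atom or the N1–O1 midpoint; the
N1 rule is the default wherever a prediction is compared with an observed
(crystallographic) label, because deposited coordinates give N1 directly,
while midpoint–midpoint comparisons are fine between predictions. Reports
record the rule used. Ensemble positions are occupancy-weighted means;
inter-ensemble distances come both as the distance between mean positions
and as the weighted distribution of all pairwise spin-center distances
(weights w_i·w_j), the analogue of a PELDOR distance distribution. The
angular deviation between experimental and predicted site-pair distance
vectors exposes error compensation: two wrong ensembles can still produce a
nearly correct scalar distance.

Surface areas use Shrake–Rupley quadrature with a deterministic
golden-spiral point set (default 960 points/atom, probe 1.4 Å), so areas
are exactly reproducible; quadrature error is < 2% against analytic one-
and two-sphere solutions and halving the point count changes a 50-atom
total by < 1%. Buried area is defined PISA-style: the area the atom set has
in its own chain's context alone minus the area retained in the full
context. Contacts are distance-based, Ligplot-like: a polar contact is an
N/O–N/O pair under 3.5 Å, a vdW contact any heavy-atom pair under
r_i + r_j + 0.5 Å; peptide-bond partners are excluded as covalent.

## Structure model and crystal mathematics

PDB I/O is strict fixed-column: malformed ATOM/HETATM records raise errors
naming the line; among altlocs the highest-occupancy conformer wins with
ties going to 'A' (single-conformer analysis). Hydrogens are carried but
ignored by clash/SASA work. The triclinic cell volume uses
V = abc·√(1 − cos²α − cos²β − cos²γ + 2cosαcosβcosγ), and solvent content
follows the Matthews relation 100·(1 − 1.23/V_M). Packing expansion covers
space group P1 — identity plus integer lattice translations, the only case
the benchmark needs — with a conservative fractional search range derived
from interplanar spacings; images are selected by a nearest-atom cutoff to
the center chain, which makes the output monotone in the cutoff. General
fractional operators stored on a model are applied if present, but no
space-group library is bundled.

The benchmark pipeline strips solvent, expands packing around every site's
chain, flags sites whose 10 Å environment sphere would include crystal
neighbours missing from the selection (such sites' predictions should not
be trusted), strips all configured sites to backbone + CB, predicts by both
methods, and tabulates per-site χ statistics and per-pair distance
comparisons. Sub-seeds are derived per site from the run seed via
`numpy.random.SeedSequence`, making reports byte-identical under a fixed
config.

## Synthetic fixtures

`make_helix` builds an ideal poly-alanine fragment from Engh–Huber-style
internal coordinates at fixed (φ, ψ), default (−57°, −47°); the geometry is
exactly repetitive (equal Cα–Cα steps, i→i+4 O…N distances ≈ 3.1 Å in the
hydrogen-bonding band). The open fixture plants an R1 at an interior
residue with a default χ of (180, −60, −90, 180, 10)° — canonical wells,
chosen clash-free against the helix at scale 0.9, a construction guarantee
checked at build time. The tight fixture adds a second helix placed by a
deterministic grid search (no RNG): over four occluder orientations and a
13-direction fan around the site, the occluder slides outward from the CB
anchor until it clears both the planted label (by `occluder_gap`, default
4.0 Å ≥ the 3.5 Å no-clash bound) and the host helix; among placements that
block the χ2+120° probe conformation — the canonical environment-enforced
failure mode — the one blocking the most of 29 probe conformations (single
±60/±120/180° shifts plus χ1/χ2 double shifts) wins. The resulting site
roughly halves the accessible-volume acceptance fraction and the
retained-rotamer count relative to the open site, robustly across seeds.

Synthetic rotamer libraries draw χ1–χ3 from von Mises mixtures at the
canonical staggered/disulfide minima ({−60, 60, 180}° and {−90, 90}° for
χ3) with κ = 16 (≈ 14° wells), and χ4/χ5 from broader mixtures (κ/2 at
{−75, 75, 180}°, κ/4 at {−90, 90}°), echoing the soft outer dihedrals of
MD-derived MTSSL libraries; priors are Dirichlet-uniform. The default 216
entries match the canonical 3³ well structure of published libraries.
Generation parameters are recorded in the library metadata.

What the fixtures do not emulate: a real protein fold (β-barrel, copper
site), real crystal-form packing beyond a single planted contact, ordered
solvent (the hydrogen-bonded waters that stabilize real tight-site
conformations), and label-induced backbone adjustment. Passing tests
therefore demonstrate the correctness and the qualitative open-vs-tight
phenomenology of the algorithms, not quantitative agreement with any
particular crystal structure; the deposited-structure checks in
`tests/test_acceptance.py` cover the latter when the PDB files are
available locally.

## Numerical choices and limitations

* Superposition enforces a proper rotation (determinant +1) via SVD sign
  correction; degenerate inputs (< 3 points, collinear sets) are rejected.
* Dihedrals are undefined for collinear triples and rejected with an error
  rather than returned as NaN.
* Ensemble weights always sum to 1 (± 1e-9, enforced by the container);
  the zero-temperature limit of the Boltzmann weighting concentrates on the
  minimum-energy entry.
* Benchmark problem sizes (200 accessible-volume conformers, 216-entry
  libraries, 10 seeds, 960 SASA points) keep a full synthetic benchmark
  under ten seconds while leaving sampling noise far below the effect sizes
  being asserted.
* The PDB writer remaps multi-character packing-image chain identifiers to
  single characters deterministically; round trips through files therefore
  preserve geometry but not necessarily image chain naming.
* Clash-based occupancies ignore attractive interactions entirely; a
  conformation stabilized by a hydrogen bond (e.g. to an ordered water) is
  invisible to both paradigms. This is a deliberate reproduction of the
  simplification the benchmark interrogates, not an oversight.
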