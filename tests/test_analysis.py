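"""Spin centers, distances, SASA, chi deviations and contacts."""

import math

import numpy as np
import pytest

from spinlabel.analysis import (bounding_box_volume, buried_sasa, chi_deviation,
                                contacts, ensemble_distance, mean_spin_position,
                                sasa, spin_center, vector_angle_deviation)
from spinlabel.geometry import Conformer, build_label, circular_difference
from spinlabel.prediction import LabelEnsemble, RotamerLibrary
from spinlabel.structure import Atom, Chain, Residue, StructureModel


def _conf(n1, o1=None, weight=1.0, chi=(0, 0, 0, 0, 0)):
    atoms = {"N1": np.asarray(n1, float)}
    if o1 is not None:
        atoms["O1"] = np.asarray(o1, float)
    return Conformer(np.asarray(chi, float), atoms, weight)


def _ens(confs, site=("A", 1), method="accessible_volume"):
    return LabelEnsemble(site, method, confs, float(len(confs)))


class TestSpinCenter:
    def test_n1_rule(self):
        assert np.allclose(spin_center(_conf((1, 1, 1)), "N1"), (1, 1, 1))

    def test_midpoint_rule(self):
        c = _conf((0, 0, 0), (0, 0, 2))
        assert np.allclose(spin_center(c, "NO_midpoint"), (0, 0, 1))

    def test_rules_differ_by_half_bond(self, backbone, rng):
        for _ in range(10):
            conf = build_label(backbone, rng.uniform(-180, 180, 5))
            d_rules = np.linalg.norm(spin_center(conf, "N1")
                                     - spin_center(conf, "NO_midpoint"))
            half_bond = 0.5 * np.linalg.norm(conf.atoms["N1"] - conf.atoms["O1"])
            assert d_rules == pytest.approx(half_bond, abs=1e-12)

    def test_missing_atoms(self):
        with pytest.raises(ValueError, match="N1"):
            spin_center(Conformer(np.zeros(5), {"O1": np.zeros(3)}))
        with pytest.raises(ValueError, match="O1"):
            spin_center(_conf((0, 0, 0)), "NO_midpoint")

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            spin_center(_conf((0, 0, 0)), "midpoint")


class TestMeanSpinPosition:
    def test_singleton(self):
        e = _ens([_conf((3, 2, 1))])
        assert np.allclose(mean_spin_position(e), (3, 2, 1))

    def test_degenerate_weights(self):
        e = LabelEnsemble(("A", 1), "rotamer",
                          [_conf((1, 0, 0), weight=1.0), _conf((9, 9, 9), weight=0.0)],
                          1.0)
        assert np.allclose(mean_spin_position(e), (1, 0, 0))

    def test_matches_explicit_loop(self, rng):
        pts = rng.normal(size=(20, 3))
        w = rng.dirichlet(np.ones(20))
        e = LabelEnsemble(("A", 1), "rotamer",
                          [_conf(p, weight=wi) for p, wi in zip(pts, w)], 1.0)
        expect = np.zeros(3)
        for p, wi in zip(pts, w):
            expect += wi * p
        assert np.allclose(mean_spin_position(e), expect, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_spin_position(_ens([]))


class TestEnsembleDistance:
    def test_singletons(self):
        a, b = _ens([_conf((0, 0, 0))]), _ens([_conf((20, 0, 0))])
        mean_d, (d, w) = ensemble_distance(a, b)
        assert mean_d == pytest.approx(20.0)
        assert d.tolist() == [20.0] and w.tolist() == [1.0]

    def test_translation_equivariance(self, rng):
        pts_a = rng.normal(size=(6, 3))
        pts_b = rng.normal(size=(6, 3)) + np.array([15.0, 0, 0])
        a = _ens([_conf(p, weight=1 / 6) for p in pts_a])
        b = _ens([_conf(p, weight=1 / 6) for p in pts_b])
        m0, _ = ensemble_distance(a, b)
        axis = mean_spin_position(b) - mean_spin_position(a)
        axis /= np.linalg.norm(axis)
        b2 = _ens([_conf(p + 5.0 * axis, weight=1 / 6) for p in pts_b])
        m1, _ = ensemble_distance(a, b2)
        assert m1 == pytest.approx(m0 + 5.0, abs=1e-9)

    def test_distribution_matches_double_loop(self, rng):
        pa, pb = rng.normal(size=(5, 3)), rng.normal(size=(7, 3)) + 8.0
        wa, wb = rng.dirichlet(np.ones(5)), rng.dirichlet(np.ones(7))
        a = _ens([_conf(p, weight=w) for p, w in zip(pa, wa)])
        b = _ens([_conf(p, weight=w) for p, w in zip(pb, wb)])
        _, (d, w) = ensemble_distance(a, b)
        mean = float(np.sum(d * w))
        var = float(np.sum(w * (d - mean) ** 2))
        bm, bv = 0.0, 0.0
        for i in range(5):
            for j in range(7):
                bm += wa[i] * wb[j] * np.linalg.norm(pa[i] - pb[j])
        for i in range(5):
            for j in range(7):
                bv += wa[i] * wb[j] * (np.linalg.norm(pa[i] - pb[j]) - bm) ** 2
        assert mean == pytest.approx(bm, abs=1e-12)
        assert var == pytest.approx(bv, abs=1e-12)

    def test_mean_between_extremes(self, rng):
        pa, pb = rng.normal(size=(4, 3)), rng.normal(size=(4, 3)) + 6.0
        a = _ens([_conf(p, weight=0.25) for p in pa])
        b = _ens([_conf(p, weight=0.25) for p in pb])
        mean_d, (d, _) = ensemble_distance(a, b)
        assert d.min() - 1e-9 <= mean_d <= d.max() + 1e-9


class TestVectorAngle:
    def test_identical(self):
        assert vector_angle_deviation(((0, 0, 0), (1, 1, 0)),
                                      ((5, 5, 5), (6, 6, 5))) == pytest.approx(0.0, abs=1e-5)

    def test_antiparallel(self):
        assert vector_angle_deviation(((0, 0, 0), (1, 0, 0)),
                                      ((0, 0, 0), (-2, 0, 0))) == pytest.approx(180.0)

    def test_matches_arccos_oracle(self, rng):
        for _ in range(50):
            a, b = rng.normal(size=(2, 3))
            got = vector_angle_deviation(((0, 0, 0), a), ((0, 0, 0), b))
            expect = math.degrees(math.acos(np.clip(
                np.dot(a, b) / np.linalg.norm(a) / np.linalg.norm(b), -1, 1)))
            assert got == pytest.approx(expect, abs=1e-9)
            assert 0.0 <= got <= 180.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            vector_angle_deviation(((0, 0, 0), (0, 0, 0)), ((0, 0, 0), (1, 0, 0)))


def _atom(name, pos, element=None, r=None):
    radii = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
    el = element or name[0]
    return Atom(name, el, np.asarray(pos, float), vdw_radius=r or radii.get(el, 1.70))


class TestSasa:
    def test_lone_atom_analytic_sphere(self):
        a = _atom("C", (0, 0, 0))
        rep = sasa([a], [], probe=1.4, n_points=960)
        expect = 4 * math.pi * 3.1 ** 2
        assert rep.total_asa == pytest.approx(expect, rel=1e-9)
        assert expect == pytest.approx(120.76, abs=0.01)

    def test_distant_pair_full_spheres_zero_buried(self):
        a, b = _atom("C", (0, 0, 0)), _atom("C", (100, 0, 0))
        rep = buried_sasa([a], [a], [a, b])
        assert rep.total_asa == pytest.approx(4 * math.pi * 3.1 ** 2, rel=1e-9)
        assert rep.buried_asa == pytest.approx(0.0, abs=1e-9)

    def test_two_overlapping_spheres_match_cap_formula(self):
        """Numeric area vs the closed-form spherical-cap solution."""
        d = 3.0
        a, b = _atom("C", (0, 0, 0)), _atom("C", (d, 0, 0))
        rep = sasa([a, b], [], probe=1.4, n_points=4000)
        R = 3.1
        x = d / 2.0                      # equal radii: plane bisects
        cap = 2 * math.pi * R * (R - x)
        expect = 2 * (4 * math.pi * R * R - cap)
        assert rep.total_asa == pytest.approx(expect, rel=0.02)

    def test_convergence_under_refinement(self, helix):
        atoms = [a for r in helix.chain("A").residues[:10] for a in r.atoms]
        coarse = sasa(atoms, atoms, n_points=480).total_asa
        fine = sasa(atoms, atoms, n_points=960).total_asa
        assert abs(fine - coarse) / fine < 0.01

    def test_per_atom_sums_to_total(self, helix):
        atoms = [a for r in helix.chain("A").residues[:4] for a in r.atoms]
        rep = sasa(atoms, atoms)
        assert sum(rep.per_atom.values()) == pytest.approx(rep.total_asa, abs=0.1)

    def test_buried_bounded_by_isolated_area(self, open_site):
        model = open_site.model
        chain = model.chain("A")
        res = chain.residue(open_site.site[1])
        side = [a for a in res.atoms if a.name not in ("N", "CA", "C", "O")]
        rep = buried_sasa(side, chain, model)
        isolated = sasa(side, []).total_asa
        assert 0.0 <= rep.buried_asa <= isolated

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            sasa([], [])


class TestChiDeviation:
    def test_exact_entry_zero(self, library):
        idx, deltas, dmax = chi_deviation(library.chis[17], library)
        assert idx == 17
        assert np.allclose(deltas, 0.0)
        assert dmax == 0.0

    def test_wraparound(self):
        lib = RotamerLibrary(np.array([[-179.0, 0, 0, 0, 0]]), np.array([1.0]))
        _, deltas, dmax = chi_deviation(np.array([179.0, 0, 0, 0, 0]), lib)
        assert dmax == pytest.approx(2.0)
        assert abs(deltas[0]) == pytest.approx(2.0)

    def test_matches_exhaustive_scan(self, rng):
        chis = rng.uniform(-180, 180, size=(50, 5))
        lib = RotamerLibrary(chis, np.ones(50))
        for _ in range(20):
            obs = rng.uniform(-180, 180, 5)
            idx, _, dmax = chi_deviation(obs, lib)
            brute = [np.abs(circular_difference(obs, e)).max() for e in chis]
            assert idx == int(np.argmin(brute))
            assert dmax == pytest.approx(min(brute))

    def test_library_permutation_invariant(self, rng):
        chis = rng.uniform(-180, 180, size=(30, 5))
        lib = RotamerLibrary(chis, np.ones(30))
        perm = rng.permutation(30)
        lib2 = RotamerLibrary(chis[perm], np.ones(30))
        obs = rng.uniform(-180, 180, 5)
        assert chi_deviation(obs, lib)[2] == pytest.approx(chi_deviation(obs, lib2)[2])

    def test_convention_mismatch(self, library):
        with pytest.raises(ValueError, match="convention"):
            chi_deviation(np.zeros(5), library, convention="C9")


class TestContacts:
    def test_isolated_residue_empty(self):
        res = Residue(1, "ALA", [_atom("CB", (0, 0, 0))])
        model = StructureModel([Chain("A", [res])])
        assert contacts(res, model, chain_id="A") == []

    def test_nitroxide_water_hydrogen_bond(self):
        o1 = _atom("O1", (0, 0, 0), element="O")
        res = Residue(21, "R1A", [o1], het=True)
        wat = Residue(301, "HOH", [_atom("O", (2.8, 0, 0), element="O")], het=True)
        model = StructureModel([Chain("A", [res]), Chain("W", [wat])])
        got = contacts(res, model, chain_id="A", polar_cutoff=3.5)
        assert len(got) == 1
        assert got[0].kind == "polar"
        assert got[0].distance == pytest.approx(2.8)
        assert not got[0].same_chain

    def test_matches_brute_force_classification(self, rng):
        own = Residue(1, "R1A", [_atom(f"C{i}", p) for i, p in
                                 enumerate(rng.normal(scale=2, size=(4, 3)))])
        partner_atoms = [_atom("O" if i % 2 else "C", p, element="O" if i % 2 else "C")
                         for i, p in enumerate(rng.normal(scale=3, size=(12, 3)))]
        partner = Residue(2, "XXX", partner_atoms)
        model = StructureModel([Chain("A", [own]), Chain("B", [partner])])
        got = contacts(own, model, chain_id="A", vdw_slack=0.5, polar_cutoff=3.5)
        expect = 0
        for a in own.atoms:
            for b in partner_atoms:
                d = np.linalg.norm(a.pos - b.pos)
                if a.element in "NO" and b.element in "NO" and d < 3.5:
                    expect += 1
                elif d < a.vdw_radius + b.vdw_radius + 0.5:
                    expect += 1
        assert len(got) == expect


def test_bounding_box_volume_unit_cube():
    pts = np.array([[0, 0, 0], [1, 1, 1], [0.5, 0.2, 0.9]])
    assert bounding_box_volume(pts) == pytest.approx(1.0)
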