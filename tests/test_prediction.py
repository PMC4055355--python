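"""Clash detection, accessible-volume sampling and rotamer placement."""

import numpy as np
import pytest

from spinlabel.geometry import build_label, circular_difference
from spinlabel.prediction import (ClashEngine, RotamerLibrary,
                                  boltzmann_occupancies, clash_count,
                                  load_library, place_rotamers,
                                  sample_accessible_volume, save_library,
                                  site_environment, write_ensemble_pdb)
from spinlabel.structure import Atom, Chain, Residue, StructureModel, read_models

VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


def brute_force_clashes(conformer, env_atoms, scale):
    """All-pairs reference clash counter, independent of the kd-tree engine."""
    from spinlabel.geometry import R1_ELEMENTS
    n = 0
    for nm in conformer.mobile_atom_names:
        p = conformer.atoms[nm]
        r1 = VDW[R1_ELEMENTS[nm]]
        for a in env_atoms:
            if np.linalg.norm(p - a.pos) < scale * (r1 + a.vdw_radius):
                n += 1
    return n


def _bare_site_model(backbone):
    res = Residue(1, "ALA", [Atom(nm, nm[0], backbone[nm]) for nm in backbone])
    return StructureModel([Chain("A", [res])])


def _env_atom(pos, element="C"):
    return Atom("X", element, np.asarray(pos, float),
                vdw_radius=VDW.get(element, 1.70))


class TestClashCount:
    def test_far_atom_no_clash(self, backbone):
        conf = build_label(backbone, (0, 0, 0, 0, 0))
        far = conf.atoms["N1"] + np.array([50.0, 0, 0])
        assert clash_count(conf, [_env_atom(far)], 1.0) == 0

    def test_coincident_atom_clashes(self, backbone):
        conf = build_label(backbone, (0, 0, 0, 0, 0))
        assert clash_count(conf, [_env_atom(conf.atoms["N1"])], 1.0) >= 1

    def test_matches_all_pairs_loop(self, backbone, rng):
        conf = build_label(backbone, (-60, 180, 90, 100, 90))
        center = conf.coords(conf.mobile_atom_names).mean(axis=0)
        env = [_env_atom(center + rng.normal(scale=4.0, size=3))
               for _ in range(50)]
        for scale in (0.6, 0.75, 0.9, 1.0):
            assert clash_count(conf, env, scale) == brute_force_clashes(conf, env, scale)

    def test_scale_bounds(self, backbone):
        conf = build_label(backbone, (0, 0, 0, 0, 0))
        with pytest.raises(ValueError):
            clash_count(conf, [], 0.0)
        with pytest.raises(ValueError):
            clash_count(conf, [], 2.0)


class TestAccessibleVolume:
    def test_unconstrained_site_accepts_everything(self, backbone):
        model = _bare_site_model(backbone)
        ens = sample_accessible_volume(("A", 1), model, n_conformers=40,
                                       max_trials=500, seed=1)
        assert ens.acceptance_fraction == 1.0
        assert len(ens) == 40
        assert ens.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_under_seed(self, open_site):
        kw = dict(n_conformers=30, max_trials=500, seed=7)
        a = sample_accessible_volume(open_site.site, open_site.model, **kw)
        b = sample_accessible_volume(open_site.site, open_site.model, **kw)
        assert np.array_equal(a.chi_matrix(), b.chi_matrix())
        assert a.n_trials == b.n_trials

    def test_tight_site_harder_than_open(self, open_site, tight_site):
        kw = dict(n_conformers=100, max_trials=600, seed=3)
        open_acc = sample_accessible_volume(open_site.site, open_site.model, **kw)
        tight_acc = sample_accessible_volume(tight_site.site, tight_site.model, **kw)
        assert tight_acc.acceptance_fraction < open_acc.acceptance_fraction

    def test_every_acceptance_respects_criterion(self, tight_site):
        ens = sample_accessible_volume(tight_site.site, tight_site.model,
                                       n_conformers=25, max_trials=400, seed=5)
        env = [a for a in site_environment(tight_site.model, tight_site.site).atoms]
        scale = ens.params["scale"]
        for conf in ens.conformers:
            assert brute_force_clashes(conf, env, scale) <= ens.params["max_clashes"]

    def test_acceptance_monotone_in_scale_and_clash_budget(self, tight_site):
        # full fixed trial budget so the same chi draws are classified each time
        def run(scale, max_clashes):
            return sample_accessible_volume(
                tight_site.site, tight_site.model, n_conformers=10_000,
                max_trials=400, scale=scale, max_clashes=max_clashes,
                seed=11).acceptance_fraction
        accs = [run(s, 5) for s in (0.6, 0.75, 0.9)]
        assert accs[0] >= accs[1] >= accs[2]
        accs = [run(0.75, m) for m in (0, 5, 15)]
        assert accs[0] <= accs[1] <= accs[2]

    def test_fully_buried_site_diagnostic(self, backbone):
        model = _bare_site_model(backbone)
        cage = [_env_atom(backbone["CB"] + 2.0 * v) for v in
                [np.array(x, float) for x in
                 [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]]]
        for a in cage:
            model.chains[0].residues.append(
                Residue(100 + len(model.chains[0].residues), "XXX", [a], het=True))
        ens = sample_accessible_volume(("A", 1), model, n_conformers=5,
                                       max_trials=50, scale=1.2, max_clashes=0,
                                       seed=1)
        assert len(ens) == 0
        assert "buried" in ens.diagnostic


class TestRotamerPlacement:
    def test_free_label_limit(self, backbone, library):
        """With no environment the prediction reproduces the library."""
        model = _bare_site_model(backbone)
        ens = place_rotamers(("A", 1), model, library)
        assert len(ens) == len(library)
        assert np.allclose(ens.weights, library.priors, atol=1e-12)
        assert ens.partition_function == pytest.approx(1.0)

    def test_boltzmann_two_entry_ratio(self):
        w, q = boltzmann_occupancies(np.array([0.5, 0.5]),
                                     np.array([0.0, np.log(2.0)]), kt=1.0)
        assert np.allclose(w, [2.0 / 3.0, 1.0 / 3.0])
        assert q == pytest.approx(0.75)

    def test_boltzmann_zero_temperature_argmax(self, rng):
        priors = rng.dirichlet(np.ones(20))
        energies = rng.uniform(0, 5, 20)
        w, _ = boltzmann_occupancies(priors, energies, kt=1e-12)
        assert np.argmax(w) == np.argmin(energies)
        assert w[np.argmin(energies)] == pytest.approx(1.0, abs=1e-6)

    def test_engineered_overlap_gives_analytic_ratio(self, backbone):
        """A single environment atom overlapping one rotamer's nitroxide by
        (ln 2)^(1/4) A halves that rotamer's Boltzmann factor."""
        model = _bare_site_model(backbone)
        chi_a = (-60.0, 180.0, 90.0, 100.0, 90.0)
        chi_b = (60.0, 180.0, 90.0, 100.0, 90.0)
        lib = RotamerLibrary(np.array([chi_a, chi_b]), np.array([0.5, 0.5]))
        conf_b = build_label(backbone, chi_b)
        o1 = conf_b.atoms["O1"]
        away = o1 - conf_b.atoms["N1"]
        away /= np.linalg.norm(away)
        overlap = np.log(2.0) ** 0.25
        contact = 1.52 + 1.52  # O...O vdW sum
        probe = Residue(99, "HOH", [Atom("O", "O", o1 + (contact - overlap) * away,
                                         vdw_radius=1.52)], het=True)
        model.chains[0].residues.append(probe)
        ens = place_rotamers(("A", 1), model, lib, scale=1.0,
                             include_solvent=True)
        # the probe must touch only rotamer B's O1
        conf_a = build_label(backbone, chi_a)
        others = [np.linalg.norm(p - probe.atoms[0].pos)
                  for nm, p in list(conf_a.atoms.items()) + list(conf_b.atoms.items())
                  if not (nm == "O1" and np.allclose(p, o1))]
        assert min(others) > 1.0 * (1.52 + 1.80)  # beyond any vdW sum
        assert np.allclose(ens.weights, [2.0 / 3.0, 1.0 / 3.0], atol=1e-9)

    def test_hard_filter_discards_clashing_rotamers(self, tight_site, library):
        ens = place_rotamers(tight_site.site, tight_site.model, library)
        assert 0 < len(ens) < len(library)
        assert ens.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_partition_function_shrinks_with_environment(self, backbone, library):
        model = _bare_site_model(backbone)
        q_free = place_rotamers(("A", 1), model, library).partition_function
        conf = build_label(backbone, (-60, 180, 90, 100, 90))
        crowd = Residue(50, "XXX", [
            _env_atom(conf.atoms["N1"] + np.array([1.0, 0, 0])),
            _env_atom(conf.atoms["CE"] + np.array([0, 1.0, 0]))], het=True)
        model.chains[0].residues.append(crowd)
        q_crowded = place_rotamers(("A", 1), model, library).partition_function
        assert q_crowded <= q_free

    def test_all_discarded_diagnostic(self, backbone, library):
        model = _bare_site_model(backbone)
        # bury the whole chi space in carbon atoms around CB
        grid = np.mgrid[-6:7:3.0, -6:7:3.0, -6:7:3.0].reshape(3, -1).T
        cage = Residue(77, "XXX", [_env_atom(backbone["CB"] + g) for g in grid],
                       het=True)
        model.chains[0].residues.append(cage)
        ens = place_rotamers(("A", 1), model, library, hard_max_clashes=0,
                             hard_scale=1.2)
        assert len(ens) == 0
        assert ens.diagnostic


class TestLibraryIO:
    def test_round_trip(self, library, tmp_path):
        p = tmp_path / "lib.txt"
        save_library(library, p)
        again = load_library(p)
        assert np.allclose(again.chis, library.chis, atol=1e-6)
        assert np.allclose(again.priors, library.priors, atol=1e-9)
        assert again.chi5_convention == library.chi5_convention

    def test_weights_normalized_on_load(self, tmp_path):
        p = tmp_path / "lib.txt"
        p.write_text("0 0 0 0 0 2\n10 10 10 10 10 2\n")
        lib = load_library(p)
        assert np.allclose(lib.priors, [0.5, 0.5])

    def test_bad_field_count_names_line(self, tmp_path):
        p = tmp_path / "lib.txt"
        p.write_text("0 0 0 0 0 1\n0 0 0 0 1\n")
        with pytest.raises(ValueError, match="line 2"):
            load_library(p)

    def test_negative_prior_rejected(self):
        with pytest.raises(ValueError):
            RotamerLibrary(np.zeros((1, 5)), np.array([-1.0]))


class TestEnsembleIO:
    def test_multi_model_round_trip(self, open_site, tmp_path):
        ens = sample_accessible_volume(open_site.site, open_site.model,
                                       n_conformers=8, max_trials=200, seed=2)
        p = tmp_path / "ens.pdb"
        write_ensemble_pdb(ens, p)
        models = read_models(p)
        assert len(models) == len(ens)
        from spinlabel.geometry import measure_chi
        sampled = ens.chi_matrix()
        for m in models:
            res = m.chain("A").residue(open_site.site[1])
            chi = measure_chi(res)
            dev = np.abs(circular_difference(sampled, chi[None, :])).max(axis=1)
            assert dev.min() < 0.2  # one sampled conformer matches to PDB precision
            n1 = res.atom("N1")
            assert n1.b_factor == pytest.approx(100.0 / len(ens), abs=0.005)
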