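import numpy as np
import pytest

import fuzzycomplex as fc
from fuzzycomplex.pre import DistanceRestraint
from fuzzycomplex.structure import (
    AnnealSchedule, BACKBONE_ATOMS, ResolvedRestraints, dihedral,
    _TorsionMover,
)
from fuzzycomplex import synthetic as syn


class TestChainBuilding:
    def test_extended_chain_geometry(self):
        m = fc.build_chain("AAA")
        assert len(m) == 15  # N, CA, C, O, CB per residue
        ca = m.coords[m.atom_name == "CA"]
        for i in range(len(ca) - 1):
            assert np.linalg.norm(ca[i + 1] - ca[i]) == pytest.approx(3.80,
                                                                      abs=0.05)

    def test_helix_torsions_by_construction(self):
        m = fc.build_chain("A" * 8, conformation="helix")
        pp = fc.compute_phi_psi(m, "A")
        for r in range(2, 8):
            assert pp[r][0] == pytest.approx(-60.0, abs=1e-6)
            assert pp[r][1] == pytest.approx(-45.0, abs=1e-6)

    def test_glycine_has_no_cb(self):
        m = fc.build_chain("AGA")
        assert np.sum((m.residue_index == 2) & (m.atom_name == "CB")) == 0

    def test_d_chain_is_exact_mirror_of_l_chain(self):
        L = fc.build_chain("AEALK", conformation="helix")
        D = fc.build_chain("AEALK", chirality="D", conformation="helix")
        reflected = L.coords.copy()
        reflected[:, 0] *= -1
        assert fc.superpose_rmsd(reflected, D.coords) < 1e-9

    def test_l_chirality_matches_reference_improper(self):
        # CCD ideal L-alanine has dihedral(N, C, CA, CB) = +120 deg
        m = fc.build_chain("AAA", conformation="helix")
        idx = {n: m.atom_index("A", 2, n) for n in ("N", "C", "CA", "CB")}
        imp = dihedral(m.coords[idx["N"]], m.coords[idx["C"]],
                       m.coords[idx["CA"]], m.coords[idx["CB"]])
        assert imp == pytest.approx(120.0, abs=1.0)

    def test_unknown_residue_letter_rejected(self):
        with pytest.raises(ValueError):
            fc.build_chain("AXA")


class TestRestraintEnergy:
    def test_satisfied_restraints_zero_violation(self, toy_complex):
        e, v = fc.restraint_energy(toy_complex.model, toy_complex.restraints)
        assert max(v) == 0.0
        assert e == 0.0  # planted pose is also clash-free

    def test_flat_bottom_quadratic_outside_bounds(self):
        m = fc.build_chain("AA")
        d = float(np.linalg.norm(
            m.coords[m.atom_index("A", 1, "CA")]
            - m.coords[m.atom_index("A", 2, "CA")]))
        r = DistanceRestraint("A/1/CA", "A/2/CA", target=d - 2, lower=0.0,
                              upper=d - 2.0, kind="upper_only")
        rset = fc.RestraintSet(distance=[r])
        e, v = fc.restraint_energy(m, rset, k_steric=0.0)
        assert v[0] == pytest.approx(2.0)
        assert e == pytest.approx(4.0)  # k=1 -> (violation)^2

    def test_contradictory_pair_always_violated(self):
        m = fc.build_chain("AAAA")
        tight = DistanceRestraint("A/1/CA", "A/4/CA", 2.0, 0.0, 2.0,
                                  "upper_only")
        wide = DistanceRestraint("A/1/CA", "A/4/CA", 10.0, 10.0, np.inf,
                                 "lower_only")
        _, v = fc.restraint_energy(m, fc.RestraintSet(distance=[tight, wide]))
        assert (v[0] > 0) or (v[1] > 0)

    def test_unresolvable_selection_names_restraint(self):
        m = fc.build_chain("AA")
        bad = DistanceRestraint("A/99/CA", "A/1/CA", 5.0, 4.0, 6.0)
        with pytest.raises(KeyError, match="A/99/CA"):
            fc.restraint_energy(m, fc.RestraintSet(distance=[bad]))

    def test_sidechain_selection_maps_to_cb_with_padding(self):
        m = fc.build_chain("WW")
        r = DistanceRestraint("A/1/HE1", "A/2/CA", 5.0, 0.0, 5.0, "upper_only")
        resolved = ResolvedRestraints(m, fc.RestraintSet(distance=[r]))
        ia, ib, lower, upper, *_ = resolved.dist_entries[0]
        assert upper == pytest.approx(8.0)  # +3 Å pseudo-atom correction
        assert m.atom_name[ia] == "CB"


class TestAnnealing:
    def test_empty_restraints_return_start_unchanged(self, toy_complex):
        ens = fc.anneal(toy_complex.model, fc.RestraintSet(),
                        toy_complex.flexible,
                        AnnealSchedule(n_cycles=1, moves_per_cycle=1),
                        n_models=2, seed=0)
        for m in ens.models:
            assert np.array_equal(m.coords, toy_complex.model.coords)

    def test_same_seed_gives_identical_ensembles(self, toy_complex):
        sched = AnnealSchedule(n_cycles=5, moves_per_cycle=5, quench_moves=10)
        e1 = fc.anneal(toy_complex.model, toy_complex.restraints,
                       toy_complex.flexible, sched, n_models=2, seed=42)
        e2 = fc.anneal(toy_complex.model, toy_complex.restraints,
                       toy_complex.flexible, sched, n_models=2, seed=42)
        for a, b in zip(e1.models, e2.models):
            assert np.array_equal(a.coords, b.coords)
        assert e1.energies == e2.energies

    def test_empty_flexible_selection_rejected(self, toy_complex):
        with pytest.raises(ValueError, match="flexible"):
            fc.anneal(toy_complex.model, toy_complex.restraints, {},
                      n_models=1)

    def test_annealing_reduces_energy_from_randomized_start(self, toy_complex):
        """Energy after annealing should not exceed the randomised starting
        energy (checked over several seeds)."""
        sched = AnnealSchedule(n_cycles=30, moves_per_cycle=20,
                               quench_moves=100)
        resolved = ResolvedRestraints(toy_complex.model,
                                      toy_complex.restraints)
        mover = _TorsionMover(toy_complex.model, toy_complex.flexible)
        improved = 0
        n_seeds = 6
        for seed in range(n_seeds):
            master = np.random.default_rng(seed)
            rng = np.random.default_rng(master.integers(2**31))
            start = mover.randomize(toy_complex.model.coords.copy(), rng)
            e_start, _ = resolved.energy(start)
            ens = fc.anneal(toy_complex.model, toy_complex.restraints,
                            toy_complex.flexible, sched, n_models=1,
                            seed=seed)
            if ens.energies[0] <= e_start:
                improved += 1
        assert improved >= 0.95 * n_seeds


class TestSelection:
    def _ensemble(self, energies):
        base = fc.build_chain("AA")
        models = []
        for i in range(len(energies)):
            m = base.copy()
            m.model_id = i
            models.append(m)
        return fc.ConformationEnsemble(models, list(energies),
                                       [[] for _ in energies])

    def test_lowest_two_of_three(self):
        best = fc.select_lowest(self._ensemble([3.0, 1.0, 2.0]), 2)
        assert best.energies == [1.0, 2.0]

    def test_tie_break_by_model_id(self):
        best = fc.select_lowest(self._ensemble([1.0, 1.0, 1.0]), 2)
        assert [m.model_id for m in best.models] == [0, 1]

    def test_select_all_is_identity_up_to_order(self):
        ens = self._ensemble([2.0, 1.0])
        assert fc.select_lowest(ens, 2).energies == [1.0, 2.0]

    def test_oversized_selection_rejected(self):
        with pytest.raises(ValueError):
            fc.select_lowest(self._ensemble([1.0]), 2)


class TestSuperposition:
    def test_identical_models_zero(self):
        m = fc.build_chain("AEAL")
        assert fc.superpose_rmsd(m, m) < 1e-12

    def test_translation_removed(self):
        m = fc.build_chain("AEAL")
        shifted = m.copy()
        shifted.coords = m.coords + np.array([5.0, 5.0, 5.0])
        assert fc.superpose_rmsd(m, shifted) < 1e-9

    def test_rotation_removed(self):
        m = fc.build_chain("AEALKF")
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        rotated = m.copy()
        rotated.coords = m.coords @ R.T
        assert fc.superpose_rmsd(m, rotated) < 1e-9

    def test_two_point_closed_form(self):
        with pytest.warns(UserWarning, match="degenerate"):
            got = fc.superpose_rmsd(np.array([[0.0, 0, 0], [1.0, 0, 0]]),
                                    np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        assert got == pytest.approx(0.5)

    def test_symmetry(self):
        a = fc.build_chain("AEAL", conformation="helix")
        b = fc.build_chain("AEAL", conformation="extended")
        assert fc.superpose_rmsd(a, b) == pytest.approx(
            fc.superpose_rmsd(b, a), rel=1e-9)


class TestEnsembleStatistics:
    def test_rmsf_zero_for_identical_models(self):
        m = fc.build_chain("AEAL")
        assert np.allclose(fc.ensemble_rmsf([m, m.copy(), m.copy()]), 0.0)

    def test_rmsf_two_point_deviation(self):
        a = fc.build_chain("A" * 12)
        b = a.copy()
        b.coords = a.coords.copy()
        b.coords[10, 0] += 1.0
        rmsf = fc.ensemble_rmsf([a, b])
        # two models +-0.5 Å around the mean; superposition absorbs a little
        assert rmsf[10] == pytest.approx(0.5, rel=0.15)
        assert rmsf[10] == max(rmsf)

    def test_rmsf_invariant_under_rigid_rotation(self):
        m = fc.build_chain("AEALKF")
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        rot = m.copy()
        rot.coords = m.coords @ R.T + 3.0
        assert np.max(fc.ensemble_rmsf([m, rot])) < 1e-9

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            fc.ensemble_rmsf([fc.build_chain("AA")])


class TestClustering:
    @staticmethod
    def _group(phi, psi, n, start_id, rng):
        out = []
        for k in range(n):
            pp = [(phi + rng.uniform(-3, 3), psi + rng.uniform(-3, 3))
                  for _ in range(10)]
            m = fc.build_chain("A" * 10, conformation=pp)
            m.model_id = start_id + k
            out.append(m)
        return out

    def test_identical_models_form_one_cluster(self):
        m = fc.build_chain("AEAL")
        clusters = fc.cluster_ensemble([m, m.copy(), m.copy()])
        assert [len(c) for c in clusters] == [3]

    def test_two_distinct_conformers_two_clusters(self):
        rng = np.random.default_rng(0)
        models = (self._group(-60, -45, 3, 0, rng)
                  + self._group(-135, 135, 3, 3, rng))
        assert len(fc.cluster_ensemble(models, 2.0)) == 2

    def test_planted_5_3_1_groups_recovered(self):
        rng = np.random.default_rng(0)
        models = (self._group(-60, -45, 5, 0, rng)
                  + self._group(-135, 135, 3, 5, rng)
                  + self._group(60, 60, 1, 8, rng))
        clusters = fc.cluster_ensemble(models, 2.0)
        assert [len(c) for c in clusters] == [5, 3, 1]

    def test_members_within_cutoff_of_representative(self):
        rng = np.random.default_rng(1)
        models = (self._group(-60, -45, 4, 0, rng)
                  + self._group(-135, 135, 2, 4, rng))
        sel = models[0].select(atom_names=BACKBONE_ATOMS)
        for members in fc.cluster_ensemble(models, 2.0):
            rep = members[0]
            for j in members:
                assert fc.superpose_rmsd(models[rep], models[j], sel) <= 2.0


class TestRamachandran:
    def test_pure_alpha(self):
        pops = fc.ramachandran_populations([-60.0] * 5, [-45.0] * 5)
        assert pops["alpha"] == 1.0

    def test_pure_beta(self):
        pops = fc.ramachandran_populations([-120.0] * 5, [130.0] * 5)
        assert pops["beta"] == 1.0

    def test_uniform_angles_match_basin_areas(self, rng):
        n = 100000
        phi = rng.uniform(-180, 180, n)
        psi = rng.uniform(-180, 180, n)
        pops = fc.ramachandran_populations(phi, psi)
        for name, area in (("alpha", 70 * 60), ("beta", 90 * 90)):
            expect = area / 360.0**2
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs(pops[name] - expect) < 3 * se
        assert sum(pops.values()) == pytest.approx(1.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            fc.ramachandran_populations([], [])
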