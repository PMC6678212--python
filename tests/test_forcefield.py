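"""Force-field closed forms, gradients, and pair-list consistency."""

import numpy as np
import pytest

import coronams as cm
from coronams._geometry import random_rotation_matrix
from coronams.forcefield import (CGEnergyModel, bonded_energy,
                                 bonded_energy_forces)
from coronams.constants import AMINO_ACIDS


@pytest.fixture(scope="module")
def two_protein_model():
    p1 = cm.make_toy_protein(cm.ToyProteinSpec(10, "coil", seed=1))
    p2 = cm.make_toy_protein(cm.ToyProteinSpec(8, "helix", seed=2))
    p2 = p2.with_coords(p2.coords + np.array([10.0, 4.0, -5.0]))
    nano = cm.build_gold_np(30.0, 100, -0.5, center=(-28.0, 0.0, 0.0))
    model = CGEnergyModel([p1, p2], nano=nano)
    coords = np.concatenate([p1.coords, p2.coords])
    return model, coords


class TestClosedForms:

    def test_morse_minimum(self):
        assert cm.morse_energy(9.5, cm.MorseParams()) == pytest.approx(-0.01)

    def test_morse_decay(self):
        assert abs(cm.morse_energy(100.0, cm.MorseParams())) < 1e-8

    def test_morse_half_depth_point(self):
        params = cm.MorseParams()
        r = params.r0 + np.log(2.0) / params.alpha
        assert cm.morse_energy(r, params) == pytest.approx(-0.0075)

    def test_debye_length_at_150mM(self):
        ld = cm.debye_length(cm.ElectrostaticsParams())
        assert ld == pytest.approx(7.93, abs=0.01)

    def test_debye_length_sqrt_law(self):
        p1 = cm.ElectrostaticsParams(ionic_strength=0.150)
        p4 = cm.ElectrostaticsParams(ionic_strength=0.600)
        assert cm.debye_length(p1) == pytest.approx(
            2.0 * cm.debye_length(p4))

    def test_dh_energy_value(self):
        params = cm.ElectrostaticsParams()
        ld = params.debye_len
        e = cm.debye_huckel_energy(ld, 1, 1, params)
        assert e == pytest.approx(33.206 * np.exp(-1.0) / ld, rel=1e-9)

    def test_dh_zero_charge_and_symmetry(self):
        params = cm.ElectrostaticsParams()
        assert cm.debye_huckel_energy(5.0, 0, 1, params) == 0.0
        assert cm.debye_huckel_energy(5.0, -1, 1, params) == \
            cm.debye_huckel_energy(5.0, 1, -1, params)

    def test_gold_lj_minimum_scaled_13(self):
        table = cm.GoldInteractionTable()
        eps, sig = table.lookup("A")
        r_min = 2.0 ** (1.0 / 6.0) * sig
        assert cm.gold_lj_energy(r_min, "A", table) == \
            pytest.approx(-13.0 * eps)

    def test_gold_lj_zero_crossing(self):
        table = cm.GoldInteractionTable()
        _, sig = table.lookup("K")
        assert cm.gold_lj_energy(sig, "K", table) == pytest.approx(0.0)

    def test_gold_lj_unknown_residue(self):
        with pytest.raises(KeyError):
            cm.gold_lj_energy(5.0, "X", cm.GoldInteractionTable())

    def test_gold_table_file_roundtrip(self, tmp_path):
        table = cm.GoldInteractionTable()
        path = tmp_path / "gold.dat"
        table.to_file(path)
        back = cm.GoldInteractionTable.from_file(path)
        for aa in AMINO_ACIDS:
            assert back.epsilon[aa] == pytest.approx(table.epsilon[aa])
            assert back.sigma[aa] == pytest.approx(table.sigma[aa])


class TestBondedEnergy:

    def test_zero_at_reference(self, coil10):
        assert bonded_energy(coil10, coil10.coords) == pytest.approx(0.0,
                                                                     abs=1e-20)

    def test_single_bond_stretch_closed_form(self):
        coords = np.array([[0.0, 0, 0], [3.8, 0, 0]])
        p = cm.CGProtein(coords=coords, sequence="GA")
        params = cm.BondedParams()
        delta = 0.25
        stretched = np.array([[0.0, 0, 0], [3.8 + delta, 0, 0]])
        assert bonded_energy(p, stretched, params) == \
            pytest.approx(params.k_bond * delta ** 2)

    def test_nonnegative_under_perturbation(self, coil10, rng):
        for _ in range(10):
            pert = coil10.coords + rng.normal(0, 0.1, coil10.coords.shape)
            assert bonded_energy(coil10, pert) >= 0.0


class TestForces:

    def test_finite_difference_gradient(self, two_protein_model, rng):
        """Forces must equal −∇U to finite-difference accuracy on a random
        10+8-bead configuration."""
        model, coords = two_protein_model
        coords = coords + rng.normal(0, 0.2, coords.shape)
        _, forces, _ = model.energy_forces(coords)
        h = 1e-5
        worst = 0.0
        for i in range(len(coords)):
            for k in range(3):
                cp = coords.copy()
                cp[i, k] += h
                cmn = coords.copy()
                cmn[i, k] -= h
                fd = -(model.energy(cp) - model.energy(cmn)) / (2 * h)
                worst = max(worst, abs(fd - forces[i, k]))
        assert worst < 1e-4

    def test_newtons_third_law_isolated(self, rng):
        """Without the fixed NP, internal forces must sum to zero."""
        p1 = cm.make_toy_protein(cm.ToyProteinSpec(10, "coil", seed=1))
        p2 = cm.make_toy_protein(cm.ToyProteinSpec(12, "hairpin", seed=2))
        model = CGEnergyModel([p1, p2])
        coords = np.concatenate([p1.coords, p2.coords + 6.0])
        coords += rng.normal(0, 0.3, coords.shape)
        _, forces, _ = model.energy_forces(coords)
        assert np.abs(forces.sum(axis=0)).max() < 1e-8

    def test_rigid_motion_invariance(self, rng):
        p1 = cm.make_toy_protein(cm.ToyProteinSpec(12, "coil", seed=5))
        model = CGEnergyModel([p1])
        coords = p1.coords + rng.normal(0, 0.2, p1.coords.shape)
        e0 = model.energy(coords)
        for _ in range(3):
            rot = random_rotation_matrix(rng)
            shift = rng.normal(0, 30, 3)
            model2 = CGEnergyModel([p1])
            assert model2.energy(coords @ rot.T + shift) == \
                pytest.approx(e0, abs=1e-9)


class TestPairListConsistency:

    def test_beyond_cutoff_zero(self):
        coords = np.array([[0.0, 0, 0], [20.0, 0, 0]])
        p = cm.CGProtein(coords=coords, sequence="GG",
                         chain_bounds=[(0, 1), (1, 2)])
        model = CGEnergyModel([p])
        assert model.energy(coords, include_bonded=False) == 0.0

    def test_three_bead_vs_brute_force(self):
        coords = np.array([[0.0, 0, 0], [6.0, 0, 0], [3.0, 5.5, 0]])
        p = cm.CGProtein(coords=coords, sequence="KDA",
                         chain_bounds=[(0, 1), (1, 2), (2, 3)])
        model = CGEnergyModel([p])
        e_fast = model.energy(coords, include_bonded=False)
        e_ref = model.brute_force_nonbonded(coords)
        assert e_fast == pytest.approx(e_ref, rel=1e-10)

    def test_many_bead_system_vs_brute_force(self, rng):
        """Pair-list path equals the O(N²) oracle on a ~200-bead system
        including the NP."""
        proteins = [cm.make_toy_protein(
            cm.ToyProteinSpec(20, "coil", seed=s)) for s in range(4)]
        shifted = []
        for k, p in enumerate(proteins):
            shift = rng.normal(0, 25, 3)
            shifted.append(p.with_coords(p.coords + shift))
        nano = cm.build_gold_np(24.0, 80, -0.5)
        model = CGEnergyModel(shifted, nano=nano)
        coords = np.concatenate([p.coords for p in shifted])
        e_fast = model.energy(coords, include_bonded=False)
        e_ref = model.brute_force_nonbonded(coords)
        assert e_fast == pytest.approx(e_ref, rel=1e-10, abs=1e-12)

    def test_pair_list_valid_after_motion(self, two_protein_model, rng):
        """Skin-buffered list must stay exact while beads move."""
        model, coords = two_protein_model
        c = coords.copy()
        for _ in range(5):
            c = c + rng.normal(0, 0.5, c.shape)
            assert model.energy(c, include_bonded=False) == pytest.approx(
                model.brute_force_nonbonded(c), rel=1e-10, abs=1e-12)


class TestCutoffScheme:

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            cm.CutoffScheme(local=12.0, nonlocal_=8.5)

    def test_local_nonlocal_bookkeeping(self, two_protein_model):
        model, coords = two_protein_model
        _, _, bd = model.energy_forces(coords)
        total_split = bd["local"] + bd["nonlocal"]
        total_nb = bd["morse"] + bd["elec"] + bd["gold"]
        assert total_split == pytest.approx(total_nb, rel=1e-9, abs=1e-12)
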