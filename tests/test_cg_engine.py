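"""Coarse-grained engine: placement, thermostats, integrator physics."""

import numpy as np
import pytest

import coronams as cm
from coronams.cg import (ThermostatSpec, kinetic_temperature,
                         maxwell_boltzmann_velocities)
from coronams.constants import ENERGY_KCAL_TO_DA_A2_FS2
from coronams.exceptions import PackingError


def total_energy(system):
    ke = 0.5 * float((system.masses *
                      (system.velocities ** 2).sum(axis=1)).sum()) \
        / ENERGY_KCAL_TO_DA_A2_FS2
    return ke + system.model.energy(system.coords)


@pytest.fixture
def small_system(small_np):
    proteins = [cm.make_toy_protein(cm.ToyProteinSpec(10, "coil", seed=s))
                for s in range(3)]
    return cm.init_system(small_np, proteins, box=200.0, seed=5,
                          temperature=310.0)


class TestInitSystem:

    def test_clearances(self, small_np):
        proteins = [cm.make_toy_protein(
            cm.ToyProteinSpec(10, "coil", seed=s)) for s in range(6)]
        s = cm.init_system(small_np, proteins, box=300.0, seed=1,
                           min_clearance=10.0)
        coords = s.coords
        off = s.model.offsets
        # protein-NP clearance
        d_np = np.linalg.norm(coords - s.nano.center, axis=1) - s.nano.radius
        assert d_np.min() >= 10.0 - 1e-9
        # protein-protein clearance
        for i in range(len(proteins)):
            for j in range(i + 1, len(proteins)):
                a = coords[off[i]:off[i + 1]]
                b = coords[off[j]:off[j + 1]]
                d = np.linalg.norm(a[:, None] - b[None], axis=-1)
                assert d.min() >= 10.0 - 1e-9

    def test_same_seed_identical(self, small_np):
        proteins = [cm.make_toy_protein(cm.ToyProteinSpec(8, "helix",
                                                          seed=0))]
        s1 = cm.init_system(small_np, proteins, box=200.0, seed=3)
        s2 = cm.init_system(small_np, proteins, box=200.0, seed=3)
        np.testing.assert_array_equal(s1.coords, s2.coords)
        np.testing.assert_array_equal(s1.velocities, s2.velocities)

    def test_equipartition_large_sample(self, rng):
        masses = np.full(2000, 110.0)
        v = maxwell_boltzmann_velocities(masses, 310.0, rng)
        assert kinetic_temperature(v, masses) == pytest.approx(310.0,
                                                               rel=0.05)

    def test_packing_error_when_impossible(self, small_np):
        proteins = [cm.make_toy_protein(
            cm.ToyProteinSpec(40, "coil", seed=s)) for s in range(30)]
        with pytest.raises(PackingError):
            cm.init_system(small_np, proteins, box=61.0, seed=1,
                           max_attempts=20)

    def test_box_too_small_rejected(self, small_np):
        with pytest.raises(ValueError):
            cm.init_system(small_np, [], box=50.0, seed=0)


class TestDeterminism:

    def test_identical_trajectories(self, small_np):
        def run():
            p = [cm.make_toy_protein(cm.ToyProteinSpec(10, "coil", seed=0))]
            s = cm.init_system(small_np, p, box=200.0, seed=9)
            return cm.run_production(s, 200, dt=10.0, stride=50)
        t1, t2 = run(), run()
        np.testing.assert_array_equal(t1.coords, t2.coords)
        np.testing.assert_array_equal(t1.adsorbed_flags, t2.adsorbed_flags)


class TestIntegratorPhysics:

    def test_nve_energy_conservation(self, small_np):
        """Symplectic check: < 1e-4 relative drift over 10⁴ steps at 1 fs."""
        p = [cm.make_toy_protein(cm.ToyProteinSpec(10, "coil", seed=3))]
        s = cm.init_system(small_np, p, box=200.0, seed=5)
        e0 = total_energy(s)
        cm.run_production(s, 10000, dt=1.0,
                          thermostat=ThermostatSpec("none", 10.0, 310.0),
                          stride=10000)
        e1 = total_energy(s)
        assert abs(e1 - e0) / abs(e0) < 1e-4

    def test_langevin_temperature(self, small_np):
        """Time-averaged kinetic temperature within 2% of 310 K over
        10⁵ steps of Langevin dynamics."""
        p = [cm.make_toy_protein(cm.ToyProteinSpec(30, "coil", seed=3))]
        s = cm.init_system(small_np, p, box=200.0, seed=5)
        spec = ThermostatSpec("stochastic", 10.0, 310.0)
        temps = []
        n_chunks, chunk = 250, 400  # 10⁵ steps total
        for _ in range(n_chunks):
            cm.run_production(s, chunk, dt=2.0, thermostat=spec,
                              stride=chunk)
            temps.append(s.kinetic_temperature())
        t_mean = np.mean(temps[n_chunks // 5:])
        assert t_mean == pytest.approx(310.0, rel=0.02)

    def test_zero_steps_initial_frame_only(self, small_system):
        x0 = small_system.coords.copy()
        traj = cm.run_production(small_system, 0, dt=10.0, stride=10)
        assert traj.n_frames == 1
        np.testing.assert_array_equal(traj.coords[0], x0)

    def test_np_beads_never_move(self, small_system):
        before = small_system.nano.coords.copy()
        cm.run_production(small_system, 300, dt=10.0, stride=100)
        np.testing.assert_array_equal(small_system.nano.coords, before)

    def test_no_systematic_drift(self, small_np):
        """Box-averaged protein position wanders diffusively, not
        ballistically."""
        p = [cm.make_toy_protein(cm.ToyProteinSpec(10, "coil", seed=2))]
        s = cm.init_system(small_np, p, box=200.0, seed=4)
        com0 = s.coords.mean(axis=0)
        cm.run_production(s, 2000, dt=10.0, stride=2000)
        drift = np.linalg.norm(s.coords.mean(axis=0) - com0)
        assert drift < 30.0  # diffusion scale over 20 ps, not a fly-away


class TestEquilibrate:

    def test_ladder_reaches_target(self, small_system):
        cm.equilibrate(small_system, steps_per_stage=300)
        assert small_system.temperature == 310.0
        assert small_system.kinetic_temperature() == pytest.approx(
            310.0, rel=0.05)

    def test_default_ladder_has_seven_stages(self):
        from coronams.cg import DEFAULT_LADDER
        assert len(DEFAULT_LADDER) == 7
        assert DEFAULT_LADDER[0] == 10.0 and DEFAULT_LADDER[-1] == 310.0
        assert all(b - a == 50.0 for a, b in zip(DEFAULT_LADDER,
                                                 DEFAULT_LADDER[1:]))

    def test_zero_steps_noop(self, small_system):
        x0 = small_system.coords.copy()
        cm.equilibrate(small_system, steps_per_stage=0)
        np.testing.assert_array_equal(small_system.coords, x0)

    def test_decreasing_ladder_rejected(self, small_system):
        with pytest.raises(ValueError):
            cm.equilibrate(small_system, ladder=(310.0, 10.0),
                           steps_per_stage=1)


class TestAdsorptionSmoke:

    def test_attracted_protein_adsorbs(self):
        """A strongly gold-attracted toy protein started 30 Å from the NP
        centre (≈8 Å surface clearance) binds within the step budget."""
        from coronams.forcefield import GoldInteractionTable
        from coronams.constants import AMINO_ACIDS
        p = cm.make_toy_protein(cm.ToyProteinSpec(10, "helix", seed=1))
        nano = cm.build_gold_np(30.0, 150, -0.5)
        strong = GoldInteractionTable(
            epsilon={aa: 0.3 for aa in AMINO_ACIDS})
        s = cm.init_system(nano, [p], box=200.0, seed=7,
                           model_kwargs={"gold": strong})
        local = s.coords - s.coords.mean(axis=0)
        s.coords = local + s.nano.center + np.array([30.0, 0.0, 0.0])
        s.model._last_coords = None
        traj = cm.run_production(
            s, 40000, dt=10.0,
            thermostat=ThermostatSpec("stochastic", 100.0, 310.0),
            stride=500)
        assert traj.adsorbed_flags.any()
        d = np.linalg.norm(s.coords - s.nano.center, axis=1) - s.nano.radius
        assert d.min() < 6.5
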