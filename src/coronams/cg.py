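"""Coarse-grained dynamics engine.

Runs bead-resolution Langevin/Berendsen dynamics of flexible CG proteins
around a rigid, fixed gold nanoparticle in a periodic cubic box.  Internal
units: Å, fs, Da, kcal/mol.  The "stochastic thermostat" is Langevin (BAOAB
splitting) with friction γ = 1/coupling-time; Berendsen weak coupling is
used for the heating ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .analysis import CONTACT_CUTOFF
from .constants import ACC_KCAL_FS, ENERGY_KCAL_TO_DA_A2_FS2, KB
from .exceptions import IntegrationError, PackingError
from .forcefield import CGEnergyModel
from .nanoparticle import GoldNP, build_gold_np
from .structure import CGProtein

__all__ = ["ThermostatSpec", "Trajectory", "CGSystem", "init_system",
           "equilibrate", "run_production", "DEFAULT_LADDER",
           "kinetic_temperature", "maxwell_boltzmann_velocities"]

#: Equilibration temperature ladder, K (10 K to 310 K in 50 K steps).
DEFAULT_LADDER = (10.0, 60.0, 110.0, 160.0, 210.0, 260.0, 310.0)

_KB_INT = KB * ENERGY_KCAL_TO_DA_A2_FS2  # Boltzmann constant, Da·Å²/fs²/K


@dataclass(frozen=True)
class ThermostatSpec:
    """Thermostat selection: 'berendsen', 'stochastic' (Langevin) or 'none'."""

    kind: str = "stochastic"
    coupling_time: float = 10.0   # fs
    temperature: float = 310.0    # K

    def __post_init__(self):
        if self.kind not in ("berendsen", "stochastic", "none"):
            raise ValueError(f"unknown thermostat {self.kind!r}")
        if self.coupling_time <= 0:
            raise ValueError("coupling time must be positive")


@dataclass
class Trajectory:
    """Recorded frames of a CG production run."""

    times: np.ndarray                 # fs, strictly increasing
    coords: np.ndarray                # (n_frames, n_protein_beads, 3)
    adsorbed_flags: np.ndarray        # (n_frames, n_proteins) bool
    offsets: np.ndarray               # bead offsets per protein
    stride: int
    metadata: dict = field(default_factory=dict)
    labels: np.ndarray = None

    def __post_init__(self):
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_proteins(self) -> int:
        return len(self.offsets) - 1

    def protein_coords(self, index: int) -> np.ndarray:
        """(n_frames, n_residues, 3) coordinates of one protein."""
        a, b = self.offsets[index], self.offsets[index + 1]
        return self.coords[:, a:b, :]

    def write_xyz(self, path, element: str = "C"):
        """Multi-frame XYZ of the protein beads."""
        with open(path, "w") as fh:
            for k in range(self.n_frames):
                fh.write(f"{self.coords.shape[1]}\n")
                fh.write(f"frame {k} time_fs {self.times[k]:.1f}\n")
                for x, y, z in self.coords[k]:
                    fh.write(f"{element} {x:.4f} {y:.4f} {z:.4f}\n")

    def write_flags_csv(self, path):
        import pandas as pd
        df = pd.DataFrame(self.adsorbed_flags.astype(int))
        df.insert(0, "time_fs", self.times)
        df.to_csv(path, index=False)


@dataclass
class CGSystem:
    """One NP plus N flexible CG proteins with dynamic state."""

    nano: GoldNP
    proteins: list
    box: float
    temperature: float
    seed: int
    coords: np.ndarray = None        # concatenated protein beads
    velocities: np.ndarray = None    # Å/fs
    model: CGEnergyModel = None
    rng: np.random.Generator = None  # advances across engine calls

    def __post_init__(self):
        if self.rng is None:
            self.rng = np.random.default_rng([self.seed, 0xC0])

    @property
    def masses(self) -> np.ndarray:
        return self.model.masses

    @property
    def n_beads(self) -> int:
        return self.model.n_beads

    def kinetic_temperature(self) -> float:
        return kinetic_temperature(self.velocities, self.masses)


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Instantaneous kinetic temperature, K (3N degrees of freedom)."""
    ke = 0.5 * float((masses * (velocities ** 2).sum(axis=1)).sum())
    ndof = 3 * len(masses)
    return 2.0 * ke / (ndof * _KB_INT)


def maxwell_boltzmann_velocities(masses: np.ndarray, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann draw, Å/fs."""
    sigma = np.sqrt(_KB_INT * temperature / masses)
    return rng.normal(size=(len(masses), 3)) * sigma[:, None]


def init_system(nano: GoldNP, proteins: list, box: float, seed: int,
                temperature: float = 310.0, min_clearance: float = 10.0,
                max_attempts: int = 2000, model_kwargs: dict | None = None
                ) -> CGSystem:
    """Place proteins at random non-overlapping positions around the NP.

    The NP is re-centred at the box centre; each protein is rigidly rotated
    and translated to a rejection-sampled position with at least
    `min_clearance` Å between its beads and both the NP surface and all
    previously placed beads.  Velocities are Maxwell-Boltzmann at
    `temperature`.
    """
    if box <= 2.0 * nano.diameter:
        raise ValueError("box edge must exceed twice the NP diameter")
    rng = np.random.default_rng(seed)
    centre = np.full(3, box / 2.0)
    nano = build_gold_np(nano.diameter, nano.n_beads, nano.bead_charge,
                         center=centre)

    from ._geometry import random_rotation_matrix
    placed = []
    obstacles = nano.coords.copy()
    tree = cKDTree(obstacles)
    for p in proteins:
        local = p.coords - p.coords.mean(axis=0)
        extent = np.linalg.norm(local, axis=1).max()
        ok = False
        for _ in range(max_attempts):
            rot = random_rotation_matrix(rng)
            com = rng.uniform(0.0, box, size=3)
            if np.linalg.norm(com - centre) < nano.radius + extent \
                    + min_clearance:
                pass  # near/inside the NP: test beads anyway, likely reject
            cand = local @ rot.T + com
            if np.any(cand < 0.0) or np.any(cand >= box):
                continue
            d, _ = tree.query(cand, k=1)
            if d.min() >= min_clearance:
                ok = True
                break
        if not ok:
            raise PackingError(
                f"could not place protein after {max_attempts} attempts")
        placed.append(p.with_coords(cand))
        obstacles = np.vstack([obstacles, cand])
        tree = cKDTree(obstacles)

    model = CGEnergyModel(placed, nano=nano, box=box,
                          **(model_kwargs or {}))
    coords = np.concatenate([q.coords for q in placed])
    vel = maxwell_boltzmann_velocities(model.masses, temperature, rng)
    return CGSystem(nano=nano, proteins=placed, box=box,
                    temperature=temperature, seed=seed, coords=coords,
                    velocities=vel, model=model)


def _check_finite(coords, step):
    if not np.all(np.isfinite(coords)):
        raise IntegrationError(f"non-finite coordinates at step {step}",
                               last_state=None)


def _integrate(system: CGSystem, n_steps: int, dt: float,
               thermostat: ThermostatSpec, rng: np.random.Generator,
               record_stride: int | None = None):
    """Velocity-Verlet core with optional Berendsen scaling or BAOAB
    Langevin noise.  Returns (frames, times, flags) if recording."""
    x = system.coords.copy()
    v = system.velocities.copy()
    m = system.masses[:, None]
    inv_m = ACC_KCAL_FS / m
    model = system.model
    box = system.box

    kind = thermostat.kind
    t0 = thermostat.temperature
    if kind == "stochastic":
        gamma = 1.0 / thermostat.coupling_time
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(1.0 - c1 * c1)
        sigma = np.sqrt(_KB_INT * t0 / system.masses)[:, None]

    frames, times, flags = [], [], []

    def record(step):
        frames.append(x.copy())
        times.append(step * dt)
        flags.append(_adsorbed_flags(system, x))

    _, forces, _ = model.energy_forces(x)
    if record_stride is not None:
        record(0)
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * forces * inv_m
        if kind == "stochastic":
            x += 0.5 * dt * v
            v = c1 * v + c2 * sigma * rng.normal(size=v.shape)
            x += 0.5 * dt * v
        else:
            x += dt * v
        if box is not None:
            np.mod(x, box, out=x)
        _check_finite(x, step)
        _, forces, _ = model.energy_forces(x)
        v += 0.5 * dt * forces * inv_m
        if kind == "berendsen":
            t_kin = kinetic_temperature(v, system.masses)
            lam2 = 1.0 + (dt / thermostat.coupling_time) \
                * (t0 / max(t_kin, 1e-9) - 1.0)
            v *= np.sqrt(np.clip(lam2, 0.64, 1.44))
        if record_stride is not None and step % record_stride == 0:
            record(step)

    system.coords = x
    system.velocities = v
    if record_stride is None:
        return None
    return np.array(frames), np.array(times), np.array(flags)


def _adsorbed_flags(system: CGSystem, coords: np.ndarray) -> np.ndarray:
    """Per-protein flag: ≥1 bead within the contact cutoff of the NP
    surface."""
    d = np.linalg.norm(coords - system.nano.center, axis=1) \
        - system.nano.radius
    within = d < CONTACT_CUTOFF
    off = system.model.offsets
    return np.array([within[off[i]:off[i + 1]].any()
                     for i in range(len(system.proteins))])


def equilibrate(system: CGSystem, ladder=DEFAULT_LADDER,
                steps_per_stage: int = 1000, dt: float = 10.0,
                coupling_time: float = 10.0) -> CGSystem:
    """Heat the system through a Berendsen-thermostatted temperature ladder.

    Stage temperatures must be increasing; zero steps per stage is a no-op.
    """
    ladder = tuple(ladder)
    if any(b <= a for a, b in zip(ladder, ladder[1:])):
        raise ValueError("ladder temperatures must be increasing")
    for t_stage in ladder:
        spec = ThermostatSpec("berendsen", coupling_time, t_stage)
        _integrate(system, steps_per_stage, dt, spec, system.rng)
        system.temperature = t_stage
    return system


def run_production(system: CGSystem, n_steps: int, dt: float = 10.0,
                   thermostat: ThermostatSpec = ThermostatSpec(),
                   stride: int = 100) -> Trajectory:
    """Production dynamics; records a frame every `stride` steps (plus the
    initial frame) with per-protein adsorbed flags."""
    if dt <= 0:
        raise ValueError("timestep must be positive")
    frames, times, flags = _integrate(system, n_steps, dt, thermostat,
                                      system.rng, record_stride=stride)
    return Trajectory(
        times=times, coords=frames, adsorbed_flags=flags,
        offsets=system.model.offsets, stride=stride,
        metadata={"seed": system.seed, "dt_fs": dt,
                  "thermostat": thermostat.kind,
                  "temperature": thermostat.temperature})
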