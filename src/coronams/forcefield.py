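"""Coarse-grained force field for proteins around a gold nanoparticle.

Energy terms
------------
bonded      harmonic virtual bonds and pseudo-angles plus a cosine
            pseudo-dihedral, minimised at the reference structure (Go-like):
            U = Σ k_b (r − R)² + Σ k_θ (θ − θ₀)² + Σ k_φ (1 − cos(φ − φ₀))
protein–protein   Morse excluded volume
            U = ε[(1 − e^{−α(r − r₀)})² − 1], ε = 0.01 kcal/mol,
            α = 0.70 Å⁻¹, r₀ = 9.5 Å
            plus Debye-Hückel electrostatics between charged beads
protein–NP  per-residue-type 12-6 Lennard-Jones with the well depth scaled by
            the average number of gold atoms facing one amino acid (×13),
            plus Debye-Hückel with the citrate bead charge
electrostatics    U = (e²/4πε₀ε_r) z_i z_j e^{−r/l_D} / r with
            l_D = (8π l_b I)^{−1/2}, l_b = 7 Å, I = 150 mM, ε_r = 10

Non-bonded interactions are truncated and shifted at the non-local cutoff
(12 Å); the 8.5 Å local/non-local split is kept as an energy bookkeeping
distinction only.  Pairs separated by one to three bonds are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import _geometry as geom
from .constants import AMINO_ACIDS, COULOMB_KCAL, N_AVOGADRO, RESIDUE_CLASS
from .structure import CGProtein
from .nanoparticle import GoldNP

__all__ = [
    "BondedParams", "MorseParams", "ElectrostaticsParams",
    "GoldInteractionTable", "CutoffScheme", "CGEnergyModel",
    "bonded_energy", "bonded_energy_forces", "morse_energy",
    "debye_length", "debye_huckel_energy", "gold_lj_energy",
]


@dataclass(frozen=True)
class BondedParams:
    """Stiffnesses of the Go-like bonded terms.

    The reference values R, θ₀, φ₀ live on the :class:`CGProtein`.
    """

    k_bond: float = 100.0     # kcal/mol/Å²
    k_angle: float = 20.0     # kcal/mol/rad²
    k_dihedral: float = 1.0   # kcal/mol

    def __post_init__(self):
        if min(self.k_bond, self.k_angle, self.k_dihedral) <= 0:
            raise ValueError("bonded stiffnesses must be positive")


@dataclass(frozen=True)
class MorseParams:
    """Morse excluded-volume parameters (protein–protein)."""

    epsilon: float = 0.01   # kcal/mol
    alpha: float = 0.70     # Å⁻¹
    r0: float = 9.5         # Å

    def __post_init__(self):
        if min(self.epsilon, self.alpha, self.r0) <= 0:
            raise ValueError("Morse parameters must be positive")


@dataclass(frozen=True)
class ElectrostaticsParams:
    """Debye-Hückel screened Coulomb parameters.

    The Debye length is always derived from the Bjerrum length and the ionic
    strength; it is not an independent input.
    """

    dielectric: float = 10.0      # relative permittivity
    bjerrum_length: float = 7.0   # Å
    ionic_strength: float = 0.150  # mol/L

    def __post_init__(self):
        if self.dielectric <= 0 or self.bjerrum_length <= 0:
            raise ValueError("dielectric and Bjerrum length must be positive")

    @property
    def debye_len(self) -> float:
        return debye_length(self)


def debye_length(params: ElectrostaticsParams) -> float:
    """l_D = (8π l_b I)^(−1/2) with I converted from mol/L to Å⁻³."""
    if params.ionic_strength <= 0:
        raise ValueError("ionic strength must be positive")
    number_density = params.ionic_strength * N_AVOGADRO / 1.0e27  # Å⁻³
    return 1.0 / np.sqrt(8.0 * np.pi * params.bjerrum_length * number_density)


def debye_huckel_energy(r, z_i, z_j, params: ElectrostaticsParams):
    """Screened Coulomb energy in kcal/mol for r in Å, charges in e."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    l_d = params.debye_len
    out = (COULOMB_KCAL / params.dielectric) * z_i * z_j \
        * np.exp(-r / l_d) / r
    return float(out) if out.ndim == 0 else out


def morse_energy(r, params: MorseParams):
    """Morse potential in kcal/mol; minimum −ε at r = r₀."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    x = 1.0 - np.exp(-params.alpha * (r - params.r0))
    out = params.epsilon * (x * x - 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class GoldInteractionTable:
    """Per-residue-type Lennard-Jones parameters for amino-acid–gold contact.

    ``epsilon[aa]`` (kcal/mol) and ``sigma[aa]`` (Å) are per single gold
    atom; the effective well depth is ``scale · epsilon`` with the scale
    factor defaulting to 13, the average number of gold surface atoms in
    contact with one amino acid.  The shipped default values are neutral
    placeholders (the calibrated per-residue table must be supplied by the
    user as a plain-text file); every operation that depends on the gold
    table therefore treats it as input data.
    """

    epsilon: dict = field(default_factory=dict)
    sigma: dict = field(default_factory=dict)
    scale: float = 13.0

    def __post_init__(self):
        if not self.epsilon:
            eps0 = {"non-polar": 0.10, "polar": 0.14, "charged": 0.18}
            self.epsilon = {aa: eps0[RESIDUE_CLASS[aa]] for aa in AMINO_ACIDS}
        if not self.sigma:
            self.sigma = {aa: 5.0 for aa in AMINO_ACIDS}
        if self.scale <= 0:
            raise ValueError("scale factor must be positive")
        missing = set(AMINO_ACIDS) - set(self.epsilon) & set(self.sigma)
        if set(self.epsilon) != set(AMINO_ACIDS) or \
                set(self.sigma) != set(AMINO_ACIDS):
            raise ValueError(f"gold table must cover all 20 residue types; "
                             f"missing {sorted(missing)}")

    def lookup(self, aa: str) -> tuple[float, float]:
        try:
            return self.epsilon[aa], self.sigma[aa]
        except KeyError:
            raise KeyError(f"residue type {aa!r} not in gold table") from None

    @classmethod
    def shipped(cls, scale: float = 13.0) -> "GoldInteractionTable":
        """Load the editable parameter file shipped with the package
        (placeholder values identical to the in-code defaults)."""
        from importlib.resources import files
        path = files("coronams").joinpath("data/gold_params.dat")
        return cls.from_file(path, scale=scale)

    @classmethod
    def from_file(cls, path, scale: float = 13.0) -> "GoldInteractionTable":
        """Read a plain-text table with lines ``RES epsilon sigma``.

        ``RES`` may be a 1- or 3-letter code; '#' starts a comment.
        """
        from .constants import THREE_TO_ONE
        eps, sig = {}, {}
        for line in Path(str(path)).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            name, e, s = line.split()[:3]
            aa = THREE_TO_ONE.get(name.upper(), name.upper())
            eps[aa] = float(e)
            sig[aa] = float(s)
        return cls(epsilon=eps, sigma=sig, scale=scale)

    def to_file(self, path):
        from .constants import ONE_TO_THREE
        lines = ["# residue  epsilon(kcal/mol)  sigma(A)"]
        for aa in AMINO_ACIDS:
            lines.append(f"{ONE_TO_THREE[aa]}  {self.epsilon[aa]:.4f}  "
                         f"{self.sigma[aa]:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")


def gold_lj_energy(r, residue_type: str, table: GoldInteractionTable):
    """12-6 LJ between one protein bead and one gold bead, kcal/mol."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    eps, sig = table.lookup(residue_type)
    sr6 = (sig / r) ** 6
    out = 4.0 * table.scale * eps * (sr6 * sr6 - sr6)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CutoffScheme:
    """Local / non-local non-bonded cutoffs (Å)."""

    local: float = 8.5
    nonlocal_: float = 12.0

    def __post_init__(self):
        if not 0 < self.local < self.nonlocal_:
            raise ValueError("require 0 < local < non-local cutoff")


# ---------------------------------------------------------------------------
# bonded energy / forces
# ---------------------------------------------------------------------------

def bonded_energy(p: CGProtein, coords: np.ndarray,
                  params: BondedParams = BondedParams(), disp=None) -> float:
    """Go-like bonded energy of one protein at the given coordinates."""
    e, _ = bonded_energy_forces(p, coords, params, disp=disp,
                                compute_forces=False)
    return e


def bonded_energy_forces(p: CGProtein, coords: np.ndarray,
                         params: BondedParams = BondedParams(), disp=None,
                         compute_forces: bool = True):
    """Return (energy, forces) of the bonded terms; forces = −∇U."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != p.coords.shape:
        raise ValueError("coordinate shape mismatch")
    forces = np.zeros_like(coords) if compute_forces else None
    energy = 0.0

    if len(p.bonds):
        d = coords[p.bonds[:, 1]] - coords[p.bonds[:, 0]]
        if disp is not None:
            d = disp(d)
        r = geom.norms(d)
        dr = r - p.ref_bond_lengths
        energy += params.k_bond * float((dr * dr).sum())
        if compute_forces:
            # dU/dr = 2 k_b (r - R), force on j is -dU/dr * d/r
            f = (2.0 * params.k_bond * dr / np.maximum(r, 1e-12))[:, None] * d
            np.add.at(forces, p.bonds[:, 0], f)
            np.add.at(forces, p.bonds[:, 1], -f)

    if len(p.angle_triples):
        if compute_forces:
            theta, gi, gj, gk = geom.angle_gradients(
                coords, p.angle_triples, disp)
        else:
            theta = geom.angles(coords, p.angle_triples, disp)
        dth = theta - p.ref_angles
        energy += params.k_angle * float((dth * dth).sum())
        if compute_forces:
            dU = 2.0 * params.k_angle * dth
            np.add.at(forces, p.angle_triples[:, 0], -dU[:, None] * gi)
            np.add.at(forces, p.angle_triples[:, 1], -dU[:, None] * gj)
            np.add.at(forces, p.angle_triples[:, 2], -dU[:, None] * gk)

    if len(p.dihedral_quads):
        if compute_forces:
            phi, gi, gj, gk, gl = geom.dihedral_gradients(
                coords, p.dihedral_quads, disp)
        else:
            phi = geom.dihedrals(coords, p.dihedral_quads, disp)
        dphi = phi - p.ref_dihedrals
        energy += params.k_dihedral * float((1.0 - np.cos(dphi)).sum())
        if compute_forces:
            dU = params.k_dihedral * np.sin(dphi)
            np.add.at(forces, p.dihedral_quads[:, 0], -dU[:, None] * gi)
            np.add.at(forces, p.dihedral_quads[:, 1], -dU[:, None] * gj)
            np.add.at(forces, p.dihedral_quads[:, 2], -dU[:, None] * gk)
            np.add.at(forces, p.dihedral_quads[:, 3], -dU[:, None] * gl)

    return energy, forces


# ---------------------------------------------------------------------------
# full-system non-bonded calculator
# ---------------------------------------------------------------------------

class CGEnergyModel:
    """Energies and forces for a set of CG proteins around a fixed NP.

    Holds the concatenated protein topology, per-bead properties, exclusion
    list (beads one to three bonds apart), and a skin-buffered Verlet pair
    list.  Coordinates passed to :meth:`energy_forces` are the protein beads
    only, concatenated in protein order; the NP beads never move.
    """

    def __init__(self, proteins: list[CGProtein], nano: GoldNP | None = None,
                 bonded: BondedParams = BondedParams(),
                 morse: MorseParams = MorseParams(),
                 elec: ElectrostaticsParams = ElectrostaticsParams(),
                 gold: GoldInteractionTable | None = None,
                 cutoffs: CutoffScheme = CutoffScheme(),
                 box: float | None = None, skin: float = 2.0):
        self.proteins = list(proteins)
        self.nano = nano
        self.bonded = bonded
        self.morse = morse
        self.elec = elec
        self.gold = gold or GoldInteractionTable()
        self.cutoffs = cutoffs
        self.box = box
        self.skin = skin

        offsets = np.cumsum([0] + [p.n_residues for p in self.proteins])
        self.offsets = offsets
        self.n_beads = int(offsets[-1])
        seq = "".join(p.sequence for p in self.proteins)
        self.charges = np.concatenate(
            [p.charges for p in self.proteins]) if self.proteins else \
            np.empty(0)
        self.masses = np.concatenate(
            [p.masses for p in self.proteins]) if self.proteins else \
            np.empty(0)
        self.gold_eps = np.array(
            [self.gold.scale * self.gold.epsilon[aa] for aa in seq])
        self.gold_sig = np.array([self.gold.sigma[aa] for aa in seq])

        self._exclusions = self._build_exclusions()
        self._np_tree = (cKDTree(nano.coords) if nano is not None else None)
        self._pp_pairs = None
        self._pnp = None
        self._last_coords = None
        self._ld = self.elec.debye_len
        # shift constants at the non-local cutoff
        rc = self.cutoffs.nonlocal_
        self._morse_shift = morse_energy(rc, self.morse)
        self._dh_shift_unit = (COULOMB_KCAL / self.elec.dielectric) \
            * np.exp(-rc / self._ld) / rc
        sr6 = (self.gold_sig / rc) ** 6
        self._gold_shift = 4.0 * self.gold_eps * (sr6 * sr6 - sr6)

    # -- topology helpers ---------------------------------------------------

    def _build_exclusions(self) -> np.ndarray:
        """Sorted codes i*n + j (i<j) of pairs separated by 1–3 bonds."""
        codes = []
        n = self.n_beads
        for p, off in zip(self.proteins, self.offsets[:-1]):
            for start, stop in p.chain_bounds:
                for i in range(start, stop):
                    for j in range(i + 1, min(i + 4, stop)):
                        codes.append((off + i) * n + (off + j))
        return np.array(sorted(codes), dtype=np.int64)

    def _min_image(self, d: np.ndarray) -> np.ndarray:
        if self.box is not None:
            d = d - self.box * np.round(d / self.box)
        return d

    def _search_coords(self, coords: np.ndarray) -> np.ndarray:
        if self.box is None:
            return coords
        return np.mod(coords, self.box)

    def _rebuild_pairs(self, coords: np.ndarray):
        rc = self.cutoffs.nonlocal_ + self.skin
        sc = self._search_coords(coords)
        boxsize = self.box if self.box is not None else None
        tree = cKDTree(sc, boxsize=boxsize)
        pairs = tree.query_pairs(rc, output_type="ndarray")
        if len(pairs):
            pairs.sort(axis=1)
            codes = pairs[:, 0].astype(np.int64) * self.n_beads + pairs[:, 1]
            keep = ~np.isin(codes, self._exclusions, assume_unique=False)
            pairs = pairs[keep]
        self._pp_pairs = pairs
        if self._np_tree is not None:
            hits = self._np_tree.query_ball_point(
                coords, rc)  # NP not wrapped; box must contain it centrally
            pi, ni = [], []
            for i, lst in enumerate(hits):
                pi.extend([i] * len(lst))
                ni.extend(lst)
            self._pnp = (np.array(pi, dtype=int), np.array(ni, dtype=int))
        self._last_coords = coords.copy()

    def _pairs(self, coords: np.ndarray):
        if self._last_coords is None or \
                len(self._last_coords) != len(coords):
            self._rebuild_pairs(coords)
        else:
            delta = self._min_image(coords - self._last_coords)
            if np.max(np.einsum("ij,ij->i", delta, delta)) > \
                    (0.5 * self.skin) ** 2:
                self._rebuild_pairs(coords)
        return self._pp_pairs, self._pnp

    # -- energies -----------------------------------------------------------

    def energy_forces(self, coords: np.ndarray, include_bonded: bool = True):
        """Total energy (kcal/mol), forces (kcal/mol/Å) on protein beads,
        and an energy breakdown dict."""
        coords = np.asarray(coords, dtype=float)
        forces = np.zeros_like(coords)
        breakdown = {"bonded": 0.0, "morse": 0.0, "elec": 0.0, "gold": 0.0,
                     "local": 0.0, "nonlocal": 0.0}

        if include_bonded:
            for p, off in zip(self.proteins, self.offsets[:-1]):
                sl = slice(off, off + p.n_residues)
                e, f = bonded_energy_forces(p, coords[sl], self.bonded,
                                            disp=self._min_image)
                breakdown["bonded"] += e
                forces[sl] += f

        rc = self.cutoffs.nonlocal_
        pp, pnp = self._pairs(coords)

        if pp is not None and len(pp):
            i, j = pp[:, 0], pp[:, 1]
            d = self._min_image(coords[j] - coords[i])
            r2 = np.einsum("ij,ij->i", d, d)
            within = r2 < rc * rc
            i, j, d, r2 = i[within], j[within], d[within], r2[within]
            r = np.sqrt(r2)
            if len(r):
                # Morse excluded volume (all protein pairs)
                ex = np.exp(-self.morse.alpha * (r - self.morse.r0))
                x = 1.0 - ex
                e_m = self.morse.epsilon * (x * x - 1.0) - self._morse_shift
                du_m = 2.0 * self.morse.epsilon * self.morse.alpha * ex * x
                # Debye-Hückel (charged pairs)
                zz = self.charges[i] * self.charges[j]
                pref = COULOMB_KCAL / self.elec.dielectric
                e_dh = zz * (pref * np.exp(-r / self._ld) / r
                             - self._dh_shift_unit)
                du_dh = -zz * pref * np.exp(-r / self._ld) / r \
                    * (1.0 / self._ld + 1.0 / r)
                breakdown["morse"] += float(e_m.sum())
                breakdown["elec"] += float(e_dh.sum())
                e_pair = e_m + e_dh
                local = r <= self.cutoffs.local
                breakdown["local"] += float(e_pair[local].sum())
                breakdown["nonlocal"] += float(e_pair[~local].sum())
                fmag = -(du_m + du_dh) / r  # along d gives force on j
                fv = fmag[:, None] * d
                np.add.at(forces, j, fv)
                np.add.at(forces, i, -fv)

        if pnp is not None and self.nano is not None and len(pnp[0]):
            pi, ni = pnp
            d = coords[pi] - self.nano.coords[ni]  # NP inside box; no wrap
            r2 = np.einsum("ij,ij->i", d, d)
            within = r2 < rc * rc
            pi, ni, d, r2 = pi[within], ni[within], d[within], r2[within]
            r = np.sqrt(r2)
            if len(r):
                eps = self.gold_eps[pi]
                sig = self.gold_sig[pi]
                sr6 = (sig / r) ** 6
                e_g = 4.0 * eps * (sr6 * sr6 - sr6) - self._gold_shift[pi]
                du_g = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
                zz = self.charges[pi] * self.nano.bead_charge
                pref = COULOMB_KCAL / self.elec.dielectric
                e_dh = zz * (pref * np.exp(-r / self._ld) / r
                             - self._dh_shift_unit)
                du_dh = -zz * pref * np.exp(-r / self._ld) / r \
                    * (1.0 / self._ld + 1.0 / r)
                breakdown["gold"] += float(e_g.sum())
                breakdown["elec"] += float(e_dh.sum())
                e_pair = e_g + e_dh
                local = r <= self.cutoffs.local
                breakdown["local"] += float(e_pair[local].sum())
                breakdown["nonlocal"] += float(e_pair[~local].sum())
                fmag = -(du_g + du_dh) / r
                np.add.at(forces, pi, fmag[:, None] * d)
                # reaction forces fall on the rigid, fixed NP

        total = breakdown["bonded"] + breakdown["morse"] \
            + breakdown["elec"] + breakdown["gold"]
        return total, forces, breakdown

    def energy(self, coords: np.ndarray, include_bonded: bool = True):
        return self.energy_forces(coords, include_bonded)[0]

    def brute_force_nonbonded(self, coords: np.ndarray):
        """O(N²) double-loop reference for the non-bonded energy; used as an
        independent oracle against the pair-list path."""
        coords = np.asarray(coords, dtype=float)
        rc = self.cutoffs.nonlocal_
        excl = set(self._exclusions.tolist())
        n = len(coords)
        e = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                if i * self.n_beads + j in excl:
                    continue
                d = self._min_image(coords[j] - coords[i])
                r = float(np.sqrt((d * d).sum()))
                if r >= rc:
                    continue
                e += morse_energy(r, self.morse) - self._morse_shift
                zz = self.charges[i] * self.charges[j]
                if zz != 0.0:
                    e += zz * (COULOMB_KCAL / self.elec.dielectric
                               * np.exp(-r / self._ld) / r
                               - self._dh_shift_unit)
        if self.nano is not None:
            for i in range(n):
                for k in range(self.nano.n_beads):
                    d = coords[i] - self.nano.coords[k]
                    r = float(np.sqrt((d * d).sum()))
                    if r >= rc:
                        continue
                    sr6 = (self.gold_sig[i] / r) ** 6
                    e += 4.0 * self.gold_eps[i] * (sr6 * sr6 - sr6) \
                        - self._gold_shift[i]
                    zz = self.charges[i] * self.nano.bead_charge
                    if zz != 0.0:
                        e += zz * (COULOMB_KCAL / self.elec.dielectric
                                   * np.exp(-r / self._ld) / r
                                   - self._dh_shift_unit)
        return e
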