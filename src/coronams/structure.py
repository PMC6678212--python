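"""Structure parsing and the one-bead-per-residue coarse-grained representation.

Each amino acid is reduced to a single bead at its α-carbon.  The bead carries
the residue's average mass, its formal charge at neutral pH (Lys/Arg +1,
Asp/Glu −1, His neutral, termini uncharged) and its physico-chemical class.
Bonded topology (virtual bonds, pseudo-angles, pseudo-dihedrals) is built per
chain, and the reference internal coordinates R, θ₀, φ₀ are measured on the
input structure, which therefore defines the minimum of the bonded potential.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from . import _geometry as geom
from .constants import (THREE_TO_ONE, residue_charges, residue_classes,
                        residue_masses)
from .exceptions import BuildError, EmptyStructureError

__all__ = [
    "AtomRecordSet", "CGProtein", "MesoProtein",
    "read_structure", "build_cg_protein", "radius_of_gyration",
    "to_meso_protein", "EFFECTIVE_RADIUS_FACTOR",
]

#: Radius of the equivalent uniform sphere: R_eff = R_G · sqrt(5/3).
EFFECTIVE_RADIUS_FACTOR = float(np.sqrt(5.0 / 3.0))


@dataclass
class AtomRecordSet:
    """Thin wrapper around a biotite :class:`AtomArray` of ATOM records."""

    atoms: struc.AtomArray

    def __len__(self) -> int:
        return self.atoms.array_length()

    @property
    def coords(self) -> np.ndarray:
        return self.atoms.coord

    @property
    def chain_ids(self) -> np.ndarray:
        return self.atoms.chain_id


def read_structure(source: str | io.TextIOBase) -> AtomRecordSet:
    """Parse PDB content into an :class:`AtomRecordSet`.

    Only ATOM records of the first model are kept (altloc "A"/first);
    waters and heteroatoms are discarded.

    Parameters
    ----------
    source
        PDB text, a path to a PDB file, or an open text handle.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    pdb = PDBFile.read(source)
    try:
        atoms = pdb.get_structure(model=1, altloc="first")
    except ValueError as exc:
        raise EmptyStructureError(
            f"no ATOM records found in structure ({exc})") from None
    atoms = atoms[~atoms.hetero]
    atoms = atoms[atoms.element != ""]  # defensive; biotite fills elements
    if atoms.array_length() == 0:
        raise EmptyStructureError("no ATOM records found in structure")
    if not np.all(np.isfinite(atoms.coord)):
        raise EmptyStructureError("non-finite coordinates in structure")
    return AtomRecordSet(atoms)


@dataclass
class CGProtein:
    """Coarse-grained protein: one bead per residue at the Cα position.

    Attributes
    ----------
    coords : (n, 3) float array, Å
    sequence : str of 1-letter codes
    charges : (n,) float, e
    classes : list of 'non-polar' | 'polar' | 'charged'
    masses : (n,) float, Da
    chain_bounds : list of (start, stop) half-open bead index ranges
    bonds, angle_triples, dihedral_quads : topology index arrays
    ref_bond_lengths (R), ref_angles (θ₀), ref_dihedrals (φ₀) :
        internal coordinates measured on the reference structure
    """

    coords: np.ndarray
    sequence: str
    chain_bounds: list = field(default_factory=list)
    charges: np.ndarray = None
    classes: list = None
    masses: np.ndarray = None
    bonds: np.ndarray = None
    angle_triples: np.ndarray = None
    dihedral_quads: np.ndarray = None
    ref_bond_lengths: np.ndarray = None
    ref_angles: np.ndarray = None
    ref_dihedrals: np.ndarray = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.sequence)
        if self.coords.shape != (n, 3):
            raise BuildError(
                f"coordinate array {self.coords.shape} does not match "
                f"sequence length {n}")
        if not self.chain_bounds:
            self.chain_bounds = [(0, n)]
        if self.charges is None:
            self.charges = residue_charges(self.sequence)
        if self.classes is None:
            self.classes = residue_classes(self.sequence)
        if self.masses is None:
            self.masses = residue_masses(self.sequence)
        if self.bonds is None:
            self._build_topology()
        if self.ref_bond_lengths is None:
            self.set_reference(self.coords)

    def _build_topology(self):
        bonds, triples, quads = [], [], []
        for start, stop in self.chain_bounds:
            idx = np.arange(start, stop)
            if len(idx) >= 2:
                bonds.append(np.column_stack([idx[:-1], idx[1:]]))
            if len(idx) >= 3:
                triples.append(np.column_stack([idx[:-2], idx[1:-1], idx[2:]]))
            if len(idx) >= 4:
                quads.append(np.column_stack(
                    [idx[:-3], idx[1:-2], idx[2:-1], idx[3:]]))
        empty = np.empty((0, 2), dtype=int)
        self.bonds = np.vstack(bonds) if bonds else empty
        self.angle_triples = (np.vstack(triples) if triples
                              else np.empty((0, 3), dtype=int))
        self.dihedral_quads = (np.vstack(quads) if quads
                               else np.empty((0, 4), dtype=int))

    def set_reference(self, coords: np.ndarray):
        """Measure R, θ₀, φ₀ on `coords` and store them as the reference."""
        self.ref_bond_lengths = geom.bond_lengths(coords, self.bonds)
        self.ref_angles = geom.angles(coords, self.angle_triples)
        self.ref_dihedrals = geom.dihedrals(coords, self.dihedral_quads)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def total_mass(self) -> float:
        """Total bead mass, Da."""
        return float(self.masses.sum())

    def with_coords(self, coords: np.ndarray) -> "CGProtein":
        """Copy sharing topology/references but with new coordinates."""
        new = replace(self)
        new.coords = np.asarray(coords, dtype=float)
        return new


@dataclass(frozen=True)
class MesoProtein:
    """Meso-scale protein: a single sphere with the mass and radius of the
    real protein."""

    mass_kda: float
    radius: float  # Å
    label: str = ""

    def __post_init__(self):
        if self.mass_kda <= 0 or self.radius <= 0:
            raise ValueError("meso protein mass and radius must be positive")


def build_cg_protein(atoms: AtomRecordSet,
                     chains: list[str] | None = None) -> CGProtein:
    """Convert an atom record set into the Cα-bead model.

    Parameters
    ----------
    atoms
        Parsed structure (first model, ATOM records only).
    chains
        Chain identifiers to keep, in order; ``None`` keeps all chains.
    """
    arr = atoms.atoms
    if chains is not None:
        arr = arr[np.isin(arr.chain_id, list(chains))]
        if arr.array_length() == 0:
            raise BuildError(f"no atoms in selected chains {chains}")

    coords, seq, bounds = [], [], []
    for chain_id in _ordered_unique(arr.chain_id):
        chain = arr[arr.chain_id == chain_id]
        start = len(seq)
        for res_id in _ordered_unique(chain.res_id):
            res = chain[chain.res_id == res_id]
            res_name = res.res_name[0]
            one = THREE_TO_ONE.get(res_name)
            if one is None:
                raise BuildError(
                    f"non-standard residue {res_name} {res_id} "
                    f"in chain {chain_id}")
            ca = res[res.atom_name == "CA"]
            if ca.array_length() == 0:
                raise BuildError(
                    f"residue {res_name} {res_id} in chain {chain_id} "
                    f"has no CA atom")
            coords.append(ca.coord[0])
            seq.append(one)
        bounds.append((start, len(seq)))

    return CGProtein(coords=np.array(coords, dtype=float),
                     sequence="".join(seq), chain_bounds=bounds)


def _ordered_unique(values: np.ndarray) -> np.ndarray:
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


def radius_of_gyration(p: CGProtein) -> float:
    """Mass-weighted RMS distance of the beads from the center of mass (Å)."""
    if p.n_residues == 0:
        raise ValueError("protein has no beads")
    m = p.masses
    com = (m[:, None] * p.coords).sum(axis=0) / m.sum()
    d2 = ((p.coords - com) ** 2).sum(axis=1)
    return float(np.sqrt((m * d2).sum() / m.sum()))


def to_meso_protein(p: CGProtein, radius_rule: str = "effective",
                    label: str = "") -> MesoProtein:
    """Reduce a CG protein to its meso-scale sphere.

    radius_rule
        ``"gyration"`` uses R_G directly; ``"effective"`` (default) uses the
        radius of the uniform sphere with the same R_G, i.e. R_G·sqrt(5/3).
    """
    rg = radius_of_gyration(p)
    if radius_rule == "gyration":
        radius = rg
    elif radius_rule == "effective":
        radius = rg * EFFECTIVE_RADIUS_FACTOR
    else:
        raise ValueError(f"unknown radius rule {radius_rule!r}")
    return MesoProtein(mass_kda=p.total_mass / 1000.0, radius=radius,
                       label=label)
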