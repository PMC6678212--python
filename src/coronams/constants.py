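"""Physical constants, unit conversions, and amino-acid property tables.

Internal unit system
--------------------
length   : Å (angstrom)
energy   : kcal/mol
mass     : Da (g/mol)
time     : fs in the coarse-grained engine, ps in the meso-scale engine
charge   : e (elementary charges)

With these units an acceleration computed as (kcal/mol/Å)/Da must be
multiplied by :data:`ACC_KCAL_FS` to obtain Å/fs² (or :data:`ACC_KCAL_PS`
for Å/ps²).
"""

from __future__ import annotations

import numpy as np

#: Boltzmann constant / gas constant, kcal/mol/K.
KB = 1.987204259e-3

#: Coulomb prefactor e²/(4πε₀) in kcal·Å/mol for charges in e and r in Å.
COULOMB_KCAL = 332.06

#: Avogadro's number, 1/mol.
N_AVOGADRO = 6.02214076e23

#: 1 kcal/mol expressed in Da·Å²/fs².
ENERGY_KCAL_TO_DA_A2_FS2 = 4.184e-4
#: 1 kcal/mol expressed in Da·Å²/ps².
ENERGY_KCAL_TO_DA_A2_PS2 = 418.4

#: Conversion for accelerations: (kcal/mol/Å)/Da -> Å/fs².
ACC_KCAL_FS = ENERGY_KCAL_TO_DA_A2_FS2
#: Conversion for accelerations: (kcal/mol/Å)/Da -> Å/ps².
ACC_KCAL_PS = ENERGY_KCAL_TO_DA_A2_PS2

#: One-letter codes of the 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Average residue masses (Da); residue = amino acid minus one water.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: Mass of one water molecule (Da), added once per chain for the termini.
WATER_MASS = 18.0153

#: Formal side-chain charge at neutral pH (His neutral, termini uncharged).
RESIDUE_CHARGE = {aa: 0 for aa in AMINO_ACIDS}
RESIDUE_CHARGE.update({"K": 1, "R": 1, "D": -1, "E": -1, "H": 0})

#: Physico-chemical class partition of the 20 residue types.
#: Charged = {K, R, D, E, H}; polar = {S, T, N, Q, Y, C, W};
#: non-polar = {A, V, L, I, M, F, G, P}.  Exhaustive and disjoint.
RESIDUE_CLASS = {}
for _aa in "KRDEH":
    RESIDUE_CLASS[_aa] = "charged"
for _aa in "STNQYCW":
    RESIDUE_CLASS[_aa] = "polar"
for _aa in "AVLIMFGP":
    RESIDUE_CLASS[_aa] = "non-polar"

CLASS_NAMES = ("non-polar", "polar", "charged")


def residue_masses(sequence: str) -> np.ndarray:
    """Per-residue average masses (Da) for a 1-letter sequence."""
    try:
        return np.array([RESIDUE_MASS[aa] for aa in sequence], dtype=float)
    except KeyError as exc:  # pragma: no cover - defensive
        raise KeyError(f"unknown residue type {exc.args[0]!r}") from None


def residue_charges(sequence: str) -> np.ndarray:
    """Formal per-residue charges (e) at neutral pH."""
    return np.array([RESIDUE_CHARGE[aa] for aa in sequence], dtype=float)


def residue_classes(sequence: str) -> list[str]:
    """Residue class labels ('non-polar' | 'polar' | 'charged')."""
    return [RESIDUE_CLASS[aa] for aa in sequence]
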