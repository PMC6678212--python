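"""Writers for the lightweight text formats used by the package."""

from __future__ import annotations

import json

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .constants import ONE_TO_THREE
from .nanoparticle import GoldNP
from .structure import CGProtein


def write_ca_pdb(p: CGProtein, path) -> None:
    """Write a CG protein as a Cα-only PDB file."""
    n = p.n_residues
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(p.coords, dtype=np.float32)
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.res_name = np.array([ONE_TO_THREE[aa] for aa in p.sequence])
    atoms.hetero = np.zeros(n, dtype=bool)
    chain_ids = np.empty(n, dtype="U2")
    res_ids = np.empty(n, dtype=int)
    for c, (start, stop) in enumerate(p.chain_bounds):
        chain_ids[start:stop] = chr(ord("A") + (c % 26))
        res_ids[start:stop] = np.arange(1, stop - start + 1)
    atoms.chain_id = chain_ids
    atoms.res_id = res_ids
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(path)


def write_topology_json(p: CGProtein, path) -> None:
    """JSON sidecar with topology and reference internal coordinates."""
    data = {
        "sequence": p.sequence,
        "chain_bounds": [list(b) for b in p.chain_bounds],
        "charges": p.charges.tolist(),
        "bonds": p.bonds.tolist(),
        "ref_bond_lengths": p.ref_bond_lengths.tolist(),
        "ref_angles": p.ref_angles.tolist(),
        "ref_dihedrals": p.ref_dihedrals.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def write_np_xyz(nano: GoldNP, path) -> None:
    """Write the NP bead sphere as an XYZ file (element Au)."""
    with open(path, "w") as fh:
        fh.write(f"{nano.n_beads}\n")
        fh.write(f"gold NP d={nano.diameter:.1f} A "
                 f"q_bead={nano.bead_charge:+.2f} e\n")
        for x, y, z in nano.coords:
            fh.write(f"Au {x:.4f} {y:.4f} {z:.4f}\n")


def write_np_charges_json(nano: GoldNP, path) -> None:
    with open(path, "w") as fh:
        json.dump({"n_beads": nano.n_beads, "bead_charge": nano.bead_charge,
                   "total_charge": nano.total_charge,
                   "diameter": nano.diameter}, fh)
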