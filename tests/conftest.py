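from __future__ import annotations

import numpy as np
import pytest

from partner_scan.structure_io import Atom, Residue, Structure


def single_atom_residue(chain, number, position, name="GLY"):
    return Residue(chain_id=chain, seq_number=number, name=name,
                   atoms=[Atom("CA", "C", np.asarray(position, dtype=float))])


def random_structure(seed: int, max_residues: int = 50,
                     two_chains: bool = False) -> Structure:
    """Random pseudo-structure with 1-3 atoms per residue, scaled so that a
    useful fraction of atom pairs lands inside the 2.5-5 Å contact band."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_residues + 1))
    box = 4.0 * n ** (1 / 3)
    residues = []
    for i in range(n):
        chain = "B" if (two_chains and i >= n // 2) else "A"
        number = i + 1 if chain == "A" else i + 1 - n // 2
        center = rng.uniform(0, box, size=3)
        atoms = [
            Atom(f"A{k}", "C", center + rng.uniform(-1.2, 1.2, size=3))
            for k in range(int(rng.integers(1, 4)))
        ]
        residues.append(Residue(chain_id=chain, seq_number=number,
                                name="ALA", atoms=atoms))
    return Structure(id=f"random_{seed}", residues=residues)


@pytest.fixture
def two_residue_pdb(tmp_path):
    """Hand-written minimal PDB: GLY at origin, ALA at (10, 0, 0), CA only."""
    text = (
        "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  CA  ALA A   2      10.000   0.000   0.000  1.00  0.00           C\n"
        "END\n"
    )
    path = tmp_path / "two_res.pdb"
    path.write_text(text)
    return path
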