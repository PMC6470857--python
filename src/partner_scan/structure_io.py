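"""PDB coordinate I/O and domain extraction.

The pipeline works on docked two-chain complexes and on single-domain
structures cut out of larger entries.  Coordinates are kept in author (PDB)
numbering throughout, so domain windows such as "residues 331 to 415" can be
applied directly.  Parsing is delegated to Biopython's PDB parser; only a
thin, deterministic model of the structure (chains -> residues -> atoms) is
retained:

* waters (HOH) are always excluded;
* other hetero groups are excluded by default (``include_hetero=True`` keeps
  them) — residue contact networks are built over protein residues;
* alternate locations are resolved to the highest-occupancy conformer, ties
  going to the first conformer encountered in the file;
* hydrogens, when present, are kept: the contact rule considers *any* atom
  pair, and files that include hydrogens are taken at face value.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
from Bio.PDB import PDBParser


class ResidueKey(NamedTuple):
    """Unique residue identifier: chain, author number, insertion code, name."""

    chain_id: str
    seq_number: int
    insertion_code: str
    name: str

    @property
    def label(self) -> str:
        """Human-readable label in the ``Trp361`` style."""
        return f"{self.name.title()}{self.seq_number}{self.insertion_code}"

    def sif_label(self) -> str:
        return f"{self.chain_id}:{self.seq_number}{self.insertion_code}:{self.name}"


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom coords must be a 3-vector, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(
                f"residue {self.chain_id}:{self.seq_number} has no atoms"
            )

    @property
    def key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.seq_number, self.insertion_code, self.name)

    def atom_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class Structure:
    """Ordered residue list with unique (chain, number, insertion code) keys."""

    id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.chain_id, r.seq_number, r.insertion_code) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate residue keys in structure {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chain_ids:
            raise KeyError(f"chain {chain_id!r} not in structure {self.id!r}")
        return [r for r in self.residues if r.chain_id == chain_id]

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


def read_pdb(path: str | os.PathLike, model_index: int = 0,
             include_hetero: bool = False) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path:
        PDB-format file with ATOM (and optionally HETATM/MODEL) records.
    model_index:
        0-based index into the models of the file; multi-model (NMR) files
        default to the first model.
    include_hetero:
        Keep non-water hetero groups.  Waters are always dropped.

    Raises
    ------
    FileNotFoundError, ValueError
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure_id = os.path.splitext(os.path.basename(path))[0]
    bio_structure = parser.get_structure(structure_id, path)
    models = list(bio_structure.get_models())
    if not models:
        raise ValueError(f"no ATOM records in {path}")
    if not 0 <= model_index < len(models):
        raise ValueError(
            f"model_index {model_index} out of range: file has {len(models)} model(s)"
        )
    model = models[model_index]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            hetflag, seq_number, icode = res.id
            if hetflag == "W" or res.resname.strip() == "HOH":
                continue
            is_hetero = hetflag.strip() != ""
            if is_hetero and not include_hetero:
                continue
            atoms = []
            # iterating a residue yields one atom per name: Biopython's
            # disordered-atom container already selects the highest-occupancy
            # altloc (first conformer wins occupancy ties)
            for atom in res:
                atoms.append(
                    Atom(
                        name=atom.get_name(),
                        element=(atom.element or "").strip(),
                        coords=atom.get_coord(),
                        is_hetero=is_hetero,
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        chain_id=chain.id.strip() or chain.id,
                        seq_number=seq_number,
                        name=res.resname.strip(),
                        atoms=atoms,
                        insertion_code=icode.strip(),
                    )
                )
    if not residues:
        raise ValueError(f"no usable ATOM records in {path}")
    return Structure(id=structure_id, residues=residues)


def extract_domain(s: Structure, chain_id: str, start: int, end: int) -> Structure:
    """Residues of ``chain_id`` with ``start <= seq_number <= end``.

    The window is inclusive on both ends (author numbering); residues with
    insertion codes are kept whenever their numeric part is inside the window.
    An empty window returns an empty Structure.
    """
    if start > end:
        raise ValueError(f"start ({start}) must be <= end ({end})")
    if chain_id not in s.chain_ids:
        raise KeyError(f"chain {chain_id!r} not in structure {s.id!r}")
    kept = [
        r for r in s.residues
        if r.chain_id == chain_id and start <= r.seq_number <= end
    ]
    return Structure(id=f"{s.id}_{chain_id}_{start}_{end}", residues=kept)


def write_pdb(s: Structure, path: str | os.PathLike) -> None:
    """Write a Structure as fixed-column PDB ATOM/HETATM records.

    Round-trips through :func:`read_pdb` preserve residue keys, atom names
    and coordinates to the 3 decimals the format carries.
    """
    lines: list[str] = []
    serial = 1
    prev_chain: str | None = None
    for res in s.residues:
        if prev_chain is not None and res.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = res.chain_id
        for atom in res.atoms:
            record = "HETATM" if atom.is_hetero else "ATOM"
            name = atom.name
            # standard alignment: 1-3 character names start in column 14
            name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
            x, y, z = atom.coords
            lines.append(
                f"{record:<6s}{serial:5d} {name_field}"
                f" {res.name:>3s} {res.chain_id[:1]}{res.seq_number:4d}"
                f"{res.insertion_code or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {atom.element[:2]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")
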