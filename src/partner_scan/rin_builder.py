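"""Residue interaction network (RIN) construction.

Two residues are in contact when at least one of their atom pairs lies inside
a closed distance band, by default 2.5–5.0 Å.  The lower bound excludes
clashes and covalently bonded pairs from counting on their own, but a residue
pair with one sub-2.5 Å atom pair still qualifies if another of its atom
pairs falls inside the band (the rule is existential over atom pairs inside
the band).

The RIN is an undirected :class:`networkx.Graph` whose nodes are
:class:`~partner_scan.structure_io.ResidueKey` tuples; every residue of the
structure becomes a node, including residues without any contact.  The band
parameters are recorded as graph attributes.  Contacts are located with a
k-d tree over all atoms; the result is identical to an exhaustive
atom-pair scan.
"""

from __future__ import annotations

import os

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Residue, ResidueKey, Structure

D_MIN_DEFAULT = 2.5
D_MAX_DEFAULT = 5.0


def residues_in_contact(r1: Residue, r2: Residue,
                        d_min: float = D_MIN_DEFAULT,
                        d_max: float = D_MAX_DEFAULT) -> bool:
    """True iff some atom pair of (r1, r2) has distance in [d_min, d_max]."""
    if d_min > d_max:
        raise ValueError(f"d_min ({d_min}) must be <= d_max ({d_max})")
    if not r1.atoms or not r2.atoms:
        raise ValueError("residues must have at least one atom")
    a = r1.atom_coords()
    b = r2.atom_coords()
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    return bool(np.any((d >= d_min) & (d <= d_max)))


def build_rin(s: Structure,
              d_min: float = D_MIN_DEFAULT,
              d_max: float = D_MAX_DEFAULT,
              min_seq_separation: int = 0) -> nx.Graph:
    """Build the residue interaction network of a structure.

    Parameters
    ----------
    s:
        Structure with at least two residues.
    d_min, d_max:
        Closed contact band in Å.
    min_seq_separation:
        Optional minimum |Δ seq_number| for same-chain contacts; 0 keeps
        sequence neighbours (the default contact rule states no exclusion).

    Returns
    -------
    networkx.Graph with ResidueKey nodes, ``d_min``/``d_max`` graph
    attributes and one edge per residue pair in contact.
    """
    if d_min > d_max:
        raise ValueError(f"d_min ({d_min}) must be <= d_max ({d_max})")
    if len(s) < 2:
        raise ValueError("a RIN needs at least two residues")

    rin = nx.Graph(d_min=d_min, d_max=d_max, structure_id=s.id)
    keys = [r.key for r in s.residues]
    rin.add_nodes_from(keys)

    coords = []
    owner = []  # atom index -> residue index
    for i, res in enumerate(s.residues):
        for atom in res.atoms:
            coords.append(atom.coords)
            owner.append(i)
    coords = np.asarray(coords)
    owner = np.asarray(owner)

    tree = cKDTree(coords)
    pairs = tree.query_pairs(d_max, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        in_band = d >= d_min
        ri = owner[pairs[:, 0]]
        rj = owner[pairs[:, 1]]
        for i, j in zip(ri[in_band], rj[in_band]):
            if i == j:
                continue
            ki, kj = keys[i], keys[j]
            if min_seq_separation and ki.chain_id == kj.chain_id:
                if abs(ki.seq_number - kj.seq_number) < min_seq_separation:
                    continue
            rin.add_edge(ki, kj)
    return rin


def _format_node(key: ResidueKey) -> str:
    return key.sif_label()


def _parse_node(label: str) -> ResidueKey:
    chain, num, name = label.split(":")
    digits = num.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz")
    icode = num[len(digits):]
    return ResidueKey(chain, int(digits), icode, name)


def write_rin(rin: nx.Graph, path: str | os.PathLike, format: str = "sif") -> None:
    """Write a RIN as a SIF (``A:338:TRP cnt A:342:LEU``) or TSV edge list.

    Isolated nodes are emitted as single-column lines (SIF) or rows with an
    empty partner (TSV) so that node inventories round-trip.
    """
    if format not in {"sif", "tsv"}:
        raise ValueError(f"unknown format {format!r}")
    edges = sorted((sorted((_format_node(u), _format_node(v))) for u, v in rin.edges()))
    isolated = sorted(_format_node(n) for n in nx.isolates(rin))
    lines = []
    if format == "tsv":
        lines.append("node1\tinteraction\tnode2")
        lines.extend(f"{u}\tcnt\t{v}" for u, v in edges)
        lines.extend(f"{n}\t\t" for n in isolated)
    else:
        lines.extend(f"{u} cnt {v}" for u, v in edges)
        lines.extend(isolated)
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + ("\n" if lines else ""))


def read_rin(path: str | os.PathLike, format: str = "sif",
             d_min: float | None = None, d_max: float | None = None) -> nx.Graph:
    """Parse a RIN written by :func:`write_rin` back into a graph."""
    if format not in {"sif", "tsv"}:
        raise ValueError(f"unknown format {format!r}")
    rin = nx.Graph(d_min=d_min, d_max=d_max)
    with open(path) as handle:
        rows = [line.rstrip("\n") for line in handle if line.strip()]
    if format == "tsv":
        rows = rows[1:]
    for row in rows:
        fields = row.split("\t") if format == "tsv" else row.split()
        if format == "sif" and len(fields) == 1 or format == "tsv" and not fields[2]:
            rin.add_node(_parse_node(fields[0]))
        else:
            u = _parse_node(fields[0])
            v = _parse_node(fields[2])
            rin.add_edge(u, v)
    return rin
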