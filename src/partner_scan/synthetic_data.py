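"""Synthetic fixtures for every stage of the pipeline.

The generators stand in for external inputs that are impractical at desk
scale (docking-server poses, database exports): toy two-chain complexes with
a designed contact map, a hub complex with a provably maximal-betweenness
interface residue, PPI networks encoding the filter-cascade topologies, toy
sequence families with planted cluster structure, and expression tables with
planted significant genes.

Geometry is pseudo-atomic: each residue carries 2–3 atoms, placed so the
designed contacts fall inside the 2.5–5.0 Å band while every non-designed
inter-chain atom pair stays beyond 6 Å (a safety margin above the band).
A small seeded jitter (±0.05 Å per coordinate) makes distinct seeds produce
distinct coordinates without ever moving a pair across the band boundaries;
the resulting contact graph is therefore identical for every seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .homolog_clustering import DomainSequence
from .structure_io import Atom, Residue, ResidueKey, Structure

_JITTER = 0.05
_CHAIN_SPACING = 4.8     # consecutive residues stay inside the contact band
_CONTACT_DISTANCE = 4.5  # designed inter-chain contact distance
_CHAIN_GAP = 40.0        # baseline separation between the two chains

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: residue key of the engineered hub in :func:`make_hub_complex`
HUB_KEY = ResidueKey("A", 1, "", "TRP")


@dataclass(frozen=True)
class ComplexSpec:
    """Design of a toy docked complex.

    ``contacts`` lists (bait_residue_number, partner_residue_number) pairs
    (1-based) that must touch inside the contact band; all other inter-chain
    residue pairs are kept > 6 Å apart.
    """

    n_res_bait: int = 8
    n_res_partner: int = 6
    contacts: tuple[tuple[int, int], ...] = ()
    bait_chain: str = "A"
    partner_chain: str = "B"
    seed: int = 0

    def validate(self) -> None:
        if self.n_res_bait < 1 or self.n_res_partner < 1:
            raise ValueError("chains need at least one residue")
        for a, b in self.contacts:
            if not 1 <= a <= self.n_res_bait:
                raise ValueError(f"contact references bait residue {a} "
                                 f"outside 1..{self.n_res_bait}")
            if not 1 <= b <= self.n_res_partner:
                raise ValueError(f"contact references partner residue {b} "
                                 f"outside 1..{self.n_res_partner}")
        if len(set(self.contacts)) != len(self.contacts):
            raise ValueError("duplicate designed contacts")


def _jitter(rng: np.random.Generator, point: np.ndarray) -> np.ndarray:
    return np.asarray(point, dtype=float) + rng.uniform(-_JITTER, _JITTER, size=3)


def make_toy_complex(spec: ComplexSpec) -> Structure:
    """Two pseudo-atom chains realising exactly the designed contact map.

    Each chain is a straight run of residues 4.8 Å apart (so consecutive
    residues are in contact); the chains sit 40 Å apart.  A designed
    contact (a, b) adds a long-arm pseudo-atom to partner residue ``b``
    placed 4.5 Å from bait residue ``a`` and > 6 Å from every other bait
    residue.  Deterministic per seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    residues: list[Residue] = []
    for i in range(1, spec.n_res_bait + 1):
        base = np.array([i * _CHAIN_SPACING, 0.0, 0.0])
        residues.append(Residue(
            chain_id=spec.bait_chain, seq_number=i, name="ALA",
            atoms=[
                Atom("CA", "C", _jitter(rng, base)),
                Atom("CB", "C", _jitter(rng, base + [0.0, 0.0, 1.5])),
            ],
        ))
    contact_atoms: dict[int, list[Atom]] = {}
    for serial, (a, b) in enumerate(spec.contacts, start=1):
        anchor = np.array([a * _CHAIN_SPACING, _CONTACT_DISTANCE, 0.0])
        contact_atoms.setdefault(b, []).append(
            Atom(f"CG{serial}", "C", _jitter(rng, anchor))
        )
    for j in range(1, spec.n_res_partner + 1):
        base = np.array([j * _CHAIN_SPACING, _CHAIN_GAP, 0.0])
        atoms = [
            Atom("CA", "C", _jitter(rng, base)),
            Atom("CB", "C", _jitter(rng, base + [0.0, 0.0, 1.5])),
        ] + contact_atoms.get(j, [])
        residues.append(Residue(
            chain_id=spec.partner_chain, seq_number=j, name="GLY", atoms=atoms,
        ))
    return Structure(id=f"toy_complex_seed{spec.seed}", residues=residues)


def make_hub_complex(seed: int = 0) -> Structure:
    """Complex whose bait residue A:1 is a provable betweenness hub.

    Chain A is a star: the hub at the origin contacts five satellite
    residues placed 4 Å away along coordinate axes (satellites are mutually
    > 5 Å apart, so all A-chain shortest paths run through the hub).  Chain
    B is a three-residue arm approaching along -z whose first residue
    contacts only the hub.  In the resulting contact graph the hub is the
    sole articulation point joining the satellite cluster to the partner
    arm, has the maximal betweenness, a Z-score above 2, and carries the
    only inter-chain contact.
    """
    rng = np.random.default_rng(seed)
    directions = np.array([
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1],
    ], dtype=float)
    residues = [Residue(
        chain_id="A", seq_number=1, name="TRP",
        atoms=[
            Atom("CA", "C", _jitter(rng, np.zeros(3))),
            Atom("CB", "C", _jitter(rng, np.full(3, 1.2 / np.sqrt(3)))),
        ],
    )]
    for i, direction in enumerate(directions, start=2):
        residues.append(Residue(
            chain_id="A", seq_number=i, name="ALA",
            atoms=[
                Atom("CA", "C", _jitter(rng, 4.0 * direction)),
                Atom("CB", "C", _jitter(rng, 5.2 * direction)),
            ],
        ))
    for j, z in enumerate([-4.0, -8.8, -13.6], start=1):
        residues.append(Residue(
            chain_id="B", seq_number=j, name="GLY",
            atoms=[
                Atom("CA", "C", _jitter(rng, np.array([0.0, 0.0, z]))),
                Atom("CB", "C", _jitter(rng, np.array([0.0, 0.0, z - 1.2]))),
            ],
        ))
    return Structure(id=f"hub_complex_seed{seed}", residues=residues)


# ---------------------------------------------------------------------------
# PPI network scenarios


@dataclass
class NetworkScenario:
    """Planted PPI fixture plus its hand-derived ground truth."""

    name: str
    experimental_edges: str
    annotations: str
    predicted_edges: str | None = None
    baits: tuple[str, ...] = ()
    #: node set expected to survive the scenario's filter
    expected_nodes: set[str] = field(default_factory=set)
    #: candidate id -> evidence class (fig4 only)
    expected_candidates: dict[str, str] = field(default_factory=dict)
    #: (u, v) sorted tuple -> provenance expected after merging (fig3 only)
    expected_provenance: dict[tuple[str, str], str] = field(default_factory=dict)


def _write_edges(path: str, edges: list[tuple[str, str, str]],
                 rng: np.random.Generator) -> None:
    rows = [f"{u}\t{v}\t{p}" for u, v, p in edges]
    order = rng.permutation(len(rows))
    with open(path, "w") as handle:
        handle.write("source\ttarget\tprovenance\n")
        for i in order:
            handle.write(rows[i] + "\n")


def _write_annotations(path: str, nodes: dict[str, tuple[str, bool]]) -> None:
    """nodes: id -> (';'-joined groups, dna_repair flag)."""
    with open(path, "w") as handle:
        handle.write("id\tgroups\tinterpro\tdna_repair\n")
        for node, (groups, repair) in sorted(nodes.items()):
            interpro = "1" if groups else "0"
            handle.write(f"{node}\t{groups}\t{interpro}\t{int(repair)}\n")


def make_network_scenario(name: str, seed: int = 0,
                          out_dir: str | os.PathLike = ".") -> NetworkScenario:
    """Emit the edge/annotation fixtures of a named filter scenario.

    ``fig2`` exercises the shared-interactor rule, ``fig3`` the
    experimental/predicted merge, ``fig4`` the full DNA-repair bridging
    cascade (14 qualifying candidates, 6 decoys), and ``custom`` a network
    without any connector.  The seed only permutes file row order; the
    planted topology — and hence the ground truth — is fixed.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    exp_path = os.path.join(out_dir, f"{name}_experimental.tsv")
    ann_path = os.path.join(out_dir, f"{name}_annotations.tsv")
    pred_path = os.path.join(out_dir, f"{name}_predicted.tsv")

    if name == "fig2":
        nodes = {
            "ETSa": ("ETS", False), "ETSb": ("ETS", False), "ETSc": ("ETS", False),
            "BRCTa": ("BRCT", True), "BRCTb": ("BRCT", False),
            "SAPa": ("SAP", True), "SAPb": ("SAP", False),
            "CONN_EB": ("", False), "CONN_ES": ("", False), "CONN_ALL": ("", False),
            "DECOY_E": ("", False), "DECOY_B": ("", False), "DECOY_SS": ("", False),
        }
        edges = [
            ("CONN_EB", "ETSa", "experimental"), ("CONN_EB", "BRCTa", "experimental"),
            ("CONN_ES", "ETSb", "experimental"), ("CONN_ES", "SAPa", "experimental"),
            ("CONN_ALL", "ETSa", "experimental"), ("CONN_ALL", "BRCTb", "experimental"),
            ("CONN_ALL", "SAPb", "experimental"),
            ("DECOY_E", "ETSa", "experimental"), ("DECOY_E", "ETSb", "experimental"),
            ("DECOY_B", "BRCTa", "experimental"),
            ("DECOY_SS", "SAPa", "experimental"), ("DECOY_SS", "SAPb", "experimental"),
            ("ETSa", "ETSb", "experimental"), ("ETSb", "ETSc", "experimental"),
        ]
        _write_edges(exp_path, edges, rng)
        _write_annotations(ann_path, nodes)
        expected = {n for n, (g, _) in nodes.items() if g}
        expected |= {"CONN_EB", "CONN_ES", "CONN_ALL"}
        return NetworkScenario(name=name, experimental_edges=exp_path,
                               annotations=ann_path, expected_nodes=expected)

    if name == "fig3":
        nodes = {
            "ETSa": ("ETS", False), "ETSc": ("ETS", False),
            "BRCTa": ("BRCT", True), "BRCTb": ("BRCT", False),
            "SAPa": ("SAP", False), "SAPb": ("SAP", True),
        }
        experimental = [
            ("ETSa", "ETSc", "experimental"),
            ("ETSc", "SAPa", "experimental"),
            ("ETSa", "BRCTa", "experimental"),
        ]
        predicted = [
            ("ETSa", "BRCTa", "predicted"),  # duplicate: experimental must win
            ("ETSa", "BRCTb", "predicted"),
            ("ETSa", "SAPb", "predicted"),
        ]
        _write_edges(exp_path, experimental, rng)
        _write_edges(pred_path, predicted, rng)
        _write_annotations(ann_path, nodes)
        expected_provenance = {
            ("ETSa", "ETSc"): "experimental",
            ("ETSc", "SAPa"): "experimental",
            ("BRCTa", "ETSa"): "experimental",
            ("BRCTb", "ETSa"): "predicted",
            ("ETSa", "SAPb"): "predicted",
        }
        return NetworkScenario(name=name, experimental_edges=exp_path,
                               predicted_edges=pred_path, annotations=ann_path,
                               expected_nodes=set(nodes),
                               expected_provenance=expected_provenance)

    if name in ("fig4", "custom"):
        nodes = {
            "ETS1": ("ETS", False), "ETS2": ("ETS", False),
            "ETS3": ("ETS", False), "ETS4": ("ETS", False),
            "PARP1": ("BRCT", True), "KU70": ("SAP", True),
            **{f"B_DIR{k}": ("BRCT", True) for k in range(1, 6)},
            "S_DIR1": ("SAP", True), "S_BRG1": ("SAP", True),
            **{f"B_NBR{k}": ("BRCT", False) for k in range(1, 4)},
            **{f"S_NBR{k}": ("SAP", False) for k in range(1, 5)},
            "DECOY_B1": ("BRCT", True), "DECOY_S1": ("SAP", False),
            "CONN1": ("", False), "DECOY_C1": ("", False), "DECOY_C2": ("", False),
        }
        experimental = [
            ("ETS1", "PARP1", "experimental"), ("ETS1", "KU70", "experimental"),
            ("ETS1", "ETS2", "experimental"), ("ETS3", "ETS4", "experimental"),
            ("CONN1", "ETS2", "experimental"), ("CONN1", "S_BRG1", "experimental"),
            ("B_NBR1", "B_DIR1", "experimental"), ("B_NBR2", "B_DIR2", "experimental"),
            ("B_NBR3", "B_DIR3", "experimental"),
            ("S_NBR1", "S_DIR1", "experimental"), ("S_NBR2", "S_DIR1", "experimental"),
            ("S_NBR3", "S_DIR1", "experimental"), ("S_NBR4", "S_DIR1", "experimental"),
            ("DECOY_B1", "B_DIR1", "experimental"),
            ("DECOY_S1", "ETS2", "experimental"),
            ("DECOY_C1", "ETS2", "experimental"), ("DECOY_C1", "DECOY_S1", "experimental"),
            ("DECOY_C2", "B_DIR1", "experimental"), ("DECOY_C2", "B_DIR2", "experimental"),
        ]
        predicted = [
            (f"ETS1", f"B_DIR{k}", "predicted") for k in range(1, 6)
        ] + [("ETS1", "S_DIR1", "predicted")]
        if name == "custom":
            # no connectors, no predicted bridge edges: only homolog nodes
            # with a path to the other side can survive
            experimental = [
                ("ETS1", "PARP1", "experimental"), ("ETS1", "KU70", "experimental"),
                ("ETS1", "ETS2", "experimental"),
                ("B_DIR1", "B_DIR2", "experimental"),
            ]
            predicted = [("ETS1", "B_DIR1", "predicted")]
            nodes = {k: v for k, v in nodes.items()
                     if k in {"ETS1", "ETS2", "PARP1", "KU70", "B_DIR1", "B_DIR2"}}
            _write_edges(exp_path, experimental, rng)
            _write_edges(pred_path, predicted, rng)
            _write_annotations(ann_path, nodes)
            return NetworkScenario(
                name=name, experimental_edges=exp_path, predicted_edges=pred_path,
                annotations=ann_path, baits=("PARP1", "KU70"),
                expected_nodes={"ETS1", "ETS2", "B_DIR1", "B_DIR2"},
                expected_candidates={"B_DIR1": "direct"},
            )
        _write_edges(exp_path, experimental, rng)
        _write_edges(pred_path, predicted, rng)
        _write_annotations(ann_path, nodes)
        expected_candidates = {
            **{f"B_DIR{k}": "direct" for k in range(1, 6)},
            "S_DIR1": "direct",
            "S_BRG1": "bridge_via_connector",
            **{f"B_NBR{k}": "neighbour_of_bridge" for k in range(1, 4)},
            **{f"S_NBR{k}": "neighbour_of_bridge" for k in range(1, 5)},
        }
        expected_nodes = (
            {"ETS1", "ETS2", "CONN1", "DECOY_B1", "DECOY_S1"}
            | set(expected_candidates)
        )
        return NetworkScenario(
            name=name, experimental_edges=exp_path, predicted_edges=pred_path,
            annotations=ann_path, baits=("PARP1", "KU70"),
            expected_nodes=expected_nodes, expected_candidates=expected_candidates,
        )

    raise ValueError(f"unknown scenario {name!r}")


# ---------------------------------------------------------------------------
# sequence families and expression tables


def make_toy_sequences(n_clusters: int = 3,
                       within_identity: float = 98.0,
                       between_identity: float = 40.0,
                       n_members: int = 4,
                       length: int = 150,
                       seed: int = 0,
                       ) -> tuple[list[DomainSequence], dict[str, int]]:
    """Sequence family with a planted partition.

    Cluster founders differ from each other at ``(100 - between_identity)%``
    of positions; members mutate their founder at half the within-identity
    complement, so realized member–member identity within a cluster stays
    within about 2 points of ``within_identity``.  Returns the sequences and
    the planted id -> cluster-index partition.
    """
    if not 0 < between_identity < within_identity <= 100:
        raise ValueError("need 0 < between_identity < within_identity <= 100")
    if n_clusters < 1 or n_members < 1:
        raise ValueError("need at least one cluster and one member")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AMINO_ALPHABET))

    def mutate(sequence: np.ndarray, n_sites: int) -> np.ndarray:
        mutant = sequence.copy()
        sites = rng.choice(length, size=n_sites, replace=False)
        for site in sites:
            options = [aa for aa in AMINO_ALPHABET if aa != mutant[site]]
            mutant[site] = options[rng.integers(len(options))]
        return mutant

    n_between = int(round(length * (100 - between_identity) / 100))
    n_within = int(round(length * (100 - within_identity) / 100 / 2))
    if n_between >= length:
        raise ValueError("between_identity too low for the sequence length")

    base = alphabet[rng.integers(len(alphabet), size=length)]
    sequences: list[DomainSequence] = []
    partition: dict[str, int] = {}
    for c in range(n_clusters):
        founder = base if c == 0 else mutate(base, n_between)
        for m in range(n_members):
            variant = founder if m == 0 else mutate(founder, n_within)
            seq_id = f"C{c}_M{m}"
            sequences.append(DomainSequence(id=seq_id, sequence="".join(variant)))
            partition[seq_id] = c
    return sequences, partition


def make_toy_expression(genes: int | list[str], n_significant: int,
                        seed: int = 0) -> pd.DataFrame:
    """Expression table with planted significant genes.

    The first ``n_significant`` genes get adjusted p <= 0.01 and
    |log2 fold-change| >= 1; all others get adjusted p > 0.05 and a small
    fold-change.  Columns: gene, log2fc, adj_p.
    """
    names = [f"G{i:04d}" for i in range(genes)] if isinstance(genes, int) else list(genes)
    if n_significant > len(names):
        raise ValueError("n_significant exceeds the number of genes")
    rng = np.random.default_rng(seed)
    rows = []
    for i, gene in enumerate(names):
        if i < n_significant:
            adj_p = float(rng.uniform(1e-6, 0.009))
            log2fc = float(rng.choice([-1, 1]) * rng.uniform(1.0, 3.0))
        else:
            adj_p = float(rng.uniform(0.06, 0.95))
            log2fc = float(rng.uniform(-0.5, 0.5))
        rows.append({"gene": gene, "log2fc": round(log2fc, 4),
                     "adj_p": round(adj_p, 6)})
    return pd.DataFrame(rows, columns=["gene", "log2fc", "adj_p"])


def write_expression(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)
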