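"""Docking-pose interface analysis and ensemble aggregation.

A bait residue belongs to the interface of a docked pose when it has at
least one RIN edge to a residue of the partner chain, i.e. interface
membership reuses the same 2.5–5.0 Å contact definition as the network
itself.  Per pose, the analysis intersects the interface set with the
central residues (betweenness Z-score >= 2 over the whole complex RIN).

Over an ensemble of poses — one pose per docking run against a different
partner homolog — residues are summarised by two counts: the number of poses
in which the residue sits at the interface (``nb_interface``) and the number
of poses in which it is simultaneously central and at the interface
(``nb_central``).  Reported rows are restricted to residues central at the
interface in at least ``min_count`` poses (default 2).  By construction
``nb_central <= nb_interface <= n_poses`` on every row.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .centrality import Z_THRESHOLD_DEFAULT, central_residues, centrality_zscores
from .rin_builder import D_MAX_DEFAULT, D_MIN_DEFAULT, build_rin
from .structure_io import ResidueKey, Structure


@dataclass(frozen=True)
class PoseReport:
    """Interface/centrality summary of a single docked pose (bait side)."""

    pose_id: str
    bait_chain: str
    partner_chain: str
    interface_residues: frozenset[ResidueKey]
    central_residues: frozenset[ResidueKey]

    @property
    def central_interface_residues(self) -> frozenset[ResidueKey]:
        return self.interface_residues & self.central_residues


def interface_residues(rin: nx.Graph, bait_chain: str,
                       partner_chain: str) -> set[ResidueKey]:
    """Bait-chain residues with at least one RIN edge to the partner chain."""
    chains = {k.chain_id for k in rin.nodes}
    for chain in (bait_chain, partner_chain):
        if chain not in chains:
            raise KeyError(f"chain {chain!r} absent from the RIN")
    return {
        u for u, v in nx.edge_boundary(
            rin,
            [k for k in rin.nodes if k.chain_id == bait_chain],
            [k for k in rin.nodes if k.chain_id == partner_chain],
        )
    }


def analyze_pose(complex: Structure, bait_chain: str, partner_chain: str,
                 d_min: float = D_MIN_DEFAULT, d_max: float = D_MAX_DEFAULT,
                 z_threshold: float = Z_THRESHOLD_DEFAULT,
                 pose_id: str | None = None) -> PoseReport:
    """Full per-pose analysis: RIN -> centrality Z-scores -> interface.

    Central residues are computed over the pooled two-chain network but the
    reported sets are restricted to the bait chain.
    """
    for chain in (bait_chain, partner_chain):
        if chain not in complex.chain_ids:
            raise KeyError(f"chain {chain!r} absent from structure {complex.id!r}")
    rin = build_rin(complex, d_min=d_min, d_max=d_max)
    result = centrality_zscores(rin, z_threshold=z_threshold)
    central = {
        k for k in central_residues(result) if k.chain_id == bait_chain
    }
    iface = interface_residues(rin, bait_chain, partner_chain)
    return PoseReport(
        pose_id=pose_id or complex.id,
        bait_chain=bait_chain,
        partner_chain=partner_chain,
        interface_residues=frozenset(iface),
        central_residues=frozenset(central),
    )


def aggregate_ensemble(reports: list[PoseReport],
                       min_count: int = 2) -> pd.DataFrame:
    """Per-residue interface/centrality counts over an ensemble of poses.

    Returns a DataFrame with one row per bait residue central at the
    interface in at least ``min_count`` poses, sorted by ``nb_central``
    descending, then ``nb_interface`` descending, then residue number.
    ``n_poses`` and ``min_count`` are stored in ``DataFrame.attrs``.
    """
    if not reports:
        raise ValueError("at least one pose report is required")
    bait_chains = {r.bait_chain for r in reports}
    if len(bait_chains) > 1:
        raise ValueError(f"mixed bait chains in ensemble: {sorted(bait_chains)}")

    nb_interface: Counter[ResidueKey] = Counter()
    nb_central: Counter[ResidueKey] = Counter()
    for report in reports:
        nb_interface.update(report.interface_residues)
        nb_central.update(report.central_interface_residues)

    rows = [
        {
            "chain": k.chain_id,
            "seq_number": k.seq_number,
            "insertion_code": k.insertion_code,
            "residue": k.label,
            "nb_interface": nb_interface[k],
            "nb_central": nb_central.get(k, 0),
        }
        for k in nb_interface
        if nb_central.get(k, 0) >= min_count
    ]
    rows.sort(key=lambda r: (-r["nb_central"], -r["nb_interface"],
                             r["chain"], r["seq_number"], r["insertion_code"]))
    table = pd.DataFrame(
        rows,
        columns=["chain", "seq_number", "insertion_code", "residue",
                 "nb_interface", "nb_central"],
    )
    table.attrs["n_poses"] = len(reports)
    table.attrs["min_count"] = min_count
    return table
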