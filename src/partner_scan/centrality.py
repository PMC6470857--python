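"""Residue centrality analysis (RCA).

A residue is called *central* when its shortest-path betweenness centrality,
Z-scored over all residues of the complex's RIN, is at least a threshold
(default 2).  Betweenness is computed on the unweighted, undirected graph
with the Brandes convention: endpoints are excluded, equally short paths
split fractionally, and pairs are only counted within connected components.

Z-scores use the sample (n-1) standard deviation over every node of the
network.  Because the Z-transform is invariant under positive affine
rescaling of the raw betweenness, normalized and unnormalized betweenness
produce identical central-residue calls.  When all residues have the same
betweenness (sd = 0) all Z-scores are defined as 0 and no residue is central.

By default the two chains of a docked complex are pooled into a single
Z-score population; ``per_chain=True`` normalizes within each chain instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .structure_io import ResidueKey

logger = logging.getLogger(__name__)

Z_THRESHOLD_DEFAULT = 2.0


def betweenness(rin: nx.Graph) -> dict[ResidueKey, float]:
    """Unnormalized shortest-path betweenness per residue.

    Each unordered node pair contributes 1, split over the equally shortest
    paths between it; endpoints are excluded.
    """
    if rin.number_of_nodes() == 0:
        raise ValueError("betweenness of an empty graph is undefined")
    return nx.betweenness_centrality(rin, normalized=False, endpoints=False)


@dataclass
class CentralityResult:
    """Per-residue betweenness and Z-scores with the central-residue calls."""

    betweenness: dict[ResidueKey, float]
    z_scores: dict[ResidueKey, float]
    z_threshold: float = Z_THRESHOLD_DEFAULT
    per_chain: bool = False
    central: set[ResidueKey] = field(init=False)

    def __post_init__(self) -> None:
        self.central = {
            k for k, z in self.z_scores.items() if z >= self.z_threshold
        }

    def is_central(self, key: ResidueKey) -> bool:
        return key in self.central

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain": k.chain_id,
                "seq_number": k.seq_number,
                "insertion_code": k.insertion_code,
                "residue": k.label,
                "betweenness": self.betweenness[k],
                "z_score": self.z_scores[k],
                "is_central": k in self.central,
            }
            for k in sorted(self.z_scores)
        ]
        return pd.DataFrame(
            rows,
            columns=["chain", "seq_number", "insertion_code", "residue",
                     "betweenness", "z_score", "is_central"],
        )


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1) if len(values) > 1 else 0.0
    if sd == 0.0:
        logger.warning("constant betweenness: all Z-scores set to 0, "
                       "no residue can be called central")
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def centrality_zscores(rin: nx.Graph,
                       z_threshold: float = Z_THRESHOLD_DEFAULT,
                       per_chain: bool = False) -> CentralityResult:
    """Betweenness Z-scores over the residues of a RIN.

    Raises
    ------
    ValueError
        For graphs with fewer than two nodes (the Z-score is undefined).
    """
    if rin.number_of_nodes() < 2:
        raise ValueError("Z-scores need at least two residues")
    b = betweenness(rin)
    keys = sorted(b)
    raw = np.array([b[k] for k in keys], dtype=float)
    z = np.empty_like(raw)
    if per_chain:
        chains = np.array([k.chain_id for k in keys])
        for chain in np.unique(chains):
            mask = chains == chain
            z[mask] = _zscore(raw[mask])
    else:
        z = _zscore(raw)
    return CentralityResult(
        betweenness=dict(zip(keys, raw)),
        z_scores=dict(zip(keys, z)),
        z_threshold=z_threshold,
        per_chain=per_chain,
    )


def central_residues(result: CentralityResult,
                     z_threshold: float | None = None) -> set[ResidueKey]:
    """Residues with Z-score >= threshold (default: the result's threshold)."""
    if z_threshold is None:
        return set(result.central)
    return {k for k, z in result.z_scores.items() if z >= z_threshold}
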