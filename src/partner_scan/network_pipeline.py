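"""PPI network assembly, filtering cascade and candidate report.

The pipeline consumes flat exports of protein–protein interaction databases:
an edge list (TSV ``source  target  provenance`` or SIF) plus a node
annotation table assigning each protein its homolog groups (any subset of
ETS / BRCT / SAP), a domain-annotation flag and a DNA-repair flag (pathway
membership is an *input* column here, typically GO:0006281 membership —
enrichment itself is upstream of this module).

The cascade mirrors the partner-identification logic:

1. ``shared_interactor_filter`` — keep all homolog-group nodes and only
   those other nodes that interact with at least two distinct homolog
   groups (the ego networks of a single group are discarded).
2. ``merge_networks`` — union of the experimentally established and the
   predicted network; a duplicated edge keeps the experimental provenance.
3. ``dna_repair_filter`` — remove the already-known bait partners, then keep
   (i) every homolog-group node, (ii) connector nodes bridging an
   ETS-group homolog to a DNA-repair-flagged BRCT/SAP homolog, and
   (iii) implicitly, BRCT/SAP homologs reached through a repair-flagged
   bridge; finally prune ETS-side nodes left without a path to any BRCT/SAP
   homolog.
4. ``expression_overlay`` — annotate nodes with differential-expression
   results, keeping only signals with adjusted p <= 0.01 (best probe per
   gene wins).
5. ``candidate_report`` — one row per BRCT/SAP homolog with an evidence
   class: ``direct`` (repair-flagged, direct edge to the bait group),
   ``bridge_via_connector`` (repair-flagged, reached through a kept
   connector) or ``neighbour_of_bridge`` (not repair-flagged itself but
   adjacent to a repair-flagged protein that bridges to the bait group).
"""

from __future__ import annotations

import logging
import os

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("ETS", "BRCT", "SAP")
PROVENANCES = ("experimental", "predicted")


def _empty_like(net: nx.Graph) -> nx.Graph:
    out = nx.Graph()
    out.graph.update(net.graph)
    return out


def _groups(net: nx.Graph, node: str) -> frozenset:
    return net.nodes[node].get("groups", frozenset())


def _is_homolog(net: nx.Graph, node: str) -> bool:
    return bool(_groups(net, node))


def _is_repair(net: nx.Graph, node: str) -> bool:
    return bool(net.nodes[node].get("dna_repair", False))


# ---------------------------------------------------------------------------
# loading

def _parse_bool(value: str) -> bool:
    return value.strip().lower() in {"1", "true", "yes", "y"}


def load_annotations(path: str | os.PathLike) -> dict[str, dict]:
    """Node annotation TSV: id, groups (';'-separated), interpro, dna_repair."""
    annotations: dict[str, dict] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields")
            record = dict(zip(header, fields))
            groups = frozenset(
                g for g in record.get("groups", "").split(";") if g
            )
            unknown = groups - set(GROUPS)
            if unknown:
                raise ValueError(f"{path}:{lineno}: unknown groups {sorted(unknown)}")
            annotations[record["id"]] = {
                "groups": groups,
                "interpro": _parse_bool(record.get("interpro", "")),
                "dna_repair": _parse_bool(record.get("dna_repair", "")),
            }
    return annotations


def load_network(edges_path: str | os.PathLike,
                 annotations_path: str | os.PathLike | None = None,
                 default_provenance: str = "experimental") -> nx.Graph:
    """Load an edge list (TSV with header, or SIF) into an annotated graph.

    Duplicate edges collapse with experimental taking precedence over
    predicted; self-loops are dropped with a warning.  Malformed rows raise
    with their line number.
    """
    if default_provenance not in PROVENANCES:
        raise ValueError(f"unknown provenance {default_provenance!r}")
    net = nx.Graph()
    path = os.fspath(edges_path)
    is_sif = path.endswith(".sif")
    with open(path) as handle:
        lines = handle.readlines()
    start = 0
    if not is_sif:
        start = 1  # header: source  target  provenance
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split() if is_sif else line.rstrip("\n").split("\t")
        if is_sif:
            if len(fields) == 1:
                net.add_node(fields[0])
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed SIF row {line!r}")
            source, target = fields[0], fields[2]
            provenance = default_provenance
        else:
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: malformed TSV row {line!r}")
            source, target = fields[0], fields[1]
            provenance = fields[2] if len(fields) > 2 and fields[2] else default_provenance
        if provenance not in PROVENANCES:
            raise ValueError(f"{path}:{lineno}: unknown provenance {provenance!r}")
        if source == target:
            logger.warning("%s:%d: dropping self-loop on %s", path, lineno, source)
            net.add_node(source)
            continue
        if net.has_edge(source, target):
            if net.edges[source, target]["provenance"] == "predicted":
                net.edges[source, target]["provenance"] = provenance
        else:
            net.add_edge(source, target, provenance=provenance)

    annotations = load_annotations(annotations_path) if annotations_path else {}
    for node in net.nodes:
        record = annotations.get(node, {})
        net.nodes[node]["groups"] = record.get("groups", frozenset())
        net.nodes[node]["interpro"] = record.get("interpro", False)
        net.nodes[node]["dna_repair"] = record.get("dna_repair", False)
    return net


def write_network(net: nx.Graph, path: str | os.PathLike) -> None:
    """Write the edge list back as a provenance-annotated TSV."""
    with open(path, "w") as handle:
        handle.write("source\ttarget\tprovenance\n")
        for u, v, data in sorted(
            (tuple(sorted((u, v))) + (d,) for u, v, d in net.edges(data=True))
        ):
            handle.write(f"{u}\t{v}\t{data.get('provenance', 'experimental')}\n")


# ---------------------------------------------------------------------------
# filters

def shared_interactor_filter(net: nx.Graph, min_groups: int = 2) -> nx.Graph:
    """Keep homolog nodes plus interactors shared by >= min_groups groups."""
    keep = set()
    for node in net.nodes:
        if _is_homolog(net, node):
            keep.add(node)
            continue
        neighbour_groups = frozenset().union(
            *(_groups(net, nbr) for nbr in net.neighbors(node)),
        ) if net.degree(node) else frozenset()
        if len(neighbour_groups) >= min_groups:
            keep.add(node)
    out = net.subgraph(keep).copy()
    out.graph.update(net.graph)
    return out


def merge_networks(experimental: nx.Graph, predicted: nx.Graph) -> nx.Graph:
    """Union of two networks; experimental provenance wins on shared edges.

    Node annotations are unioned; a node flagged True in one network and
    False in the other keeps True for set-valued/boolean annotations, but a
    group assignment conflict (both non-empty and different) is an error.
    """
    merged = nx.Graph()
    merged.graph.update(experimental.graph)
    for net in (experimental, predicted):
        for node, data in net.nodes(data=True):
            if node not in merged:
                merged.add_node(node, **{k: v for k, v in data.items()})
                continue
            current = merged.nodes[node]
            incoming_groups = data.get("groups", frozenset())
            existing_groups = current.get("groups", frozenset())
            if (existing_groups and incoming_groups
                    and existing_groups != incoming_groups):
                raise ValueError(
                    f"contradictory group annotations for {node!r}: "
                    f"{sorted(existing_groups)} vs {sorted(incoming_groups)}"
                )
            current["groups"] = existing_groups | incoming_groups
            for flag in ("interpro", "dna_repair"):
                current[flag] = current.get(flag, False) or data.get(flag, False)
    for net in (experimental, predicted):
        for u, v, data in net.edges(data=True):
            provenance = data.get("provenance", "experimental")
            if merged.has_edge(u, v):
                if provenance == "experimental":
                    merged.edges[u, v]["provenance"] = "experimental"
            else:
                merged.add_edge(u, v, provenance=provenance)
    return merged


def _bridges_to_repair(net: nx.Graph, node: str, bait_group: str) -> bool:
    """Connector test: neighbours include the bait group and a repair-flagged
    homolog of another group."""
    has_bait_side = False
    has_repair_side = False
    for nbr in net.neighbors(node):
        groups = _groups(net, nbr)
        if bait_group in groups:
            has_bait_side = True
        if (groups - {bait_group}) and _is_repair(net, nbr):
            has_repair_side = True
    return has_bait_side and has_repair_side


def dna_repair_filter(net: nx.Graph, remove_baits: list[str] | tuple[str, ...] = (),
                      bait_group: str = "ETS") -> nx.Graph:
    """DNA-repair bridging filter with bait removal.

    After removing the bait nodes (the already-established partners), keeps

    (i)   every homolog-group node,
    (ii)  non-homolog connectors adjacent both to a bait-group homolog and
          to a DNA-repair-flagged homolog of another group,

    and finally prunes bait-group-only nodes whose connected component no
    longer reaches any BRCT/SAP homolog.
    """
    unknown = [b for b in remove_baits if b not in net]
    if unknown:
        raise KeyError(f"unknown bait id(s): {unknown}")
    work = net.copy()
    work.remove_nodes_from(remove_baits)

    keep = set()
    for node in work.nodes:
        if _is_homolog(work, node):
            keep.add(node)
        elif _bridges_to_repair(work, node, bait_group):
            keep.add(node)

    sub = work.subgraph(keep)
    partner_groups = set(GROUPS) - {bait_group}
    pruned = set(keep)
    for component in nx.connected_components(sub):
        if not any(_groups(sub, n) & partner_groups for n in component):
            pruned -= {
                n for n in component
                if _groups(sub, n) and not (_groups(sub, n) - {bait_group})
            }
    out = work.subgraph(pruned).copy()
    out.graph.update(net.graph)
    return out


def expression_overlay(net: nx.Graph,
                       table: str | os.PathLike | pd.DataFrame,
                       p_threshold: float = 0.01) -> nx.Graph:
    """Annotate nodes with differential expression at adjusted p <= threshold.

    ``table`` is a TSV (columns gene, log2fc, adj_p) or an equivalent
    DataFrame; multiple probes per gene resolve to the smallest adjusted p.
    Nodes failing the threshold carry no fold-change annotation.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    required = {"gene", "log2fc", "adj_p"}
    if not required <= set(table.columns):
        raise ValueError(f"expression table must have columns {sorted(required)}")
    table = table.copy()
    for column in ("log2fc", "adj_p"):
        table[column] = pd.to_numeric(table[column], errors="raise")
    best = table.loc[table.groupby("gene")["adj_p"].idxmin()]
    out = net.copy()
    for record in best.itertuples():
        if record.gene in out and record.adj_p <= p_threshold:
            out.nodes[record.gene]["log2fc"] = float(record.log2fc)
            out.nodes[record.gene]["adj_p"] = float(record.adj_p)
    return out


def candidate_report(net: nx.Graph, bait_group: str = "ETS") -> pd.DataFrame:
    """Candidate partner table over the filtered network.

    One row per BRCT/SAP homolog with an evidence class (mutually exclusive,
    assigned with precedence direct > bridge_via_connector >
    neighbour_of_bridge); homologs with no evidence are omitted.
    """
    partner_groups = set(GROUPS) - {bait_group}
    rows = []
    for node in net.nodes:
        groups = _groups(net, node)
        if not groups & partner_groups:
            continue
        evidence = None
        repair = _is_repair(net, node)
        neighbours = list(net.neighbors(node))
        if repair and any(bait_group in _groups(net, n) for n in neighbours):
            evidence = "direct"
        elif repair and any(
            not _is_homolog(net, n)
            and any(bait_group in _groups(net, m) for m in net.neighbors(n))
            for n in neighbours
        ):
            evidence = "bridge_via_connector"
        elif not repair and any(
            _is_repair(net, n)
            and any(bait_group in _groups(net, m) for m in net.neighbors(n))
            for n in neighbours
        ):
            evidence = "neighbour_of_bridge"
        if evidence is None:
            continue
        data = net.nodes[node]
        rows.append({
            "id": node,
            "groups": ";".join(sorted(groups & partner_groups)),
            "dna_repair": repair,
            "evidence": evidence,
            "log2fc": data.get("log2fc"),
            "adj_p": data.get("adj_p"),
        })
    rows.sort(key=lambda r: r["id"])
    return pd.DataFrame(
        rows, columns=["id", "groups", "dna_repair", "evidence", "log2fc", "adj_p"]
    )
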