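import networkx as nx
import pandas as pd
import pytest

from partner_scan.network_pipeline import (candidate_report, dna_repair_filter,
                                           expression_overlay, load_network,
                                           merge_networks,
                                           shared_interactor_filter,
                                           write_network)
from partner_scan.synthetic_data import make_network_scenario


def _net(edges, annotations, default_provenance="experimental"):
    """Build an annotated graph in memory; annotations: id -> (groups, repair)."""
    g = nx.Graph()
    for u, v, *rest in edges:
        g.add_edge(u, v, provenance=rest[0] if rest else default_provenance)
    for node in g.nodes:
        groups, repair = annotations.get(node, ((), False))
        g.nodes[node]["groups"] = frozenset(groups)
        g.nodes[node]["interpro"] = False
        g.nodes[node]["dna_repair"] = repair
    return g


def test_load_network_basic_and_duplicate_precedence(tmp_path):
    edges = tmp_path / "edges.tsv"
    edges.write_text(
        "source\ttarget\tprovenance\n"
        "A\tB\texperimental\n"
        "B\tC\tpredicted\n"
        "C\tA\tpredicted\n"
        "A\tB\tpredicted\n"    # duplicate: experimental must win
        "B\tA\texperimental\n"  # duplicate again, reversed orientation
    )
    net = load_network(edges)
    assert net.number_of_edges() == 3
    assert net.edges["A", "B"]["provenance"] == "experimental"
    assert net.edges["B", "C"]["provenance"] == "predicted"


def test_load_network_drops_self_loops_and_reports_bad_rows(tmp_path):
    edges = tmp_path / "loop.tsv"
    edges.write_text("source\ttarget\tprovenance\nA\tA\texperimental\nA\tB\texperimental\n")
    net = load_network(edges)
    assert net.number_of_edges() == 1 and "A" in net
    bad = tmp_path / "bad.tsv"
    bad.write_text("source\ttarget\tprovenance\nonlyonefield\n")
    with pytest.raises(ValueError, match=":2"):
        load_network(bad)


def test_load_network_sif_dialect(tmp_path):
    sif = tmp_path / "net.sif"
    sif.write_text("A pp B\nB pp C\nLONER\n")
    net = load_network(sif, default_provenance="predicted")
    assert set(net.nodes) == {"A", "B", "C", "LONER"}
    assert net.edges["A", "B"]["provenance"] == "predicted"


def test_shared_interactor_rule():
    ann = {"E1": ({"ETS"}, False), "E2": ({"ETS"}, False), "S1": ({"SAP"}, False)}
    net = _net([("X", "E1"), ("X", "S1"), ("Y", "E1"), ("Y", "E2")], ann)
    out = shared_interactor_filter(net)
    assert "X" in out          # bridges two groups
    assert "Y" not in out      # two homologs of a single group
    assert {"E1", "E2", "S1"} <= set(out.nodes)


def test_shared_interactor_never_drops_homologs_and_is_idempotent():
    ann = {"E1": ({"ETS"}, False), "B1": ({"BRCT"}, True)}
    net = _net([("E1", "X"), ("B1", "Y")], ann)
    once = shared_interactor_filter(net)
    assert {"E1", "B1"} <= set(once.nodes)
    twice = shared_interactor_filter(once)
    assert set(twice.nodes) == set(once.nodes)
    assert set(once.nodes) <= set(net.nodes)


def test_merge_disjoint_and_provenance_precedence():
    ann = {"A": ((), False), "B": ((), False), "C": ((), False)}
    experimental = _net([("A", "B", "experimental")], ann)
    predicted = _net([("B", "C", "predicted"), ("A", "B", "predicted")], ann)
    merged = merge_networks(experimental, predicted)
    assert merged.number_of_edges() == 2
    assert merged.edges["A", "B"]["provenance"] == "experimental"
    assert merged.edges["B", "C"]["provenance"] == "predicted"


def test_merge_contradictory_groups_raise():
    a = _net([("A", "B")], {"A": ({"ETS"}, False), "B": ((), False)})
    b = _net([("A", "C")], {"A": ({"SAP"}, False), "C": ((), False)})
    with pytest.raises(ValueError, match="contradictory"):
        merge_networks(a, b)


def test_repair_filter_direct_bridge_and_connector():
    ann = {
        "E1": ({"ETS"}, False),
        "B1": ({"BRCT"}, True),   # repair-flagged homolog, direct edge
        "S1": ({"SAP"}, True),    # repair-flagged homolog behind a connector
        "CONN": ((), False),
    }
    net = _net([("E1", "B1", "predicted"), ("E1", "CONN"), ("CONN", "S1")], ann)
    out = dna_repair_filter(net)
    assert set(out.nodes) == {"E1", "B1", "S1", "CONN"}
    report = candidate_report(out)
    evidence = dict(zip(report.id, report.evidence))
    assert evidence == {"B1": "direct", "S1": "bridge_via_connector"}


def test_repair_filter_removes_baits_and_unknown_bait_errors():
    ann = {"E1": ({"ETS"}, False), "P1": ({"BRCT"}, True), "B2": ({"BRCT"}, True)}
    net = _net([("E1", "P1"), ("E1", "B2")], ann)
    out = dna_repair_filter(net, remove_baits=("P1",))
    assert "P1" not in out and "B2" in out
    with pytest.raises(KeyError):
        dna_repair_filter(net, remove_baits=("NOPE",))


def test_repair_filter_prunes_disconnected_bait_group_nodes():
    ann = {"E1": ({"ETS"}, False), "E2": ({"ETS"}, False),
           "E3": ({"ETS"}, False), "B1": ({"BRCT"}, True)}
    net = _net([("E1", "B1", "predicted"), ("E2", "E3")], ann)
    out = dna_repair_filter(net)
    assert "E1" in out and "B1" in out
    assert "E2" not in out and "E3" not in out


def test_repair_filter_idempotent_and_subset(tmp_path):
    scenario = make_network_scenario("fig4", seed=0, out_dir=tmp_path)
    experimental = load_network(scenario.experimental_edges, scenario.annotations)
    predicted = load_network(scenario.predicted_edges, scenario.annotations,
                             default_provenance="predicted")
    merged = merge_networks(shared_interactor_filter(experimental),
                            shared_interactor_filter(predicted))
    once = dna_repair_filter(merged, remove_baits=scenario.baits)
    assert set(once.nodes) <= set(merged.nodes)
    twice = dna_repair_filter(once)
    assert set(twice.nodes) == set(once.nodes)
    assert not set(scenario.baits) & set(once.nodes)


def test_expression_overlay_thresholds_and_probe_precedence():
    ann = {"G1": ({"BRCT"}, True), "G2": ({"SAP"}, False), "G3": ((), False)}
    net = _net([("G1", "G2"), ("G2", "G3")], ann)
    table = pd.DataFrame({
        "gene": ["G1", "G2", "G3", "G3"],
        "log2fc": [-1.2, 0.8, 1.0, -2.0],
        "adj_p": [0.005, 0.02, 0.02, 0.001],
    })
    out = expression_overlay(net, table)
    assert out.nodes["G1"]["log2fc"] == pytest.approx(-1.2)
    assert "log2fc" not in out.nodes["G2"]          # above the 0.01 cut
    assert out.nodes["G3"]["log2fc"] == pytest.approx(-2.0)  # best probe wins


def test_expression_overlay_rejects_non_numeric():
    net = _net([("G1", "G2")], {})
    table = pd.DataFrame({"gene": ["G1"], "log2fc": ["high"], "adj_p": [0.001]})
    with pytest.raises((ValueError, TypeError)):
        expression_overlay(net, table)


def test_candidate_report_empty_and_multi_group():
    empty = nx.Graph()
    assert len(candidate_report(empty)) == 0
    ann = {"E1": ({"ETS"}, False), "DUAL": ({"BRCT", "SAP"}, True)}
    net = _net([("E1", "DUAL", "predicted")], ann)
    report = candidate_report(net)
    assert len(report) == 1
    assert report.iloc[0].groups == "BRCT;SAP"


def test_candidate_evidence_classes_are_exclusive_and_exhaustive(tmp_path):
    scenario = make_network_scenario("fig4", seed=5, out_dir=tmp_path)
    experimental = load_network(scenario.experimental_edges, scenario.annotations)
    predicted = load_network(scenario.predicted_edges, scenario.annotations,
                             default_provenance="predicted")
    net = dna_repair_filter(
        merge_networks(shared_interactor_filter(experimental),
                       shared_interactor_filter(predicted)),
        remove_baits=scenario.baits)
    report = candidate_report(net)
    assert report.evidence.isin(
        ["direct", "bridge_via_connector", "neighbour_of_bridge"]).all()
    assert report.id.is_unique


def test_write_network_round_trip(tmp_path):
    ann = {"A": ({"ETS"}, False), "B": ({"BRCT"}, True)}
    net = _net([("A", "B", "predicted"), ("B", "C", "experimental")], ann)
    path = tmp_path / "net.tsv"
    write_network(net, path)
    back = load_network(path)
    assert set(back.edges) == set(net.edges)
    assert back.edges["A", "B"]["provenance"] == "predicted"
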