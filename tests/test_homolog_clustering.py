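import pytest

from partner_scan.homolog_clustering import (DomainSequence, SequenceCluster,
                                             StructureMeta, cluster_sequences,
                                             pairwise_identity, read_fasta,
                                             read_structure_meta,
                                             select_representative,
                                             write_clusters, write_fasta)
from partner_scan.synthetic_data import make_toy_sequences

from oracles import needleman_wunsch_identity


@pytest.mark.parametrize("a,b,expected", [
    ("ACDEF", "ACDEF", 100.0),
    ("AAAA", "AAAT", 75.0),
    ("ACDEFGHIK", "ACDEFGHIKLMNP", 100.0),  # shorter fully contained
])
def test_pairwise_identity_examples(a, b, expected):
    assert pairwise_identity(a, b) == pytest.approx(expected)
    assert needleman_wunsch_identity(a, b) == pytest.approx(expected)


def test_pairwise_identity_symmetric_and_validated():
    assert pairwise_identity("MKV", "MKVLL") == pairwise_identity("MKVLL", "MKV")
    with pytest.raises(ValueError):
        pairwise_identity("", "MKV")
    with pytest.raises(ValueError):
        DomainSequence(id="bad", sequence="MKZ123")


def _seqs(pairs):
    return [DomainSequence(id=i, sequence=s) for i, s in pairs]


def test_two_identical_plus_unrelated_gives_two_clusters():
    seqs = _seqs([("a", "MKVLWAALLG"), ("b", "MKVLWAALLG"), ("c", "GGGPPPSTTT")])
    clusters = cluster_sequences(seqs, threshold=95)
    assert len(clusters) == 2
    memberships = sorted(sorted(c.members) for c in clusters)
    assert memberships == [["a", "b"], ["c"]]


def test_threshold_100_on_distinct_sequences_gives_singletons():
    seqs = _seqs([("a", "MKVLWAALLG"), ("b", "MKVLWAALLA"), ("c", "MKVLWAALLS")])
    assert len(cluster_sequences(seqs, threshold=100)) == 3


def test_planted_partition_recovered():
    seqs, partition = make_toy_sequences(3, within_identity=98,
                                         between_identity=40, seed=7)
    clusters = cluster_sequences(seqs, threshold=95)
    assert len(clusters) == 3
    got = {frozenset(c.members) for c in clusters}
    planted: dict[int, set] = {}
    for seq_id, c in partition.items():
        planted.setdefault(c, set()).add(seq_id)
    assert got == {frozenset(v) for v in planted.values()}


def test_cluster_partition_properties():
    seqs, _ = make_toy_sequences(4, within_identity=97, between_identity=55,
                                 n_members=3, seed=13)
    at95 = cluster_sequences(seqs, threshold=95)
    at80 = cluster_sequences(seqs, threshold=80)
    # clusters partition the input
    members95 = [m for c in at95 for m in c.members]
    assert sorted(members95) == sorted(s.id for s in seqs)
    assert len(set(members95)) == len(members95)
    # centroid belongs to its cluster, members meet the threshold
    for c in at95:
        assert c.centroid in c.members
        assert all(v >= 95 for v in c.identities.values())
    # lowering the threshold cannot increase the cluster count
    assert len(at80) <= len(at95)


def _meta(pdb_id, method, resolution=None, start=331, end=415, organism="Homo sapiens"):
    return StructureMeta(pdb_id=pdb_id, organism=organism, start=start,
                         end=end, method=method, resolution=resolution)


def test_representative_full_coverage_beats_partial():
    cluster = SequenceCluster(centroid="x", members=["x"])
    best = select_representative(cluster, [
        _meta("FULL", "x-ray", 2.0),
        _meta("PART", "x-ray", 1.5, start=340, end=400),
    ], (331, 415))
    assert best.pdb_id == "FULL"


def test_representative_lowest_resolution_wins():
    cluster = SequenceCluster(centroid="x", members=["x"])
    best = select_representative(cluster, [
        _meta("HI", "x-ray", 2.5), _meta("LO", "x-ray", 1.8),
    ], (331, 415))
    assert best.pdb_id == "LO"


def test_representative_nmr_only_when_no_xray():
    cluster = SequenceCluster(centroid="x", members=["x"])
    only_nmr = select_representative(cluster, [_meta("NMR1", "nmr")], (331, 415))
    assert only_nmr.pdb_id == "NMR1"
    with_xray = select_representative(cluster, [
        _meta("NMR1", "nmr"),
        _meta("XR", "x-ray", 2.8, start=340, end=400),
    ], (331, 415))
    assert with_xray.pdb_id == "XR"


def test_representative_human_only_or_none():
    cluster = SequenceCluster(centroid="x", members=["x"])
    assert select_representative(cluster, [], (331, 415)) is None
    mouse = _meta("MOUSE", "x-ray", 1.0, organism="Mus musculus")
    assert select_representative(cluster, [mouse], (331, 415)) is None


def test_fasta_and_meta_round_trip(tmp_path):
    seqs, _ = make_toy_sequences(2, n_members=2, seed=3)
    fasta = tmp_path / "seqs.fasta"
    write_fasta(seqs, fasta)
    back = read_fasta(fasta)
    assert [(s.id, s.sequence) for s in back] == [(s.id, s.sequence) for s in seqs]

    meta_path = tmp_path / "meta.tsv"
    meta_path.write_text(
        "pdb_id\torganism\tstart\tend\tmethod\tresolution\n"
        "1GVJ\tHomo sapiens\t331\t415\tx-ray\t1.75\n"
        "2NMR\tHomo sapiens\t331\t415\tnmr\t\n"
    )
    meta = read_structure_meta(meta_path)
    assert meta[0].resolution == pytest.approx(1.75)
    assert meta[1].resolution is None

    clusters = cluster_sequences(back, threshold=95)
    out = tmp_path / "clusters.tsv"
    write_clusters(clusters, out)
    lines = out.read_text().splitlines()
    assert lines[0].startswith("cluster_id\t")
    assert len(lines) == 1 + len(back)
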