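"""Homolog sequence clustering and representative-structure selection.

Domain homologs are grouped by greedy centroid clustering at a pairwise
identity threshold (default 95%), in the UCLUST style: sequences are
processed by decreasing length (ties broken lexicographically by id), each
one joining the first existing cluster whose centroid it matches at or above
the threshold, or founding a new cluster otherwise.

Pairwise identity is computed from a global alignment (match +1, mismatch 0,
affine internal gaps, free end gaps) as the number of identical aligned
positions divided by the length of the shorter sequence.  The shorter-
sequence denominator means a sequence fully contained in a longer one scores
100%.

Each cluster may be assigned one representative experimental structure from
a metadata table.  Only human entries are considered; crystallographic
structures take precedence over NMR ones, and within a method full coverage
of the domain window beats partial coverage, then (X-ray) the lowest
resolution value wins.  "Best validation criteria" is operationalized as
lowest resolution, the only criterion universally available in such tables.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Align import PairwiseAligner

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")
IDENTITY_THRESHOLD_DEFAULT = 95.0


@dataclass(frozen=True)
class DomainSequence:
    id: str
    sequence: str
    source_domain: str | None = None
    organism: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.sequence.upper()) - AMINO_ACIDS
        if bad:
            raise ValueError(f"sequence {self.id!r} has invalid letters {sorted(bad)}")


@dataclass(frozen=True)
class StructureMeta:
    pdb_id: str
    organism: str
    start: int
    end: int
    method: str  # "x-ray" | "nmr"
    resolution: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.pdb_id}: malformed coverage range")

    def covers(self, domain_range: tuple[int, int]) -> bool:
        return self.start <= domain_range[0] and self.end >= domain_range[1]


@dataclass
class SequenceCluster:
    centroid: str
    members: list[str] = field(default_factory=list)
    identities: dict[str, float] = field(default_factory=dict)
    representative: StructureMeta | None = None


def _make_aligner(match: float = 1.0, mismatch: float = 0.0,
                  gap_open: float = -5.0, gap_extend: float = -0.5) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps: a domain fully contained in a longer homolog aligns
    # without penalty for the overhang
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: DomainSequence | str, b: DomainSequence | str) -> float:
    """Percent identity of two sequences over the shorter sequence length."""
    seq_a = a.sequence if isinstance(a, DomainSequence) else a
    seq_b = b.sequence if isinstance(b, DomainSequence) else b
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    if seq_a == seq_b:
        return 100.0
    alignment = _ALIGNER.align(seq_a.upper(), seq_b.upper())[0]
    identities = alignment.counts().identities
    return 100.0 * identities / min(len(seq_a), len(seq_b))


def cluster_sequences(seqs: list[DomainSequence],
                      threshold: float = IDENTITY_THRESHOLD_DEFAULT,
                      ) -> list[SequenceCluster]:
    """Greedy centroid clustering at a percent-identity threshold.

    Deterministic: sequences are visited by decreasing length, ties broken
    by id; a sequence joins the earliest-founded cluster whose centroid it
    matches at >= threshold.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    by_id = {s.id: s for s in seqs}
    order = sorted(seqs, key=lambda s: (-len(s.sequence), s.id))
    clusters: list[SequenceCluster] = []
    for seq in order:
        for cluster in clusters:
            identity = pairwise_identity(seq, by_id[cluster.centroid])
            if identity >= threshold:
                cluster.members.append(seq.id)
                cluster.identities[seq.id] = identity
                break
        else:
            clusters.append(SequenceCluster(
                centroid=seq.id, members=[seq.id], identities={seq.id: 100.0},
            ))
    return clusters


def select_representative(cluster: SequenceCluster,
                          meta: list[StructureMeta],
                          domain_range: tuple[int, int],
                          ) -> StructureMeta | None:
    """Pick the representative structure of a cluster, or None.

    Human structures only; X-ray precedes NMR; within a method, full
    coverage of ``domain_range`` precedes partial, then lowest resolution
    (X-ray), with the PDB id as the final deterministic tie-break.
    """
    human = [m for m in meta if m.organism.strip().lower() == "homo sapiens"]
    if not human:
        cluster.representative = None
        return None

    def rank(m: StructureMeta) -> tuple:
        is_nmr = m.method.strip().lower().startswith("nmr")
        resolution = m.resolution if m.resolution is not None else float("inf")
        return (is_nmr, not m.covers(domain_range), resolution, m.pdb_id)

    best = min(human, key=rank)
    cluster.representative = best
    return best


# ---------------------------------------------------------------------------
# file formats

def read_fasta(path: str | os.PathLike,
               source_domain: str | None = None) -> list[DomainSequence]:
    records = list(SeqIO.parse(os.fspath(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [
        DomainSequence(id=r.id, sequence=str(r.seq), source_domain=source_domain)
        for r in records
    ]


def write_fasta(seqs: list[DomainSequence], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for s in seqs:
            handle.write(f">{s.id}\n{s.sequence}\n")


def read_structure_meta(path: str | os.PathLike) -> list[StructureMeta]:
    """Read a structure-metadata TSV: pdb_id, organism, start, end, method, resolution."""
    rows: list[StructureMeta] = []
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for record in reader:
            resolution = record.get("resolution", "")
            rows.append(StructureMeta(
                pdb_id=record["pdb_id"],
                organism=record["organism"],
                start=int(record["start"]),
                end=int(record["end"]),
                method=record["method"],
                resolution=float(resolution) if resolution not in ("", None) else None,
            ))
    return rows


def write_clusters(clusters: list[SequenceCluster], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("cluster_id\tcentroid\tmember\tidentity_to_centroid\trepresentative\n")
        for i, cluster in enumerate(clusters):
            rep = cluster.representative.pdb_id if cluster.representative else ""
            for member in cluster.members:
                identity = cluster.identities.get(member, float("nan"))
                handle.write(f"{i}\t{cluster.centroid}\t{member}\t{identity:.2f}\t{rep}\n")
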