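"""End-to-end orchestration: configuration, stages, manifest.

``run_pipeline`` chains the library stages over files on disk: homolog
clustering (FASTA in, clusters TSV out), per-pose RIN/centrality analysis of
a directory of docked-pose PDBs, ensemble aggregation, and the PPI filter
cascade with optional expression overlay.  Docking itself is an external
boundary — the pipeline consumes whatever pose PDBs are supplied (one pose
per docking run, e.g. the first model of the top cluster).

Every run writes a ``manifest.json`` recording the configuration, SHA-256
checksums of all inputs, per-stage counts and the package version, plus a
re-runnable ``config.txt``.  For fixed inputs and configuration all TSV
outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass

from . import __version__
from .homolog_clustering import (cluster_sequences, read_fasta,
                                 read_structure_meta, select_representative,
                                 write_clusters)
from .interface_analysis import aggregate_ensemble, analyze_pose
from .network_pipeline import (candidate_report, dna_repair_filter,
                               expression_overlay, load_network,
                               merge_networks, shared_interactor_filter,
                               write_network)
from .structure_io import read_pdb

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending file."""

    def __init__(self, stage: str, message: str, path: str | None = None):
        self.stage = stage
        self.path = path
        where = f" ({path})" if path else ""
        super().__init__(f"stage {stage!r} failed{where}: {message}")


@dataclass
class RunConfig:
    """Parameter constellation of a full run.

    Defaults carry the pipeline's standard thresholds: contact band
    2.5–5.0 Å, centrality Z >= 2, residues reported when central at the
    interface at least twice, 95% clustering identity, expression cut at
    adjusted p <= 0.01.
    """

    out_dir: str
    d_min: float = 2.5
    d_max: float = 5.0
    z_threshold: float = 2.0
    min_count: int = 2
    identity_threshold: float = 95.0
    p_threshold: float = 0.01
    bait_chain: str = "A"
    partner_chain: str = "B"
    bait_ids: tuple[str, ...] = ()
    domain_start: int | None = None
    domain_end: int | None = None
    fasta: str | None = None
    structure_meta: str | None = None
    poses_dir: str | None = None
    experimental_edges: str | None = None
    predicted_edges: str | None = None
    annotations: str | None = None
    expression: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.d_min > self.d_max:
            raise ValueError(f"d_min ({self.d_min}) must be <= d_max ({self.d_max})")
        if self.d_min < 0:
            raise ValueError("d_min must be non-negative")
        if self.min_count < 0:
            raise ValueError("min_count must be non-negative")
        if not 0 < self.identity_threshold <= 100:
            raise ValueError("identity_threshold must be in (0, 100]")
        if not 0 <= self.p_threshold <= 1:
            raise ValueError("p_threshold must be in [0, 1]")
        if (self.domain_start is None) != (self.domain_end is None):
            raise ValueError("domain_start and domain_end must be set together")

    # -- plain key = value serialisation ------------------------------------

    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as handle:
            for f in dataclasses.fields(self):
                value = getattr(self, f.name)
                if value is None:
                    continue
                if isinstance(value, tuple):
                    value = ",".join(value)
                handle.write(f"{f.name} = {value}\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        values: dict = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, _, raw = line.partition("=")
                key = key.strip()
                raw = raw.strip()
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                hint = fields[key].type
                if key == "bait_ids":
                    values[key] = tuple(x for x in raw.split(",") if x)
                elif "int" in hint:
                    values[key] = int(raw)
                elif "float" in hint:
                    values[key] = float(raw)
                else:
                    values[key] = raw
        return cls(**values)


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> str:
    """Execute all configured stages; returns the run directory."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if v is not None},
        "inputs": {},
        "stages": [],
    }
    outputs: dict[str, str] = {}

    def record_input(path: str | None) -> None:
        if path and os.path.isfile(path):
            manifest["inputs"][path] = _sha256(path)

    for path in (config.fasta, config.structure_meta, config.experimental_edges,
                 config.predicted_edges, config.annotations, config.expression):
        record_input(path)

    def stage(name: str, fn, path: str | None = None):
        started = time.monotonic()
        try:
            counts = fn() or {}
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise PipelineError(name, str(exc), path) from exc
        manifest["stages"].append({
            "stage": name,
            "seconds": round(time.monotonic() - started, 3),
            **counts,
        })
        logger.info("stage %s done: %s", name, counts)

    # -- clustering ---------------------------------------------------------
    if config.fasta:
        def do_cluster():
            seqs = read_fasta(config.fasta)
            clusters = cluster_sequences(seqs, threshold=config.identity_threshold)
            if config.structure_meta and config.domain_start is not None:
                meta = read_structure_meta(config.structure_meta)
                for cluster in clusters:
                    select_representative(
                        cluster, meta, (config.domain_start, config.domain_end))
            out = os.path.join(config.out_dir, "clusters.tsv")
            write_clusters(clusters, out)
            outputs["clusters"] = out
            return {"n_sequences": len(seqs), "n_clusters": len(clusters)}
        stage("cluster", do_cluster, config.fasta)

    # -- per-pose analysis + ensemble ---------------------------------------
    if config.poses_dir:
        def do_ensemble():
            pose_paths = sorted(glob.glob(os.path.join(config.poses_dir, "*.pdb")))
            if not pose_paths:
                raise FileNotFoundError(f"no pose PDBs in {config.poses_dir}")
            reports = []
            for path in pose_paths:
                record_input(path)
                structure = read_pdb(path)
                reports.append(analyze_pose(
                    structure, config.bait_chain, config.partner_chain,
                    d_min=config.d_min, d_max=config.d_max,
                    z_threshold=config.z_threshold,
                ))
            table = aggregate_ensemble(reports, min_count=config.min_count)
            out = os.path.join(config.out_dir, "ensemble.tsv")
            table.to_csv(out, sep="\t", index=False)
            outputs["ensemble"] = out
            return {"n_poses": len(reports), "n_rows": len(table)}
        stage("ensemble", do_ensemble, config.poses_dir)

    # -- network cascade ----------------------------------------------------
    if config.experimental_edges:
        def do_network():
            experimental = load_network(
                config.experimental_edges, config.annotations,
                default_provenance="experimental")
            net = shared_interactor_filter(experimental)
            if config.predicted_edges:
                predicted = load_network(
                    config.predicted_edges, config.annotations,
                    default_provenance="predicted")
                net = merge_networks(net, shared_interactor_filter(predicted))
            net = dna_repair_filter(net, remove_baits=config.bait_ids)
            if config.expression:
                net = expression_overlay(net, config.expression,
                                         p_threshold=config.p_threshold)
            report = candidate_report(net)
            net_out = os.path.join(config.out_dir, "filtered_network.tsv")
            write_network(net, net_out)
            report_out = os.path.join(config.out_dir, "candidates.tsv")
            report.to_csv(report_out, sep="\t", index=False)
            outputs["network"] = net_out
            outputs["candidates"] = report_out
            return {"n_nodes": net.number_of_nodes(),
                    "n_edges": net.number_of_edges(),
                    "n_candidates": len(report)}
        stage("netfilter", do_network, config.experimental_edges)

    config.to_file(os.path.join(config.out_dir, "config.txt"))
    manifest["outputs"] = {k: _sha256(v) for k, v in outputs.items()}
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return config.out_dir
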