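# partner-scan

Post-docking analysis for nominating candidate binding partners of a bait
protein domain: residue interaction networks, betweenness-centrality hub
detection, docking-pose interface statistics, homolog sequence clustering,
and a rule-based protein–protein interaction (PPI) filter cascade focused on
DNA-repair-associated partners.

## The problem

Suppose a transcription-factor domain (the bait — think of the DNA-binding
ETS domain of an oncoprotein) is known to bind two different domains of two
DNA-repair enzymes (a BRCT domain, a SAP domain). Could it also bind other
proteins carrying homologous domains? `partner-scan` implements the desk
side of that question:

1. **Homologs.** Cluster the bait's and the candidates' domain homologs at
   ≥ 95% pairwise sequence identity (greedy centroid clustering, UCLUST
   style) and pick one representative experimental structure per cluster
   (human; X-ray before NMR; full domain coverage before partial; then best
   resolution).
2. **PPI evidence.** Assemble experimentally curated and predicted
   interaction networks over the homolog groups, keep interactors shared by
   at least two groups, merge the two networks (experimental provenance
   wins), remove the already-known partners, and keep the proteins that
   connect the bait's homolog group to DNA-repair-flagged homologs of the
   candidate groups — directly, through a bridging connector, or as
   neighbours of a repair-flagged bridge. Differential-expression results
   can be overlaid (adjusted p ≤ 0.01).
3. **Structural plausibility.** For each docked bait–candidate pose, build
   the residue interaction network (RIN): residues are nodes, and two
   residues are in contact when any of their atom pairs lies within
   2.5–5.0 Å. Compute shortest-path betweenness centrality b_i for every
   residue, normalize within the network, z_i = (b_i − mean b)/sd(b), and
   call residues with z ≥ 2 *central*. Intersect central residues with the
   interface (bait residues contacting the partner chain) and count, over
   the whole pose ensemble, how often each bait residue is at the interface
   (`nb_interface`) and central there (`nb_central`). Residues central at
   the interface in at least two poses are reported — a consistent hot spot
   across unrelated candidate partners is evidence for a conserved binding
   mode.

Everything is testable without external services: the `synthetic_data`
module generates docked complexes with designed contact maps and an
engineered high-betweenness interface residue, PPI networks with planted
filter outcomes, sequence families with planted cluster structure, and
expression tables with planted significant genes.

## Worked example

```bash
partner-scan simulate hub --seed 3 --out sim
partner-scan rin --pdb sim/hub_complex_seed3.pdb --out hub.sif
# 9 residues, 8 contacts -> hub.sif
partner-scan rca --pdb sim/hub_complex_seed3.pdb --out rca.tsv
# 1 central residue(s) -> rca.tsv
```

`rca.tsv` (abridged):

```
chain  seq_number  residue  betweenness  z_score     is_central
A      1           Trp1     25.0          2.3166606  True
A      2           Ala2      0.0         -0.5631661  False
B      1           Gly1     12.0          0.8191507  False
B      2           Gly2      7.0          0.2431854  False
```

The engineered hub (chain A, residue 1) funnels all shortest paths between
the two residue clusters of the complex: betweenness 25 over this 9-residue
network, Z = 2.32 ≥ 2, hence the single central call — and it carries the
only inter-chain contact, so it is a central interface residue.

The network cascade on a simulated scenario:

```bash
partner-scan simulate network --seed 1 --scenario fig4 --out net
partner-scan netfilter --edges net/fig4_experimental.tsv \
    --predicted net/fig4_predicted.tsv --annot net/fig4_annotations.tsv \
    --remove PARP1,KU70 --out candidates.tsv
# 14 candidate(s) -> candidates.tsv
```

`candidates.tsv` lists each surviving BRCT/SAP homolog with its evidence
class — `direct` (repair-flagged, directly linked to the bait group),
`bridge_via_connector`, or `neighbour_of_bridge` — exactly the 14 partners
planted by the generator, with the 6 planted decoys excluded.

A full run (clustering + pose ensemble + network cascade) is driven by a
plain key–value config file: `partner-scan run --config run.cfg`. Each run
directory contains the outputs, the config, and a `manifest.json` with
input checksums; reruns are byte-identical.

## Layout

- `src/partner_scan/structure_io.py` — PDB reading/writing, domain extraction
- `src/partner_scan/rin_builder.py` — distance-band residue interaction networks
- `src/partner_scan/centrality.py` — betweenness Z-scores, central-residue calls
- `src/partner_scan/interface_analysis.py` — interface detection, pose ensembles
- `src/partner_scan/homolog_clustering.py` — identity clustering, representatives
- `src/partner_scan/network_pipeline.py` — PPI loading, filters, candidate report
- `src/partner_scan/synthetic_data.py` — seeded generators for all fixtures
- `src/partner_scan/pipeline.py`, `cli.py` — orchestration and `partner-scan` CLI

See `docs/methods.md` for the model, parameter and design details.
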