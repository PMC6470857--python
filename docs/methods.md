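# Methods

## Residue interaction networks

A RIN is built over all residues of a structure (both chains of a docked
complex pooled). Two residues are connected when **at least one** of their
atom pairs has a distance inside the closed band **[2.5 Å, 5.0 Å]**. Points
worth stating explicitly:

- The band is read inclusively on both ends; boundary behaviour is tested.
- The rule is existential *inside* the band: a residue pair with a clashing
  sub-2.5 Å atom pair still qualifies if another atom pair falls in band.
  The lower bound therefore removes pairs whose *only* proximity is a clash
  or covalent bond, not pairs that also touch at van der Waals range.
- Sequence neighbours (i, i+1) are **not** excluded; an optional
  `min_seq_separation` flag exists for sensitivity analyses.
- Hydrogens and hetero groups: waters are always dropped; other hetero
  groups are dropped by default (`include_hetero=True` keeps them);
  hydrogens present in a file are used as ordinary atoms. Crystal
  structures typically carry no hydrogens, so this is documented behaviour
  rather than a normalization step.
- Alternate locations resolve to the highest-occupancy conformer (ties:
  first in file), giving a deterministic single-conformer graph.
- Contacts are found with a k-d tree over all atoms (query radius `d_max`,
  then an exact `>= d_min` check in double precision). The accelerator is
  required — and tested — to agree exactly with an exhaustive O(atoms²)
  scan; it is an implementation detail, not an approximation.

## Residue centrality analysis

Betweenness centrality is computed on the unweighted, undirected RIN with
the Brandes conventions: endpoints excluded, equally short paths split
fractionally, pairs counted within connected components only. Scores are
Z-normalized over **all** nodes of the complex's network with the sample
(n−1) standard deviation, and a residue is *central* when z ≥ 2.

- Pooling both chains into one Z-score population is the default; a
  `per_chain` mode normalizes within chains instead. The choice matters
  little in practice because the Z-transform is invariant under positive
  affine rescaling of raw betweenness — normalized and unnormalized
  betweenness yield identical central sets (property-tested).
- Degenerate case sd = 0 (for example a ring or complete graph): all
  Z-scores are defined as 0, no residue is central, and a warning is
  logged. A single-node network is an error — a Z-score is meaningless.

## Interface detection and ensemble statistic

A bait residue is at the interface of a pose when it has a RIN edge to a
partner-chain residue; interface membership thus reuses the single contact
definition rather than introducing a second (buried-surface) criterion.
Per pose the analysis reports interface residues, central residues and
their intersection. Over an ensemble of poses (one pose per docking run
against a different partner), each bait residue accumulates
`nb_interface` — poses where it is at the interface — and `nb_central` —
poses where it is central **and** at the interface. Counting centrality
only at the interface enforces `nb_central ≤ nb_interface ≤ n_poses` by
construction. Rows with `nb_central ≥ 2` are reported (configurable),
sorted by `nb_central`, then `nb_interface`, then residue number.

## Homolog clustering and representatives

Pairwise identity comes from a global alignment with match +1, mismatch 0,
affine internal gaps (open −5, extend −0.5) and free end gaps, as the
number of identical aligned positions divided by the **shorter** sequence
length — so a domain fully contained in a longer homolog scores 100%. The
denominator convention follows greedy centroid clusterers; it is
configurable in spirit (the function is small and explicit) and its choice
is the main reason identity values here can differ from tools that divide
by alignment length.

Clustering is greedy: sequences sorted by decreasing length (ties by id),
each joining the first cluster whose **centroid** it matches at ≥ 95%, else
founding a new cluster. This is deterministic and order-stable; like all
greedy centroid schemes it can split borderline families that
average-linkage would merge, which is acceptable at the 95% threshold used.

Representative structures per cluster: human entries only; crystallographic
structures take precedence over NMR (NMR is used only when no X-ray entry
exists); within a method, full coverage of the domain window beats partial;
among X-ray entries the lowest resolution value wins; PDB id breaks the
final ties. "Best validation criteria" is operationalized as resolution —
the one criterion universally present in metadata tables.

## PPI filter cascade

Networks are undirected graphs with node annotations (homolog groups ⊆
{ETS, BRCT, SAP}, a domain-annotation flag, a DNA-repair flag) and an edge
provenance (`experimental` or `predicted`). DNA-repair status is an input
column (in practice GO:0006281 membership); enrichment analysis is
upstream of this package. Loading collapses duplicate edges (experimental
wins) and drops self-loops.

- **Shared-interactor filter**: homolog nodes always survive; any other
  node survives only with neighbours in ≥ 2 distinct homolog groups.
- **Merge**: node and annotation union, edge union; a shared edge keeps
  experimental provenance; group assignments that genuinely conflict raise.
- **DNA-repair filter**: the known bait partners are removed first; then
  the kept set is (i) all homolog nodes and (ii) connector nodes adjacent
  both to a bait-group (ETS) homolog and to a repair-flagged BRCT/SAP
  homolog. A connector's own repair flag is not required to be false: a
  repair-involved protein that bridges is at least as informative as a
  non-repair one, and the retained-network reading ("proteins connecting an
  ETS homolog to a BRCT/SAP homolog") includes it. Finally, ETS-group-only
  nodes whose component reaches no BRCT/SAP homolog are pruned.
- **Candidate report**: one row per BRCT/SAP homolog with a mutually
  exclusive evidence class, assigned with precedence
  `direct` (repair-flagged, direct edge to an ETS-group node) >
  `bridge_via_connector` (repair-flagged, reached through a kept
  non-homolog connector) > `neighbour_of_bridge` (not repair-flagged, but
  adjacent to a repair-flagged protein that itself links to the ETS
  group). A non-repair homolog whose only evidence is a direct edge to the
  ETS group is deliberately *not* a candidate: the cascade nominates
  repair-associated partners, and such a node carries no repair signal of
  its own or from a bridge. The "neighbour of bridge" rule requires the
  repair-flagged intermediary to touch the ETS group directly; a looser
  reading (intermediary merely kept) would admit second-order neighbours
  with no path of repair evidence to the bait.
- **Expression overlay**: genes with adjusted p ≤ 0.01 annotate their nodes
  with log2 fold-change; with several probes per gene the smallest adjusted
  p wins; everything else stays unannotated (grey in a viewer).

## Synthetic data: what it emulates, what it does not

Generators are seeded (`numpy.random.default_rng`), have no global state,
and emit the exact file dialects the pipeline reads.

- **Toy complexes** place two straight pseudo-atom chains (2–3 atoms per
  residue, consecutive residues 4.8 Å apart) 40 Å apart and realise each
  designed inter-chain contact with a long-arm atom 4.5 Å from the bait
  residue. Non-designed inter-chain pairs stay > 6 Å apart — a margin above
  the band — and the ±0.05 Å per-coordinate jitter cannot move any pair
  across a boundary, so the contact graph is exactly the designed one for
  every seed (verified against the exhaustive scan, not assumed).
- **Hub complexes** realise a star of five satellites around a hub residue
  plus a three-residue partner arm contacting only the hub. The hub is the
  sole articulation point joining the satellite cluster to the partner arm;
  with betweenness values (25, 12, 7, 0, …) over nine residues its Z-score
  is 2.32 ≥ 2 and maximal, and it is the only interface residue — the
  ground truth is provable from the graph, for every seed.
- **Network scenarios** plant the cascade topologies: shared connectors vs
  single-group decoys; duplicated experimental/predicted edges; and a full
  DNA-repair scenario with 14 qualifying candidates (5 + 1 direct, 1 via a
  connector, 7 neighbours of bridges) and 6 decoys each violating one rule
  (single-group connectors, bridges to non-repair targets, connectors
  without a bait-side edge, disconnected bait-group nodes, repair homologs
  without bait evidence, non-repair homologs with only a direct edge). The
  seed permutes file row order only; the topology and hence the hand-derived
  ground truth are fixed.
- **Sequence families**: cluster founders differ at (100 − between)% of
  positions; members mutate their founder at half of (100 − within)%, so
  member–member identity within a cluster stays within ~2 points of the
  nominal value. Substitution-only mutations keep lengths equal, which
  keeps the identity denominator trivial.
- **Expression tables**: planted significant genes get adjusted p ≤ 0.01
  and |log2FC| ≥ 1; all others p > 0.05.

What passing these tests shows: the algorithms implement their definitions
exactly and recover engineered ground truth under clean conditions. What it
does not show: performance on real docked poses (no physical geometry, no
near-boundary contact ambiguity), on real interaction databases (no
identifier mismatches, no annotation noise) or on real sequence families
(no indels, no domain-boundary uncertainty).

## Numerical and scale choices

- Distances in double precision; edge cases at exactly 2.5/5.0 Å are exact
  for constructed fixtures and measure-zero for random ones.
- Oracle checks use 100 random structures (≤ 50 residues) for contacts and
  200 random connected graphs (≤ 8 nodes) for betweenness; hub and
  clustering recovery use 20 seeds; the ensemble statistic 10 poses. These
  sizes exercise every code path while keeping the whole suite near two
  seconds.
- All TSV outputs are sorted on stable keys, so identical inputs give
  byte-identical outputs; the run manifest records input checksums.

## Known limitations

- PDB only (no mmCIF); single-model analysis of multi-model files.
- Identity denominator and greedy order are conventions, not ground truth;
  families near the 95% threshold can be split differently by other tools.
- The candidate evidence classes encode one defensible reading of the
  bridging rules; alternative readings (e.g. requiring connectors to be
  non-repair, or allowing indirect bridges) would change borderline nodes.
- Edge types (hydrogen bonds, salt bridges) and weighted RINs are out of
  scope, as are docking itself, homology search, GO enrichment and
  differential-expression testing — the pipeline consumes their outputs.
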