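# Methods

## Structure model and preparation

Input files (mmCIF preferred, legacy PDB accepted) are read with gemmi into
a minimal chain/residue/atom model. Author-assigned chain identifiers are
kept verbatim so graph vertices match deposition labels. Only the first
model of multi-model files is used; coordinates are taken as deposited (no
symmetry expansion — the intended inputs are biological-assembly files).
Alternate locations are resolved per atom name to the conformer with the
highest occupancy, ties to the lexicographically smallest altloc code —
deterministic and standard practice. Hydrogens are kept if present.

Residues are classified by chemical-component identity: waters
(HOH/DOD/WAT) are solvent and never enter any computation; amino acids
(standard or modified) are polymer; everything else is a ligand attached to
its author chain. A chain is a polypeptide — and thus a graph vertex — when
it has amino-acid residues and more than half of them are standard amino
acids (robust to modified residues). Detached ligand-only chains are dropped
from the vertex set with a warning; nucleic-acid chains are not treated as
vertices.

## Contact model

Atoms are spheres: 2.0 Å radius for atoms of polymer residues, 3.0 Å for
ligand atoms (`ContactParameters`, overridable). Two atoms are in contact
when their centre distance is at most the radius sum. The boundary case
counts as contact: deposited coordinates carry three decimals, so an
inclusive comparison is the only reproducible convention at tangency. Radii
are per residue class, not per element — no van-der-Waals table.

Two residues of different chains are in contact when at least one atom pair
is; a chain pair's count is the number of distinct residue pairs in contact,
counted once per residue pair regardless of how many atom pairs overlap.
Intra-chain pairs are never counted (no self-loops), including
polymer–ligand pairs sharing one chain id. Ligand residues attached to a
vertex chain contribute their contacts to that chain's counts; the
`exclude_ligands` flag (CLI `--exclude-ligands`) disables this.

The production path bins atoms into a uniform grid with cell edge
2·max(r_protein, r_ligand), so any contacting pair lies in the same or an
adjacent cell; only the 27-cell neighbourhood is scanned (each unordered
cell pair once). An O(N²) all-pairs implementation is kept as the testing
oracle; the two agree exactly on every fixture, and the matrix is invariant
under rigid motion of the whole structure by construction.

## Complex graph

`build_complex_graph` maps the contact matrix to an undirected simple graph:
edge iff count ≥ 1, weight = count; contact-free chains stay as isolated
vertices. Graphs round-trip losslessly through a fixed minimal GML dialect
(`graph [` / `node [ id <int> label "…" ]` / `edge [ source … target …
weight … ]` / `]`, node ids 0-based in vertex sort order, lowercase keys, no
graphics blocks). Interoperability with other GML dialects is not
guaranteed. For plotting, each vertex is placed at the unweighted mean of
its chain's non-solvent atom coordinates ("geometrical centre", not centre
of mass); layouts export as TSV with optional module ids, and an edge-label
TSV lists edges at or above a weight threshold (default 30) — a presentation
option that never affects the graph itself.

## Modularity

The quality function is generalized weighted modularity

    Q = sum_c [ w_in(c)/m − gamma · (s_c/(2m))² ]

with m the total edge weight, w_in(c) the intra-module edge weight (self-
loops of aggregate graphs counted once at full weight), s_c the summed
vertex strengths (a self-loop adds twice to its vertex's strength) and gamma
the resolution (default 1.0; larger values resolve smaller modules and are
the exposed answer to the resolution limit of plain modularity). Edgeless
graphs get Q = 0 by definition. The implementation agrees with the direct
double-sum definition and with igraph's weighted modularity to 1e-10 on
randomized cross-checks.

## Leiden procedure

Each run starts from the singleton partition and iterates three phases:

* **Local movement** — queue-based; a dequeued vertex may move to a
  neighbouring community that strictly increases Q, the target drawn with
  probability proportional to its Q gain. Neighbours left outside the chosen
  community re-enter the queue. Randomized-proportional selection was chosen
  over greedy best-gain deliberately: with purely greedy moves there are
  small weighted graphs whose global optimum is unreachable from any vertex
  ordering (best-of-200 runs misses it), while proportional selection
  explores enough to reach the enumerated optimum on all tested graphs; the
  best-of-N protocol absorbs the extra per-run variance.
* **Refinement** — within each community, starting from singletons, a vertex
  that is still alone and well-connected inside its community may merge into
  a well-connected sub-community of the same community, sampled with
  probability ∝ exp(ΔQ/θ) among non-decreasing-Q candidates (θ = 0.01, the
  Leiden method's customary default; staying put is always a candidate).
  Well-connectedness of a set S inside community C uses the gamma-scaled
  criterion E(S, C−S) ≥ γ·k_S·(k_C−k_S)/(2m) on summed strengths.
* **Aggregation** — refined sub-communities become vertices of a weighted
  aggregate graph (internal weight preserved as self-loops); its starting
  partition is induced from the *non-refined* partition.

The cascade repeats until every aggregate vertex is its own community, and
the whole cascade is then restarted from the resulting flat partition on the
original graph until a restart no longer improves Q — the "iterate until no
further improvement" convergence rule. Q is monotone non-decreasing
throughout (every accepted move strictly improves it; aggregation preserves
it exactly), and both properties are asserted at runtime under
`leiden_once(..., audit=True)`.

All randomness flows through one `numpy.random.default_rng(seed)` per run.
`cluster_best_of` executes n_runs independent runs with seeds base_seed …
base_seed+n_runs−1 (default 2000, matching the production protocol for real
complexes), returns the max-Q partition (ties to the earliest seed) with
modules renumbered canonically by their smallest contained vertex label, so
outputs are identical across platforms given the same inputs and seed.

For graphs of ≤ 10 vertices, `exhaustive_best_partition` enumerates all set
partitions in restricted-growth-string order and returns the global Q
maximizer; ties resolve to the lexicographically smallest canonical form.
Edgeless graphs (m = 0, every partition scores 0) return the all-singleton
partition by convention, consistent with what a Leiden run yields when no
improving move exists.

## Evaluation

The adjusted Rand index is computed from the contingency table over the
elements both assignments cover (omitted chains are logged — references may
label only a subset); binomial counts use exact integer arithmetic with the
division deferred to the end, so large complexes cannot lose precision. A
zero denominator only occurs when both sides are all-singletons or both a
single block, i.e. identical clusterings: 1.0 is returned. Cross-checked
against scikit-learn's implementation on randomized inputs.

The module interface report gives per-module sizes and intra-module weight,
per-module-pair inter-module weight, and the overall intra-weight fraction;
intra plus inter weights always sum to the total graph weight. Inter-module
weight is the rigidity/flexibility proxy: heavily connected module pairs
behave as rigidly coupled, weak interfaces are candidate flexible regions.
Biological interpretation is left to the user.

## Synthetic fixtures

`generate_planted_structure` emulates exactly the geometric property the
pipeline depends on — spatial clusters of chains with dense intra-cluster
and absent inter-cluster residue contacts. Chains are straight CA-only
alanine runs (3.8 Å spacing, ±0.05 Å seeded jitter); chains of one module
stack at 3.5 Å (inside the 4.0 Å protein–protein threshold: ~1 contact per
residue with the adjacent chain), module blocks sit 12.0 Å apart (zero
cross-contacts; the generator refuses an inter-block gap ≤ 4.0 Å unless
`allow_module_contact=True` is passed explicitly). It does not emulate
side-chain packing, realistic interface sizes or shapes, ligands, altlocs or
sequence content — so passing tests demonstrate the correctness of the
contact/graph/clustering machinery, not parsing robustness against the full
variety of real depositions (that is what gemmi provides) nor biological
validity of predicted modules on real complexes. `generate_planted_graph`
plants modules directly in a weighted graph (complete intra-module edges at
w_in = 10, inter-module edges with probability p_out = 0.1 at w_out = 1 by
default — a strong-separation regime where the modularity optimum provably
aligns with the planted blocks in practice).

## Numerical choices and problem sizes

Floating-point gain comparisons use an absolute tolerance of 1e-12; Q
monotonicity and aggregation invariance are asserted at 1e-9. Test and
acceptance problem sizes are chosen so every oracle is exact and the whole
suite runs in well under its budget on one CPU: random contact fixtures of
2–4 chains × up to ~12 residues × ≤ 3 atoms (100 draws) for grid-vs-brute
force; random weighted graphs of 4–9 vertices (100 draws) for the
best-of-200 vs exhaustive-enumeration check; a 4×4-chain planted structure
with the full 2000-run protocol for the end-to-end acceptance computation.

## Limitations

* Modularity optimization has a resolution limit; the exposed gamma
  parameter mitigates but does not remove it. Whether a structural module
  contains finer sub-modules cannot be decided from a single gamma.
* The pure-Python Leiden implementation targets complex graphs (hundreds of
  vertices), not million-edge networks.
* Contact counting is geometric only: no chemistry, no buried-surface-area,
  no hydrogen-bond typing.
* Reference assignments for ARI evaluation must be supplied by the user as
  two-column TSV; published module tables often live in supplementary
  material and need manual transcription.
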