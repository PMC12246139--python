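# Methods

## Scope and data model

The package analyzes protein–ligand–solvent trajectories the way binding
modes of switch-II-pocket KRAS(G12C) inhibitors are derived from long
multi-replica MD: geometric interaction fingerprints aggregated into
per-residue fractions, conserved-water-site occupancy and exchange,
side-chain flip-state classification, and representative-frame selection by
clustering. Coordinates are in Å throughout, times in ns, atom indices
0-based, residue numbers author-numbered (1-based), matching the field's
labels (Gly10, Thr58, …). Frames are analyzed at a configurable time stride
(default 1 ns); the stride is applied by timestamp, not frame index, so
irregularly spaced inputs are handled correctly.

File parsing (multi-model PDB, DCD, XTC) is delegated to MDAnalysis.
Chemistry of standard residues and waters comes from a built-in template
table (bond graphs, potential donors, acceptors, charged groups, aromatic
rings, apolar carbons, PDB v3 atom names). Ligand chemistry comes from a
YAML sidecar — deterministic and format-independent, hence the source of
truth — with RDKit bond-graph perception as a fallback when no sidecar is
given. Hydrogens are required for hydrogen-bond analysis; topologies
lacking them are rejected for that analysis rather than rebuilt, because
adding hydrogens is system preparation, not analysis.

## Interaction criteria

A hydrogen bond requires H⋯A ≤ 2.5 Å, donor angle D–H⋯A ≥ 120° and
acceptor angle H⋯A–X ≥ 90°. The distance cutoff applies to the
**hydrogen–acceptor** separation: a 2.5 Å donor–acceptor cutoff would
exclude essentially all real hydrogen bonds (typical D–A separations are
2.8–3.2 Å). The acceptor angle is evaluated against each heavy-atom
substituent X of the acceptor and the **maximum** is compared (the most
permissive convention); acceptors with no heavy substituent (water oxygen)
satisfy the criterion vacuously. A water bridge is one water satisfying the
same geometry at 2.8 Å / 110° / 90° simultaneously to a protein residue and
to the ligand; only single-water bridges are counted, and one event is
recorded per (residue, water, ligand atom) per frame.

π–π stacking uses ring centroids and normals (smallest singular vector of
the centered ring coordinates). Because normals carry an arbitrary sign,
the interplanar angle is folded to [0°, 90°]: face-to-face means centroids
≤ 4.4 Å with folded angle ≤ 30°, edge-to-face means ≤ 5.5 Å with folded
angle ≥ 60° (the configured [60°, 120°] window on the unfolded angle).
π–cation uses a single 4.5 Å centroid–centroid cutoff. Hydrophobic contacts
are apolar-carbon pairs within 3.6 Å and ionic contacts are
opposite-charge groups whose closest atoms lie within 3.7 Å — conventional
fingerprinting values, since these thresholds are tool defaults rather than
published numbers. Every threshold lives in `InteractionCriteria`.

Aggregation binarizes per frame: several same-type contacts between one
residue and the ligand in one frame contribute one occupied frame to that
(residue, type) fraction. Replicas are pooled by unweighted frame counts.
Per-residue totals sum the per-type fractions and may exceed 1; a residue is
flagged *displayed* above 0.2 and *key* above 0.5, both strict.

## Geometry

Minimum-image displacements for triclinic boxes are computed by fractional
rounding refined over the 27 neighbouring images, which is exact for any
reasonably reduced box; the test suite gates this against a literal
27-image enumeration. Superposition is Kabsch (SVD with reflection
correction). The ligand-RMSD convention fits each frame to the reference on
the protein backbone and measures the ligand heavy atoms **without**
re-fitting; a re-fit mode exists for the alternative reading. RMSF uses an
iterated-mean reference (fit to the first frame, average, re-fit to the
average) because vendor tools leave the reference unstated; a first-frame
mode is available.

## Conserved-water site

The site is a sphere (default radius 3 Å) around the per-frame centroid of
the anchor residues' side-chain heavy atoms, so it moves with the protein.
Glycine has no side-chain heavy atoms; its anchor degenerates to the Cα,
keeping the construction total — the 3 Å radius makes the statistic fairly
insensitive to this choice, but exact reproduction of literature values may
depend on the original tool's convention. Occupancy is judged on water
oxygens only (hydrogens ignored), PBC-aware. Exchange is summarized as the
number of distinct water identities that ever occupy the site per replica,
with the across-replica median reported; because occupancy is evaluated at
the analysis stride, sub-stride exchange events are undercounted by
construction. Conditional occupancy is the occupied fraction within each
state label; by total probability, the state-frequency-weighted
conditionals reproduce the marginal exactly, which the suite asserts to
1e-12.

## Flip states

Descriptors are the distance from the donor residue's side-chain oxygen
(OG1) to the reference residue's backbone amide hydrogen, and the interior
angle OG1–CB–H. The default partition calls a frame *native* when distance
≤ 4.0 Å and angle ∈ [60°, 180°], else *flipped*; the boundary is closed on
the native side and fully exposed in configuration, because the partition is
drawn but not printed in the literature — any comparison against published
conditional-occupancy tables must treat it as a free parameter. Density
grids are 2-D histograms normalized by total frame count (so masking does
not distort fractions); cells below 0.05 are masked and their frames echoed
back as raw points, the scatter-overlay convention.

## Clustering and representative selection

Similarity between frames i and j is −RMSD², measured over the key
interaction residues plus ligand heavy atoms after superposing on the
protein backbone, symmetrized by averaging both fit directions. Affinity
propagation is implemented directly (responsibility/availability messages)
so the result is deterministic: no random tie-breaking noise is injected;
instead an index-derived micro-jitter (~1e-9 of the similarity span) breaks
exact degeneracies, and argmax ties resolve toward the lower frame index.
Preference defaults to the median off-diagonal similarity and damping to
0.5 — the method's canonical defaults. When the messages oscillate (which
happens on trajectories whose frames are nearly identical within basins;
scikit-learn's implementation shows the same non-convergence there) the
damping is escalated deterministically to 0.7 and then 0.9, the remedy the
method's authors prescribe. If no attempt converges, the result is returned
with `converged=False` and a warning rather than an exception. A frame cap
(default 2000, even subsampling by time) keeps the n² matrix tractable.

The representative frame is the exemplar of the most populated cluster
whose exemplar exhibits at least one event with every key residue,
evaluated on the exemplar frame only (the simplest reading of
"representing all the key interactions"); if no cluster qualifies, the
largest cluster's exemplar is returned with a warning. Clustering operates
on all replicas merged.

## Synthetic generator

The generator is a statistical emulator, not MD: it reproduces the
*statistical* structure of a 20-replica × 5 µs study sampled at 1 ns — not
forces, energetics or kinetics. A mini receptor places the pocket's named
residues on a ring around a ligand whose annotated fragments (donor amine,
carbonyl and pyridine-like acceptors, aromatic ring, two charged amines,
ether, apolar carbon) are switched per frame between an "on" geometry
planted deep inside the corresponding criterion (e.g. H⋯A = 1.9 Å with
near-linear angles) and a parked position far outside every criterion.
Contact schedules are independent Bernoulli draws at the configured
probabilities; defaults plant hydrogen bonds at {1.0, 0.7, 0.2} and the
other classes at intermediate values. The conserved-water site follows a
two-state Markov chain with stationary occupancy 0.8 whose entry rate is
set by the expected number of distinct waters per replica (default 30, so
p(enter|empty) = rate/(n·(1−p)) and p(leave|occupied) = rate/(n·p)); each
re-entry assigns a fresh water identity from the pool. An optional
state-coupled mode draws occupancy conditioned on the Thr58 state instead.
The Thr58 schedule is a two-state process with configurable stationary
native fraction (default 0.7) and mean dwell (default 1 frame, i.e.
independent draws — the setting under which realized fractions admit exact
binomial confidence statements; note that for the Markov water chain the
stationary-fraction variance is inflated by (1+ρ)/(1−ρ) with
ρ = 1 − p01 − p10, which the validation uses).

Positional noise is Gaussian with σ = 0.03 Å truncated at ±4σ, so the
largest possible pairwise perturbation (≈0.42 Å, ≈13° on the planted arm
lengths) stays below every planted margin (≥0.53 Å, ≥25°); a configuration
requesting σ > 0.05 Å is rejected. At generation time the real detectors
run on noise-free template frames (all contacts on/off × native/flipped ×
site occupied/empty) and the planted (residue, type) event set must match
exactly, so cross-talk between planted fragments is impossible rather than
merely unlikely. Every per-frame truth is recorded in a ledger; all
analysis modules must reproduce the ledger's realized values **exactly**,
which is the core of the validation suite. Replicas draw from sub-seeds
spawned from the master seed, and trajectories are regenerated lazily and
reproducibly from the ledger.

What passing these tests shows — and does not show. Exact ledger recovery
demonstrates that the detectors implement their criteria correctly, that
occupancy/exchange/state accounting is right, and that the pipeline's
bookkeeping across replicas is sound. It does not probe borderline
geometries (contacts are planted away from thresholds by design; the
randomized oracle-equivalence tests cover the boundaries instead), force
fields, sampling convergence, or any property of real MD data such as
correlated motions, wrapping artifacts or protonation ambiguity.

## Problem sizes

The validation suite runs the full 20-replica × 1000-frame design (20 000
analyzed frames, ~300 atoms) for statistical recovery, 100 randomized
micro-frames for oracle equivalence, and a 90–120-frame three-basin
trajectory for clustering; the numbered analysis scripts use a 5 × 400
dataset. These sizes give sub-percent binomial confidence half-widths on
the planted fractions while keeping any single run in the minutes range on
one CPU.

## Known limitations

Two-water bridges are not counted (the stated criterion defines a single
water). Donor/acceptor typing follows the built-in templates and sidecar,
not a force field. mmCIF, PSF and protonation assignment are out of scope.
The ligand-chemistry perception fallback cannot recover bond orders from a
PDB bond graph reliably; supply a sidecar for production use. Ions are kept
in the topology but carry no template annotations beyond element identity.
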