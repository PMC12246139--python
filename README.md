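# bindmode

Trajectory analysis of protein–ligand binding modes, built around the way
covalent KRAS(G12C) switch-II-pocket (SII-P) inhibitors are characterized
from long multi-replica molecular-dynamics simulations. Given a topology and
per-replica coordinate trajectories of a protein–ligand–solvent system,
the package derives:

- **Interaction fingerprints** — per-frame geometric detection of hydrogen
  bonds, water bridges, π–π stacking, π–cation, ionic and hydrophobic
  contacts, pooled across replicas into per-residue *interaction fractions*
  (fraction of analyzed frames in which a residue engages the ligand through
  a given interaction type). A residue is *displayed* when its total
  fraction exceeds 0.2 and *key* when it exceeds 0.5.
- **Conserved-water-site statistics** — occupancy of a hydration site
  defined as a 3 Å sphere around the per-frame centroid of anchor-residue
  side chains (Thr58/Gly10 in the SII-P), and exchange statistics: the
  number of distinct water molecules that ever occupy the site per replica,
  with the across-replica median as an exchange-rate proxy.
- **Side-chain flip states** — the Thr58-type native/flipped classification
  from the distance of the side-chain oxygen to the Gly10 amide hydrogen and
  the interior angle OG1–CB–H, with masked distance–angle density grids and
  occupancy conditioned on state.
- **Representative-frame selection** — affinity-propagation clustering of a
  pairwise RMSD matrix (similarity −RMSD², measured over key residues plus
  ligand heavy atoms after protein-backbone superposition), then the
  exemplar of the most populated cluster that exhibits every key
  interaction.

## Geometric criteria

Defaults (all configurable via `InteractionCriteria`):

| interaction | criterion |
|---|---|
| hydrogen bond | H⋯A ≤ 2.5 Å, donor angle D–H⋯A ≥ 120°, acceptor angle H⋯A–X ≥ 90° |
| water bridge | the same geometry at 2.8 Å / 110° / 90°, simultaneously to protein and ligand through one water |
| π–cation | charged-group centroid to ring centroid ≤ 4.5 Å |
| π–π | face-to-face: centroids ≤ 4.4 Å, interplanar ≤ 30°; edge-to-face: ≤ 5.5 Å, interplanar in [60°, 120°] |
| hydrophobic | apolar C⋯C ≤ 3.6 Å |
| ionic | opposite-charge closest atoms ≤ 3.7 Å |

Because no public trajectory is needed for validation, the package ships a
synthetic-trajectory generator (`bindmode.synthetic`) that emulates the
statistical structure of a 20-replica study — a KRAS-like mini receptor
with the pocket's named residues (Gly10, Cys12, Lys16, Thr58, Glu62, Glu63,
Tyr64, Asp69, His95, Tyr96), an annotated ligand, and exchanging explicit
waters — and plants every statistic as *exactly recoverable* per-frame
ground truth recorded in a ledger.

## Worked example

```python
import bindmode as bm

traj = bm.simulate(bm.GeneratorConfig(n_replicas=5, n_frames=400,
                                      n_waters=40, water_exchange_rate=12,
                                      seed=7))
topo = traj.topology
events, n = [], 0
for r in range(5):
    for k, frame in enumerate(traj.replica(r)):
        events.extend(bm.detect_all(frame, topo, frame_index=k, replica=r))
        n += 1
table = bm.aggregate_fractions(events, n)
print([f"{name}{num}" for num, name, _ in table.key_residues()])
```

prints

```
['LYS16', 'TYR64', 'ASP69', 'TYR96']
```

— the residues whose total interaction fraction exceeds 0.5 under the
planted contact probabilities (the Asp69 hydrogen bond is planted in every
frame, so its fraction is exactly 1.0). The numbered scripts under
`analysis/` run the full sequence on this dataset and write their tables to
`results/`; for example `analysis/03_water_site_occupancy.py` reports

```
site occupied 0.852 of frames (absent 0.148)
unique waters per replica: {0: 11, 1: 7, 2: 13, 3: 19, 4: 10} median 11.0
ledger agreement: exact
```

meaning the analysis stack recovered the generator's realized per-frame
truth without a single disagreement.

The same machinery is exposed as a CLI (`bindmode analyze | fingerprint |
water | states | cluster | synth`) for file-based inputs: multi-model PDB,
DCD or XTC trajectories over a PDB topology with CONECT records, plus an
optional YAML ligand sidecar listing donors, acceptors, aromatic rings,
charged groups and hydrophobic carbons by atom name.

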