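# pocketdyn

Transient (cryptic) binding-pocket detection and binding-site flexibility
analysis for protein structure ensembles.

Protein binding sites move. Side chains rotate, loops shift, and sub-pockets
that are invisible in any single crystal structure can open transiently —
and such pockets are prime real estate for designing selective inhibitors.
`pocketdyn` takes an ensemble of conformations of one protein (crystal
structures, trajectory snapshots exported as multi-model PDB, or homologous
structures from related species) plus a binding-site definition, and answers:

* how variable is the binding site across the ensemble, and which residues
  move most (RMSD matrix, per-member means, per-residue maxima, clustering
  into representative conformations);
* where does the site cavity grow or shrink relative to a reference structure
  (per-snapshot grid cavities, appearing/disappearing/conserved regions,
  compact sub-pockets and their per-snapshot extent of opening);
* which binding-site residues are conserved — or, given on-target and
  off-target sequences, which residues *discriminate* the targets
  (Jensen–Shannon divergence conservation mapped onto the structure).

## Method core

**Superposition and RMSD.** Binding-site residues are resolved on the
reference (all residues with a heavy atom within radius *r*, default 5 Å, of a
ligand or point) and carried onto each member through global sequence
alignment (Needleman–Wunsch, BLOSUM62), so homologs with gaps, insertions or
mutations remain comparable. Each member is rigidly fitted to the reference by
the Kabsch algorithm on paired site backbone atoms (N, CA, C, O). Site RMSD is
computed either over backbone atoms (default) or over per-residue geometric
centers of the side-chain heavy atoms.

**Clustering.** Simplified single-linkage clustering at an RMSD threshold
(default 3 Å), computed exactly as connected components of the thresholded
distance graph, or threshold-driven k-means on concatenated side-chain
centers: the smallest *k* whose clusters all lie within the threshold
(e.g. 1.5 Å) of their centroid. Each cluster is summarized by its medoid.

**Pocket detection.** Structures are rasterized onto a shared grid (default
1.0 Å). Points within vdW + probe (1.4 Å) of a heavy atom are protein; free
points inside the site sphere are scored by a LIGSITE-style buriedness scan
along 7 directions (3 axes + 4 cube diagonals, depth 10 Å each way); a point
is pocket when ≥ 5 of 7 directions hit protein on both sides and its
26-connected component reaches the site core. Per-structure cavities yield
volume, solvent-facing surface, lining residues and physicochemical contact
counts (donor/acceptor/positive/negative/hydrophobic).

**Transient regions.** Per-point occupancy across members gives a frequency
grid; appearing regions are non-reference points open in ≥ 25% / 50% (both
defaults reported) of members, disappearing regions the reverse, conserved
regions those open in ≥ 90%. Regions split into compact sub-pockets
(26-connectivity, ≥ 5 points) whose opening fraction is traced per member.

**Conservation.** Per MSA column, the Jensen–Shannon divergence (log₂, bounded
by 1 bit) between the column's amino-acid distribution and the BLOSUM62
background, damped by the gap fraction, linearly rescaled to [30, 70] and
mapped onto reference residues (also written into a PDB B-factor column). The
differential mode scores each column by |score(on-targets + off-target) −
score(on-targets)|: high rescaled values mark selectivity-relevant positions.

## Worked example

Generate a synthetic 8-member ensemble whose wall opens a side sub-pocket in
exactly 4 members, then run the full workflow:

```sh
pocketdyn fixtures make-ensemble --n-members 8 --hollow-radius 5 \
    --open-fraction 0.5 --noise-sigma 0.1 --seed 7 --out example/fixture
pocketdyn run --reference example/fixture/reference.pdb \
    --ensemble example/fixture/ensemble.pdb \
    --center 0 0 0 --site-radius 10 --out example/run
```

which prints

```json
{
  "out_dir": "example/run",
  "n_clusters": 1,
  "representatives": ["ensemble_model3"],
  "reference_pocket_volume": 515.0,
  "n_subpockets": 7
}
```

One conformational cluster (the planted ensemble has no side-chain cluster
structure, only noise), a 515 Å³ reference cavity — the discretized volume of
the planted 5 Å hollow, (4/3)π·5³ ≈ 524 Å³ — and several transient
sub-pockets. The largest appearing sub-pocket in `example/run/subpockets.csv`:

```
threshold,region,label,n_points,volume,centroid_x,centroid_y,centroid_z
0.25,appearing,0,81,81.0,6.73,-0.09,0.01
```

an 81 Å³ region centered ~6.7 Å along +x — exactly where the fixture opens its
wall cap — open in half the members (see `opening_series.csv`). The run
directory also holds `rmsd_matrix.csv`, `clusters.csv`, `pocket_stats.csv`,
DX grids (`frequency.dx`, `appearing_50.dx`, ...) for any OpenDX-reading
viewer, and `summary.json`.

With an alignment (`--msa alignment.fasta`, optionally
`--off-target <id>`), `conservation.csv` and a B-factor-colored
`reference_conservation.pdb` are added.

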