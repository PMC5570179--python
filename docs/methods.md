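# Methods

This note documents the models, algorithms, numerical choices and limitations
behind `pocketdyn`, and what the synthetic test bed does and does not
establish about real data.

## Binding-site definition and cross-structure mapping

A binding site is the set of reference residues having at least one heavy atom
(elements other than H/D) within a radius of either any heavy atom of a
user-supplied ligand or a user-supplied center point. The default radius is
5 Å, the conventional ligand-contact cutoff. Using any heavy atom of the
residue (rather than CA only) follows common practice for "residues within
*r* of the ligand"; ligand hydrogens are ignored for the same reason the
protein's are — their positions are usually absent or modeled.

Site residues are mapped onto every ensemble member by global pairwise
sequence alignment (Needleman–Wunsch with BLOSUM62, gap open −11 /
extend −1, via Biopython's PairwiseAligner). Chains are paired by identical
chain id when the structures share one, otherwise by the best-identity chain
pair. Residues whose column falls in a gap are UNMAPPED: they are excluded
from superposition and RMSD with a logged warning rather than failing the
run, since homologs with deletions are expected input. A member whose overall
aligned identity falls below `mapping.min_identity` (default 0.2) is rejected
outright — below that, residue correspondence is not meaningful. Nonstandard
residues enter the alignment as 'X'. Residue identity across files is
`(chain_id, res_seq, insertion_code)`; a different residue name at the same
aligned position is recorded as a mutation, not an error.

## Superposition and RMSD metrics

Members are rigidly fitted to the reference by the Kabsch SVD algorithm on
paired site backbone atoms. The backbone set is {N, CA, C, O}; when the
carbonyl O is missing on either side the residue contributes its N/CA/C
triplet. Reflections are corrected (det = +1 enforced); at least three usable
residues are required. Superposition is idempotent to ≤ 1e-9 and recovers an
applied rigid transform to ≤ 1e-6 (asserted in tests).

Two site RMSD metrics are provided:

* **backbone** (default) — RMSD over all paired site backbone atoms;
* **sidechain_center** — RMSD over per-residue geometric centers of
  side-chain heavy atoms. Residues without side-chain heavy atoms (glycine,
  truncated side chains) fall back to all their heavy atoms so every residue
  yields a center.

The member×member RMSD matrix compares members pairwise *after each has been
independently fitted to the reference* (no pairwise re-fitting): this matches
the single-reference workflow and keeps the fit count linear in ensemble
size. A consequence worth knowing: RMSD after independent fits is not a
metric (no triangle inequality), which is acceptable because downstream
clustering uses it only as a similarity threshold. The per-member summary is
computed per residue and then averaged (unweighted), not atom-pooled, so
large residues do not dominate; the per-residue maximum over members is
reported per site residue.

## Clustering

**Single linkage.** "Simplified single-linkage at threshold t" is realized as
the exact connected components of the graph with an edge wherever RMSD ≤ t
(default 3 Å). This is the closure of agglomerative single linkage cut at t,
computed deterministically and order-independently via
`scipy.sparse.csgraph.connected_components`. Cluster ids are assigned in
order of first member occurrence; representatives are medoids (minimum summed
intra-cluster distance, ties to the lowest index). Note that a two-member
cluster always ties, so for such clusters the representative depends on
member order through the tie rule — unavoidable for any index-based
tie-break.

**Threshold-driven k-means.** Features are the concatenated per-residue
side-chain geometric centers of the site residues (3R dimensions); Euclidean
distances are divided by √R to live on the per-residue RMSD scale. k is the
smallest value in 1..max_k for which every member lies within the threshold
(default for refinement: 1.5 Å) of its cluster centroid. Initialization is
farthest-point: the first center is drawn from the seeded generator
(default seed 17, logged), subsequent centers maximize distance to the chosen
set; Lloyd iterations (cap 100) then run to convergence. The procedure is
deterministic given the seed — a single deterministic initialization replaces
random restarts, trading a (rare) suboptimal local minimum for bit
reproducibility. Members unmapped in some structure contribute the member's
site centroid as a neutral placeholder feature.

## Grid cavity detection

All structures in a run share one axis-aligned grid covering the site sphere
plus a margin (default 2 Å), snapped so the site center lies on a grid point;
spacing is isotropic, default 1.0 Å, accepted range 0.25–2.0 Å (finer grids
exceed 10⁷ points and are refused with a suggestion to coarsen).

Detection is a LIGSITE-style buriedness scan:

1. **Protein marking** — points within `vdW(element) + probe` of any heavy
   atom are protein. Radii: C 1.70, N 1.55, O 1.52, S/P 1.80, halogens per
   Bondi, 1.70 Å for unknown elements; probe 1.4 Å (water).
2. **Buriedness** — each free point inside the site sphere casts rays along 7
   directions (±x, ±y, ±z collapsed to 3 axes, plus the 4 cube diagonals) up
   to `scan_depth` (default 10 Å) each way, stepping on grid nodes; the point
   is buried if ≥ `min_buried_directions` (default 5) of the 7 lines hit
   protein on both sides.
3. **Component filter** — buried points are split into 26-connected
   components and only components reaching the inner half of the site sphere
   are kept, discarding detached surface dimples.

All parameters are exposed because the criterion is a reconstruction of the
classic grid-scan lineage rather than a published constant set. The scan
depth interacts with cavity size: for cavities wider than `scan_depth`,
wall-adjacent points lose the through-cavity directions, which slightly
erodes the detected boundary — visible as the small negative bias at 1.0 Å
spacing in the volume-convergence test. An independent brute-force
implementation of the same three rules (plain loops, in the test suite)
agrees bit-exactly on every synthetic fixture.

**Statistics.** Volume is exactly point count × spacing³. Surface area counts
6-adjacent faces between pocket points and free solvent (anything neither
pocket nor protein, including space outside the grid) × spacing²; a fully
enclosed cavity therefore reports 0 — the quantity measures *solvent-exposed*
pocket surface. Lining residues have ≥ 1 side-chain heavy atom within the
contact distance (default 4.0 Å) of ≥ 1 pocket point. Physicochemical
contact counts assign each pocket point the classes of the side-chain atoms
it contacts (positive: Lys NZ, Arg NE/NH1/NH2, His ND1/NE2; negative:
Asp OD1/OD2, Glu OE1/OE2; donors and acceptors per the standard side-chain
table; hydrophobic: side-chain carbons of Ala/Val/Leu/Ile/Phe/Met/Pro/Trp); a
point may carry several classes.

## Transient regions and sub-pockets

The frequency grid is the per-point mean of member pocket booleans (the
reference is excluded unless explicitly included — transients are defined
*relative to* the reference). At threshold f (defaults 0.25 and 0.50, both
always computed): appearing = non-reference points with frequency ≥ f;
disappearing = reference points with (1 − frequency) ≥ f; conserved =
frequency ≥ 0.9. Appearing and disappearing are disjoint by construction and
asserted on every run. "Compact sub-region" is realized as a 26-connected
component of at least `min_subpocket_points` (default 5 points ≈ 5 Å³ at
1 Å spacing); components are labeled by decreasing size with lexicographic
tie-break. The extent of opening of a sub-pocket in member m is the fraction
of its points that are pocket in m; the absolute open volume is also written
to the CSV, since either convention is defensible. The mean of the opening
series over members equals the mean frequency over the sub-pocket's points —
an exact identity used as a consistency check.

## Sequence conservation

Column score: Jensen–Shannon divergence JSD(p, q) = H((p+q)/2) − (H(p) +
H(q))/2 in bits (≤ 1), between the column's amino-acid distribution p and the
BLOSUM62 marginal background q (embedded 20-value table, normalized to sum to
1), multiplied by (1 − gap fraction). 'X' and '-' count as gaps; an all-gap
column scores 0 with a warning. A pseudocount of 1e-7 is added to the
*normalized frequencies* (not the counts) so that columns with identical
composition score identically regardless of alignment depth — this makes the
differential profile of an off-target identical to the on-target consensus
exactly zero. No sequence weighting or window smoothing is applied; both are
deliberate defaults, exposed as parameters of the scoring functions.

Rescaling to the display range is the min–max affine map
30 + 40·(s − min)/(max − min); a constant profile maps to the midpoint 50.
The map is strictly monotone for non-constant input and attains exactly 30
and 70 at the extremes. The differential profile |score(on+off) − score(on)|
is rescaled with the same map; its polarity is: low = on/off similar,
high = dissimilar.

Mapping to the structure: the MSA row with the best identity to the
structure-derived sequence is the reference row (required identity > 0.9);
its non-gap columns are walked in order against the structure's non-hetero
residues. Structure residues beyond the row (tags) stay unscored with a
warning. Scores are also written into the B-factor column of a PDB copy for
external viewers.

## Synthetic test bed

The fixture generator builds hollow pseudo-proteins whose ground truth is
known by construction:

* **Shell** — two concentric near-uniform spherical layers (golden-angle
  spirals, inter-residue spacing 0.6 × `wall_spacing`) of compact
  pseudo-alanines (five heavy atoms within 0.5 Å of the residue center). Each
  wall atom's radial position is calibrated so its steric clearance surface
  (vdW + probe) touches the hollow sphere exactly; the detectable cavity is
  therefore a sphere of `hollow_radius` up to grid discretization. A zero
  hollow yields a solid lattice ball with no cavity.
* **Planted sub-pocket** — in "open" members, wall residues within an angular
  cap (half-angle 0.7 rad) around `subpocket_offset` are displaced outward by
  4 Å, opening a compact side recess; exactly
  round(`subpocket_open_fraction` × n) members (the first ones) are open. The
  planted appearing region is obtained by differencing the noise-free open
  and closed exemplars with the same detector.
* **Planted conformational clusters** — member i joins cluster i mod k; all
  CB atoms are displaced by the cluster's offset vector (pairwise offsets
  ≥ 6 Å), leaving the backbone untouched so superposition is unaffected while
  side-chain-center metrics separate the clusters cleanly.
* **Toy MSA** — on-target rows share a base sequence at planted conserved
  columns (and at off-divergent columns, so the off-target signal is not
  masked by on-target variability) and vary randomly elsewhere; the off-target
  row differs from the base exactly at the divergent columns.

All generators are pure functions of (spec, seed) with a single seeded
`numpy` generator — repeated calls are bit-identical.

What the fixtures do **not** emulate: real protein topology (the walls are
disconnected pseudo-residues, not a chain), realistic side-chain rotamers,
partial occupancy/altloc disorder, correlated backbone motions, or realistic
MSA phylogeny (columns are i.i.d.). Passing tests therefore demonstrate the
correctness of the geometry, set-operations and scoring machinery and the
recoverability of planted signals, not field performance on crystallographic
ensembles; for real input the alignment and mapping layers carry the burden
the fixtures bypass.

## Problem sizes and runtime choices

Test and acceptance runs use hollows of 3.5–6 Å radius (≈ 2 700–4 200 atoms),
ensembles of 4–10 members, grids up to 65³ points, alignments of 20–40
columns. These sizes keep a full run in seconds while every stage is still
exercised through its public interface; all quantities they verify (volume
ratios, Jaccard recovery, partition identity, rescaling endpoints) are
size-invariant properties rather than scale benchmarks.

## Known limitations

* Multi-model PDB is the only ensemble dialect; binary trajectories (DCD/XTC)
  must be exported to models upstream. mmCIF is not read.
* The buriedness criterion is a reconstruction (parameterized, documented
  above), not a reimplementation of a published constant set; absolute
  volumes depend on its parameters, though transient-region *differences*
  are much less sensitive.
* Surface area is solvent-exposed pocket surface on the grid, not a
  Shrake–Rupley molecular surface; enclosed cavities report 0.
* Pocket-shape clustering across members and druggability scoring are out of
  scope; k-means cluster counts above 7 planted offsets are not supported by
  the fixture generator (the detection code itself has no such limit).
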