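# Methods

## The refinement model

`pocketforge` refines the orthosteric binding pocket of a 7-transmembrane
(7-TM) receptor around a single known ligand. The working assumption is
that of ligand-directed modeling: a receptor conformation in which the
known ligand docks with a favorable score and an intact pocket is closer
to the ligand-bound state than the starting structure, so iterating
*sample → select → dock → extract* concentrates the search in the
relevant region of conformational space.

The receptor is split into two regions before refinement:

* **cytoplasmic (static)** — TM1 plus everything at or below the seven
  Ballesteros–Weinstein anchor residues 1.48, 2.51, 3.38, 4.51, 5.50,
  6.43 and 7.45 (roughly the bottom third of the bundle). Holding this
  region rigid preserves the 7-TM fold without a membrane model.
* **extracellular (flexible)** — the upper segments of TM2–TM7 and any
  retained extracellular loop; this region contains the pocket and is
  the only part the samplers may move.

Flexible loops are deleted before refinement except the distal half of
extracellular loop 2 — the segment from the conserved disulfide cysteine
(kept, because it is covalently anchored to TM3) toward TM5 — which
participates in orthosteric ligand binding. Docking exerts no selective
pressure on the other loops, and their flexibility only dilutes the
conformational search and can occlude the pocket.

The pocket itself is the set of residues with any heavy atom within
1.5 Å (inclusive) of a seed point set. Since the original cavity-finder
is proprietary, the seed defaults to a padded envelope of the bound
ligand: each ligand heavy atom plus a shell of points 2 Å away in 26
directions, approximating the cavity surface. A user-supplied box or
point set can replace it.

## The iterative engine

A run is organised as `n_replicas` independent restarts, each running
`n_rounds` sequential rounds of `n_directories_per_round` parallel
sampling chains:

1. **backbone sampling** of the flexible region;
2. **pocket-distance filter** — pocket Cα RMSD to the round's starting
   system (after least-squares superposition) must be ≤
   `pocket_rmsd_cutoff`;
3. **side-chain sampling** of pocket residues;
4. **polar-conservation filter** — at least
   `polar_conservation_fraction` of the reference pocket's polar
   side-chain groups must keep their group centroid within
   `polar_tolerance` (default 1.5 Å) of the reference position after
   pocket superposition. The reference defines "polar" via a fixed
   residue-type table; a pocket with no polar residues passes everything
   with a warning;
5. **rebuild and minimise** (static region snapped back to its reference
   coordinates, soft-sphere clash relief on the flexible region);
6. **dock** of the single refinement ligand, yielding a lower-is-better
   score.

The best-docking survivor of each round is extracted, given a fold
score, and seeds the next round; all other candidates are discarded.
Rounds in which every directory is filtered out produce no model and the
replica continues from its previous complex. The output is therefore at
most `n_replicas × n_rounds` models. Each model's dock and fold scores
are min–max normalised over the output set (1 = most favorable; a
zero-range score contributes 0.5 for every model) and combined with
equal weights; ties break by (dock score, replica, round). `top_k`
renames the leading models `LDM 000 … LDM (k−1)`.

Default capacity is 16 replicas × 20 rounds × 8 directories with a
1.0 Å pocket-RMSD cutoff and 0.8 polar-conservation fraction. These are
this package's own defaults for a production-scale run; the shipped
tests use scaled-down runs (2×3×4 for capacity/determinism checks,
1×10×10 for recovery studies) chosen so the whole suite runs on a
single CPU in minutes.

Every stage receives a seed derived by SHA-256 from
`(master_seed, replica, round, directory)`, so runs are bit-reproducible
and independent of execution order. The samplers never move the ligand;
docking re-poses it each round, which makes the first round operationally
identical to processing the receptor alone.

## Stage backends

The heavy stages sit behind a `StageBackends` contract (`bind(context)`
plus pure per-stage functions of complex and seed). The package ships
**toy backends** — seeded smooth collective displacements for backbone
sampling, small side-chain jitter, a soft-sphere steepest-descent
minimiser that excludes bonded context, a rigid-ligand dock, and a fold
score summing squared deviations of consecutive virtual Cα–Cα bonds
from 3.8 Å plus Cα soft-sphere clashes. They are intentionally simple
test engines, not reimplementations of any production sampler or
docking program.

The toy dock has two scoring modes:

* **generic** — charge-channel-matched Gaussian contact wells (anionic
  residue groups vs cationic ligand atoms, etc., ideal 3.0 Å) plus
  apolar contacts (ideal 3.8 Å), capped at one contact per protein atom,
  minus a soft-sphere clash penalty. Poses are searched by seeded random
  rigid perturbations polished with Nelder–Mead.
* **contact wells** — an explicit harmonic restraint network
  `(residue atom, ligand atom, ideal distance, weight)` supplied by the
  caller; the pose is then fitted by Levenberg–Marquardt. The synthetic
  module's `designed_contact_wells` emits such a network from a
  complex's current geometry, using ≥3 directionally diverse ligand
  partners per residue atom so that rigid per-residue translations are
  fully pinned (a single distance constraint would leave motion on the
  sphere around the partner invisible). This makes that geometry the
  strict score optimum — the "planted" target of the recovery studies.

The generic score is deliberately not used for planted-optimum tests:
its optimum is a broad degenerate manifold of pocket shapes (many
geometries realise the same contact counts), which is realistic for
docking scores but unsuitable as a ground-truth target.

## Interaction fingerprints

A fingerprint is an ordered boolean matrix over pocket residues × 8
interaction types: hydrophobic, H-bond donor/acceptor, weak H-bond
donor/acceptor, ionic positive/negative, aromatic. All criteria are
heavy-atom rules with configurable thresholds: apolar C/S pair ≤ 4.5 Å;
donor→acceptor ≤ 3.5 Å with an antecedent–donor–acceptor angle ≥ 120°
when the antecedent is resolvable (distance-only otherwise); Cα or
aromatic-carbon weak donor ≤ 3.8 Å; opposite formal charges ≤ 4.0 Å;
ring centroids ≤ 4.5 Å with interplanar angle ≤ 30° or ≥ 60° (face and
edge pooled). Protein atom roles come from fixed per-residue tables
(Asp/Glu anionic, Lys/Arg cationic; no pKa model); ligand roles from
element and formal charge, with rings detected from distance-based
connectivity. The **ionic bit is named after the ligand's charge sign**:
`ionic_negative` means an anionic ligand group contacts a cationic
residue.

Fingerprints are compared with the Jaccard distance
d_J = (C_TF + C_FT)/(C_TT + C_TF + C_FT); two all-False fingerprints are
defined to be at distance 0 (identical absence of contacts). Sets of
fingerprints are clustered by average-linkage agglomeration on the
pairwise Jaccard matrix and cut so that distances at or above the cutoff
(default 0.6) separate clusters; each cluster is represented by its
best-scoring member, ties broken by model id.

## Pocket PCA

Superimposed pockets are flattened to 3n-coordinate vectors and
decomposed by covariance PCA (no per-feature scaling — the features are
like-for-like Å coordinates). Components are ordered by explained
variance and sign-fixed so each component's largest-magnitude loading is
positive, making scores reproducible. When all pockets are identical the
total variance is zero and explained fractions are reported as 0 with an
explicit flag. All inputs passed by the caller are pooled into one
decomposition; the superposition reference is the first pocket unless
the caller aligns otherwise.

## Virtual-screening metrics

Scores follow the docking convention (lower = better; a flag flips it).
Each compound's best of k repeat scores is used for ranking; ranking is
a stable sort by (best score, compound id), so ties are deterministic.
ROC curves are stepwise over this strict ranking, recovery = actives vs
decoys, selectivity = one pharmacology class vs the other (decoys
excluded; a missing class is an error mirroring screens where
selectivity is not applicable). The normalised square-root AUC is

    NSQ_AUC = 100 · (A_sq − 1/3) / (1 − 1/3),   A_sq = ∫ TPR d√FPR

so a random ranking scores 0, perfect 100, fully reversed −50. The
sqrt abscissa weights early recovery. Enrichment factors per chemotype
cluster at library fraction f use n_top = ceil(f·N), EF =
(recovered/n_top)/(n_cluster/N), bounded by 1/f and exactly 1 for the
union of all compounds; empty clusters are flagged, not errors.

Chemotypes are complete-linkage clusters of 1 − Tanimoto over Gobbi 2D
pharmacophore point-pair fingerprints, cut at 0.5; labels are stable
under input order (ids processed sorted, clusters numbered by first
member). Racemic library preparation removes exact duplicates (canonical
isomeric SMILES) and enumerates only *unassigned* stereocenters, capped
at 2⁵ = 32 isomers per molecule (overflowing molecules pass through
unexpanded with a warning); assigned centers and tautomer states are
never touched.

## Synthetic fixtures

`make_toy_complex` builds an idealised 7-helix bundle: ideal α-helix Cα
geometry (2.3 Å radius, 1.5 Å rise, 100°/residue) on an 11 Å ring,
standard topology (odd helices run extracellular→cytoplasmic), short
generated loops including an ECL2 with a central cysteine, coarse side
chains with real PDB atom names so the fingerprint tables apply
unmodified. One residue per helix lines the pocket (Asn, Asp, Val, Ser,
Phe, Arg around the ring; the Phe one turn higher so its ring stacks
edge-on with the ligand ring above the polar tier), and an 11-atom
ligand is posed so every designed interaction sits at canonical
geometry: salt bridges at 2.9–3.1 Å, H-bonds at 3.0–3.2 Å, ring
centroids at 4.3 Å, hydrophobic contact at 3.0 Å, with a receptor–ligand
clash floor of 2.7 Å. That clean geometry is the planted optimum.

What the fixtures emulate: the region/topology bookkeeping, pocket
definition, fingerprint typing, filter behavior and the selection
dynamics of the engine. What they do not: all-atom side-chain packing,
rotamer statistics, membrane environment, real docking energetics, and
property-matched decoys. Green tests therefore demonstrate the
correctness of the orchestration, geometry and metric code — not that
refinement improves real receptor structures.

`make_screen_table` draws repeat scores i.i.d. from class-conditional
normal distributions (defaults: actives −32 ± 3, decoys −26 ± 3, three
repeats), giving a strong but imperfect screen; disjoint supports force
NSQ_AUC = 100 and identical distributions give 0 in expectation. Mean
NSQ_AUC is monotone in the class-mean separation (property-tested).

## Numerical choices

* Pocket membership boundary inclusive (d ≤ cutoff); residue order
  (chain, residue number, insertion code).
* Altloc: highest occupancy, first-in-file on ties; waters and
  unselected heteros dropped at parse time.
* Kabsch RMSD below 1e-7 is snapped to 0 (SVD noise on identical
  coordinates), so identity passes a distance filter with cutoff 0.
* Flat cluster cuts split merges at exactly the cutoff height
  (`fcluster` at `nextafter(cutoff, −∞)`).
* PCA `n_components` is clipped to n_models − 1 with a warning;
  component signs fixed by the largest-magnitude loading.
* Min–max normalisation with zero range yields 0.5 for every model.
* Emitted PDB coordinates are rounded to 3 decimals (PDB convention),
  which also makes fixture file hashes platform-stable.

## Known limitations

* The toy backends' planted-optimum recovery is a property of the
  harmonic contact-well score; the generic channel score has a
  degenerate optimum and is not expected to recover a unique geometry.
* Pocket definition from the padded ligand envelope uses fixed
  lab-frame offset directions, so membership exactly at the cutoff
  boundary is not rotation-equivariant; analyses that compare complexes
  should fix the residue list once (the CLI does).
* No mmCIF input, no protonation/pKa model, no water-mediated contacts,
  no count-valued fingerprint variants.
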