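# pocketforge

Ligand-directed binding-pocket refinement for G protein-coupled
receptors (GPCRs), with the full analysis stack used to evaluate it:
protein–ligand interaction fingerprints with Jaccard clustering, pocket
Cα PCA, and virtual-screening performance metrics.

## The problem

GPCR crystal structures are mostly inactive, inhibitor-bound
conformations, yet structure-based drug discovery frequently needs the
*agonist*-bound pocket: even sub-ångström conformational differences
bias a virtual screen toward ligands of the pharmacology that shaped
the pocket. Ligand-directed modeling refines a receptor's orthosteric
pocket around a **single known ligand** — sampling the extracellular
two-thirds of the transmembrane bundle while holding the cytoplasmic
third rigid, and selecting conformations in which the ligand docks
favorably with an intact pocket — so that a screen run on the refined
model enriches molecules resembling that ligand.

`pocketforge` implements this workflow as a library + CLI with the
heavy physics behind a pluggable backend contract. Simple, seeded *toy
backends* ship in-repo so the entire engine (replica/round/directory
orchestration, both selection filters, per-round extraction, combined
ranking) and every analysis is testable offline; production samplers
and docking engines can be plugged in behind the same interface.

## The quantities it computes

* **Interaction fingerprint (IFP)** — per pocket residue, 8 boolean
  interaction types with the ligand (hydrophobic, H-bond donor/acceptor,
  weak H-bond donor/acceptor, ionic ±, aromatic). Fingerprints are
  compared by the Jaccard distance
  *d*<sub>J</sub> = (C<sub>TF</sub>+C<sub>FT</sub>)/(C<sub>TT</sub>+C<sub>TF</sub>+C<sub>FT</sub>)
  (0 = identical interaction pattern) and clustered with a dendrogram
  cut at 0.6.
* **Pocket PCA** — covariance PCA of superimposed pocket Cα
  coordinates, components labeled with % variance explained.
* **Screening metrics** — best-of-repeats score aggregation, ROC
  recovery (actives vs decoys) and selectivity (agonists vs inhibitors),
  the normalised square-root AUC
  **NSQ_AUC** = 100·(A<sub>√</sub> − ⅓)/(1 − ⅓) with
  A<sub>√</sub> = ∫ TPR d√FPR (0 = random, 100 = perfect, −50 = fully
  reversed), and chemotype enrichment factors EF at 1/5/10 % of the
  library with pharmacophore-based chemotype clustering and racemic
  library preparation.

## Worked example

Everything below runs offline on generated fixtures:

```bash
pocketforge fixtures --seed 1 --out fixtures
printf '{"n_replicas": 2, "n_rounds": 3, "n_directories_per_round": 6}' > run.json
pocketforge ldm run --receptor fixtures/complex.pdb \
    --topology fixtures/topology.json --bw fixtures/bw_map.json \
    --config run.json --seed 3 --out models
pocketforge ldm rank --in models --top 3
```

```
  model  dock_score  fold_score  combined_score  replica  round
LDM 000  -12.142895   11.519194        0.786003        0      1
LDM 001  -12.159891   11.848748        0.718167        0      2
LDM 002  -12.005739   11.005656        0.616077        1      0
```

Two replicas × three rounds produced the maximum six models. Each row
is the best-docking complex extracted from one round; `combined_score`
is the equal-weight min–max-normalised dock+fold score (1 = best), and
the ranking interleaves replicas — the engine is a selection over
rounds, not a trajectory. Analysing the top models:

```bash
pocketforge ifp --complex models/LDM_000.pdb --complex models/LDM_001.pdb \
    --complex models/LDM_002.pdb --out ifp
pocketforge ifp-cluster --in ifp/ifp.csv --cutoff 0.6 --out clusters
pocketforge pca --complex models/LDM_000.pdb --complex models/LDM_001.pdb \
    --complex models/LDM_002.pdb --out pca
```

```
wrote ifp/ifp.csv (3 fingerprints)
1 clusters at cutoff 0.6
PC1 88.9%, PC2 11.1%
```

All three models fall in one IFP cluster (pairwise Jaccard distance
< 0.6 — they share an interaction pattern), and the first principal
component captures 88.9 % of the pocket-conformation variance among
them. Screening metrics on the generated labeled score table:

```bash
pocketforge vs --scores fixtures/screen.csv --mode recovery --out vs
pocketforge vs --scores fixtures/screen.csv --mode selectivity --out vs_sel
```

```
recovery NSQ_AUC = 86.5
selectivity NSQ_AUC = -9.5
```

The fixture screen separates actives from decoys by a 6-unit score gap
(hence strong recovery, 86.5), but gives agonists and inhibitors
identical score distributions — so selectivity is statistically random
(−9.5, near the 0 anchor). Every invocation also writes a
`manifest.json` with input hashes and resolved options.

## Layout

| module | contents |
| --- | --- |
| `pocketforge.core_model` | PDB complex I/O, pocket definition, region partition, loop trimming, Kabsch superposition |
| `pocketforge.ifp` | interaction fingerprints, Jaccard distance, clustering, representatives |
| `pocketforge.pocket_pca` | pocket-coordinate PCA and Jaccard annotation |
| `pocketforge.vs_metrics` | ROC / NSQ_AUC / EF, chemotype clustering, racemic library prep |
| `pocketforge.orchestrator` | the replica/round refinement engine and both selection filters |
| `pocketforge.backends` | the stage-backend contract and the in-repo toy backends |
| `pocketforge.synthetic` | deterministic toy receptor/ligand and screening-table generators |
| `pocketforge.cli` | the `pocketforge` command |

See `docs/methods.md` for the model, parameter defaults, numerical
conventions, and what the synthetic fixtures do and do not demonstrate.
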