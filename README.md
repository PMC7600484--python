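# tfatlas

Analysis pipeline for mammalian transcription-factor (TF) repertoires: how
many TFs a genome encodes, how families expanded and contracted along the
species tree, and how TFs that sit outside the TF-to-TF interaction network
("isolated" TFs) differ from the connected majority in lethality, orthology
and the expression of their target genes.

It is written for computational biologists studying regulatory-network
evolution. Every stage works on plain-text inputs (Newick trees,
STRING-style edge lists, TSV tables), and a synthetic-data generator with
recorded ground truth makes the whole pipeline runnable and testable
without any external downloads.

## What it computes

- **TF census** (`tfatlas.census`) — from per-protein DNA-binding-domain
  hit tables (hmmscan per-domain output or a 6-column TSV): E-value
  filtering (≤ 1e-4 by default, inclusive), best-isoform retention per
  (gene, family), species × family count matrices, per-family
  standardization to mean 1, and the fraction of family pairs whose sizes
  correlate across species (Pearson *r*).
- **Duplication-loss atlas** (`tfatlas.reconcile`) — LCA reconciliation of
  each family's gene tree with the species tree. A gene-tree node is a
  duplication iff it maps to the same species-tree node as one of its
  children; losses on an edge spanning *d* species-tree edges number *d*
  below a duplication and *d* − 1 below a speciation, each charged to the
  sibling branch where the copy disappeared. This yields per-branch
  gain/loss counts and per-species turnover: the share of a species' TFs
  that arose after the common ancestor, and the share of its lineage's TFs
  that were lost.
- **Isolated-TF classification** (`tfatlas.network`) — networks built from
  score-thresholded edge lists (combined score ≥ 0.4); TFs inside the
  largest connected component of the TF-to-TF subnetwork vs isolated TFs
  (connected to the proteome but not to the main TF component), with class
  summaries (lethality %, absence in a comparator species, degree) and the
  paired relative-difference statistic 100·|a−b|/mean(a,b).
- **Functional cartography** (`tfatlas.cartography`) — within-module degree
  z-score z_i = (κ_i − mean κ)/sd κ and participation coefficient
  p_i = 1 − Σ_s (k_is/k_i)², with the eight standard node roles
  (ultra-peripheral … kinless hub).
- **Expression contrasts** (`tfatlas.expression`) — genes typed by their TF
  partners (none / orthologous / both-species-specific / A-specific /
  B-specific) and, per organ and species, a negative-binomial regression
  log E[expression | type = C_k] = α + β_k with the no-TF-interaction type
  as reference and maximum-likelihood dispersion.
- **GO overlap curves** (`tfatlas.go_overlap`) — per GO term, the
  intersection proportion of the two species' TF sets relative to the
  average set size (equivalently the Sørensen–Dice coefficient), smoothed
  against log set size by degree-2 local polynomial (loess) regression.
- **Synthetic data** (`tfatlas.simulate`) — birth-death gene families on a
  simulated species tree, stochastic-block-model interaction networks with
  a planted isolated-TF subset, NB expression with known contrasts,
  paired GO annotations with a configurable overlap-size decay, and domain
  hit tables — all with a JSON ground-truth sidecar.

## Worked example

```sh
printf 'n_species: 10\nn_families: 24\nn_genes: 600\nn_tfs: 150\nn_modules: 3\n' > cfg.yaml
tfatlas simulate --config cfg.yaml --seed 42 --out data
tfatlas reconcile --species data/species.nwk --genetrees data/genetrees --out rec
```

prints

```
23 families: average gained 57.4%, lost 8.1%
```

— of the 24 simulated families one went extinct; averaged over the ten
species, 57.4% of extant TF copies arose from duplications after the common
ancestor and 8.1% of the copies that ever existed on each lineage were lost
(at the default duplication rate 0.3 and loss rate 0.1 per copy per unit
branch length). Then

```sh
tfatlas network --edges data/edges.tsv --tfs tfs.txt --annotations ann.tsv --out net
```

(with `tfs.txt` and `ann.tsv` extracted from `data/nodes.tsv`) prints
`98 large-component, 52 isolated, 0 without interactions` and writes the
class summary

| tf_class | n | lethal % | absent % | degree |
|---|---|---|---|---|
| large_component | 98 | 58.2 | 3.1 | 25.6 ± 4.5 |
| isolated | 52 | 5.8 | 38.5 | 21.4 ± 4.7 |

recovering the generator's planted contrast: isolated TFs are rarely
lethal when mutated but often missing in the comparator species, while
large-component TFs show the opposite pattern.

The other stages run analogously (`tfatlas census`, `tfatlas cartography`,
`tfatlas expression`, `tfatlas go-overlap`); every command is a thin
wrapper over the library functions.

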