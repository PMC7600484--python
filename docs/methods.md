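# Methods

This note records the models behind each pipeline stage, the conventions
chosen where several were defensible, and what the synthetic data do and do
not establish about real data.

## TF census

TFs are identified by profile-HMM hits of DNA-binding domains (DBDs) on
protein sequences. The pipeline takes hit tables as input (hmmscan
per-domain tabular output, or a portable 6-column TSV) and never rescores
sequences itself; an external HMMER run is the upstream step.

Conventions:

- **E-value boundary is inclusive** (keep `e_value <= 1e-4`). Search tools
  report hits *at* their threshold; the inclusive rule matches that
  semantics and is stated here because the choice at the boundary is
  otherwise invisible.
- **Isoform collapse** keeps, per (gene, species, family), the hit with the
  highest bit score, breaking ties by the lexicographically smallest
  protein id. Hits without a gene name cannot be grouped and are kept
  keyed by protein id (logged); grouping isoforms by gene name is a
  convention of this package, reasonable whenever the annotation carries
  gene symbols.
- **Multi-DBD genes count once per family they carry.** This deliberately
  lets a gene with, say, two bZIP-family domains inflate the correlation
  between those families' sizes — which is exactly the signal seen in real
  repertoires, where the few strongly correlated family pairs are driven
  by shared-domain genes rather than co-duplication.
- **Family-size correlations** are Pearson over species on raw counts.
  Standardization (each family scaled to cross-species mean 1) only
  rescales columns and leaves Pearson r unchanged, so either input gives
  the same pair fraction. Zero-variance families have undefined r and are
  excluded from numerator and denominator alike.

## Duplication-loss reconciliation

Gene trees are taken as given (tree inference and any bootstrap-guided
rearrangement of weak branches are upstream of this package). Each gene
tree is embedded in the rooted binary species tree by the LCA mapping
M(v) = LCA of the species below v, computed bottom-up. Events:

- v is a **duplication** iff M(v) = M(c) for a child c; the event is
  charged to the species-tree branch above M(v). The LCA embedding
  minimizes the duplication count, and among duplication-minimal
  embeddings also the loss count; the test suite verifies both against a
  brute-force enumeration of *all* valid embeddings — exhaustively for
  every labeled gene-tree topology with up to 4 leaves over a 3-species
  tree, and on random 5–6-leaf cases.
- On a gene-tree edge (u, v) spanning d species-tree edges there are d
  **losses** if u is a duplication and d − 1 if a speciation. Each loss is
  charged to the *sibling* branch at which the lineage failed to survive.
  This sibling-assignment makes copy number exactly conservative: for
  every species X, extant copies = 1 (origin copy) + duplications −
  losses along the origin-to-X path. That identity is asserted on every
  simulated replicate.
- The **family origin** is the species-tree node the gene-tree root maps
  to. A family absent from part of the tree because of losses near the
  root maps below the root; species outside the origin clade simply never
  carried the family and are excluded from its turnover bookkeeping.
  Duplications mapping to the species root are "pre-divergence" and are
  reported on a synthetic root branch.

Turnover per species X:

- `gained_pct`: share of X's extant copies created by a duplication
  strictly below the species root. At each duplication one child lineage
  continues the parental copy and the other starts the new copy; the
  second child in tree order is taken as the new copy. Any fixed
  convention gives the same per-species counts whenever both daughter
  lineages survive in the same species sets; the convention only matters
  in edge cases after loss, and it is applied deterministically.
- `lost_pct`: losses on the root-to-X path divided by all copies that ever
  existed on that lineage (origin copy + path duplications; equivalently,
  extant + path losses, by conservation). The alternative denominator
  `extant` divides by today's copies instead and can exceed 100% under
  heavy loss; both are available (`--turnover-denominator`).

The per-branch atlas reports raw sums over families, each branch's share
of all events tree-wide, and a per-family-normalized share (families are
first normalized to total 1, then averaged), since with very uneven family
sizes the two weightings answer different questions.

## Network classification

Edges are read from STRING-style lists; integer scores on the 0–1000 scale
are divided by 1000, and the confidence threshold (default 0.4, medium
confidence) is inclusive. Self-loops are dropped, reciprocal duplicates
collapsed.

"Isolated TF" follows the component definition: a TF with at least one
interaction of any kind that is *not* in the single largest connected
component of the TF-to-TF subnetwork. This includes small TF-TF components
(pairs, triples) as well as TFs whose partners are all non-TFs — a wider
set than "no TF-TF interactions", and the one that matches how isolated
sets behave in curated networks. TFs with no interactions at all are a
third bin, excluded from both classes but reported, because absence from
an interaction database is missing evidence rather than evidence of
isolation. A tie for the largest component raises by default (it signals
the network is too fragmented for the dichotomy to be meaningful);
`tie_break='lexicographic'` forces a deterministic choice.

Class summaries treat annotation flags as tri-state; unknowns leave both
the numerator and denominator. The relative difference of paired counts is
100·|a − b|/((a + b)/2), bounded by 200%, with both-zero pairs excluded.
Lethality and ortholog-absence flags are input annotations: keyword
searches of phenotype databases are upstream curation, not pipeline
computation.

## Cartography

Within-module degree z uses the **population** standard deviation of κ
over the module, matching the cartography literature; a module with
constant κ carries no ranking signal, so σ = 0 yields z = 0 rather than a
division error. p = 1 − Σ_s (k_is/k_i)² with k_i the total degree;
degree-0 nodes have undefined p (NaN) and land in role 1 ("no
experimental interactions"). Role boundaries are lower-bound inclusive;
the kinless-hub role additionally requires z ≥ 2.5 so hub and non-hub
roles partition the (z, p) plane without overlap — without that extra
bound, p ≥ 0.75 alone would double-classify high-participation non-hubs.

Module detection uses deterministic greedy modularity maximization
(Clauset–Newman–Moore, via networkx). The original cartography protocol
used simulated annealing; a deterministic optimizer was preferred here for
reproducibility, and a precomputed assignment file can be supplied to use
any external detector. The `seed` parameter exists for interface stability
and is unused by the greedy optimizer.

## Expression contrasts

Gene types derive from the TF partners of each orthologous gene in the two
species' networks, in a shared ortholog namespace: no partners →
reference; all partners orthologous → orth_TF; species-specific partners
in both species → spec_TF_HM; in one species only → spec_TF_H / spec_TF_M.
Mixed profiles resolve with the precedence HM > H/M > orth (a gene with
specific partners on both sides is "both-specific" even if it also has
orthologous partners); the precedence is a convention of this package.

The regression is an NB2 GLM with log link, gene type as the sole
categorical covariate, and jointly ML-estimated dispersion (statsmodels
`NegativeBinomial`; the reported θ is 1/α_NB2, variance μ + μ²/θ). TPM
values are continuous, so they are rounded to the nearest integer for the
count likelihood (`nb_input='rounded'`; `'raw-counts'` validates
integer input instead). The fit is cross-checked in the test suite against
R's `MASS::glm.nb` on identical data (coefficients agree to < 2e-3).
TPM renormalization (`tpm_normalize`, columns to 1e6) is available but not
applied implicitly: no cross-species rescaling is performed beyond TPM.

## GO overlap

q = |A∩B|/((|A|+|B|)/2) per term, identical to Sørensen–Dice (asserted as
a cross-check). Unmapped comparator-species TFs keep their own identifier:
they contribute to set size but can never intersect, which
underestimates rather than overestimates overlap. The smoother is local
polynomial regression of q on log mean size: degree 2, tricube weights
over the ⌈span·n⌉ nearest points, span 0.75 by default, predictions
clipped to [0, 1]. It reproduces constants and quadratics exactly and is
order-invariant. No GO-hierarchy propagation is performed; terms are
compared as annotated.

## Synthetic data: what it emulates, and what it does not

- **Species tree**: pure-birth (Yule) with ultrametric tips, terminal
  edges padded by a constant so no tip branch has zero length. Defaults:
  12 species (16 in the acceptance run, 96 being the realistic mammalian
  scale but unnecessary for testing the algebra).
- **Gene families**: one origin copy at the root; along every branch each
  copy duplicates at rate 0.3 and dies at rate 0.1 (events per copy per
  unit branch length), simulated in continuous time; copies split at
  speciations. These rates give mammal-like turnover — roughly half of a
  species' repertoire post-dating the root and ~10–15% of lineage copies
  lost — while keeping families small enough that reconciliation is
  exactly checkable. True events are recorded per branch, so duplication
  recovery (exact when loss is absent) and copy-number conservation are
  testable per replicate.
- **Interaction network**: stochastic block model, 1200 genes in 4
  modules, p_in = 0.12, p_out = 0.01; 300 TFs spread evenly over modules;
  a planted third of the TFs made isolated by deleting their TF-TF edges
  (each keeps ≥ 1 TF–non-TF edge). Scores are STRING-style integers:
  structural edges 400–999, plus ~5% sub-threshold noise edges (150–399)
  that exercise the score filter. Lethality/absence flags are drawn at
  48.8%/3.8% for connected and 5.0%/36.7% for isolated TFs — the contrast
  magnitudes reported for curated human TF annotations — so class
  summaries on synthetic data resemble real ones.
- **Expression**: NB counts with α = log 50, β = (0.5, 1.0, −0.5, 0.25)
  for the four non-reference types, θ = 2, 2000 genes per type, five
  organs, two species. β of this size (±0.25–1 on the log scale) spans the
  range typically seen in organ-level contrasts; θ = 2 is strong
  overdispersion, the harder regime for the fitter.
- **GO annotations**: term sizes log-uniform on [5, 400]; a term of size s
  shares m ~ Binomial(s, s^(−decay)) orthologous TFs, the rest
  species-specific; the default decay puts the expected overlap at 0.5 for
  terms of size 100, mimicking the empirical pattern that small terms are
  regulated by mostly-orthologous TFs and large ones are not.

Passing tests on these data show the *algorithms* are correct (exact
recovery, conservation laws, closed forms) and that the *estimators*
recover planted parameters at realistic sizes. They do not show anything
about annotation quality, incomplete interactomes, gene-tree estimation
error, or cross-species expression normalization — all of which affect
real analyses upstream of this package. In particular the generator plants
no correlation between a TF's network isolation and its families' gain/loss
history; the pipeline measures such associations, it does not assume them.

## Problem sizes and numerics

The default test-and-acceptance sizes (16-species trees, 48 families,
1200-node networks, 10 000-observation NB fits, 2000 GO terms) were chosen
so the full suite runs in seconds while every statistical check retains
comfortable margins. The brute-force reconciliation oracle enumerates all
valid embeddings, which is exponential; it is applied exhaustively to ≤
4-leaf gene trees and by sampling at 5–6 leaves. NB fitting uses
statsmodels' Newton-type optimizer (up to 200 iterations); the loess
solver uses `numpy.linalg.lstsq` on the weighted Vandermonde matrix, with
weights floored at 1e-12 to keep degenerate windows full-rank.

## Known limitations

- Reconciliation assumes rooted binary trees; polytomies are only handled
  by seeded random resolution, and transfer events (DTL) are out of scope.
- The greedy modularity optimizer can split or merge modules near
  resolution limits; planted-module recovery is checked statistically
  (≥ 95% agreement), not exactly.
- The per-leaf "new copy" convention after losses is one of several
  defensible bookkeeping rules; alternatives change per-species gained
  counts only in post-loss edge cases.
- The loess implementation matches the standard tricube/nearest-neighbor
  definition but is not a bit-for-bit reimplementation of any particular
  statistical package's interpolation surface; it is evaluated directly at
  each requested point.
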