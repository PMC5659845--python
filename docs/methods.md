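# Methods

## The analysis in one paragraph

`coexnet` organises a transcriptional response into coordinately regulated
gene clusters without computing any correlation itself.  Replicate log2
differential-expression values are averaged per gene; the top n genes per
direction (up, down) form hit lists; a precomputed coexpression database
(gene → top-K coregulated partners with pair multiplicities) supplies the
clustering prior.  For every hit found in the database, all (K+1)×(K+1)
ordered pairs over its neighborhood — the hit plus its K partners — are
enumerated as connection slots; a slot becomes an undirected weighted edge
only when both members are hits.  The resulting network is validated three
ways: connectivity against random gene lists, a rank-sum prediction score
(CoRegScore) for the non-hit genes most connected to the hits, and, per
cluster, a rank-sum regulation score (UpRegScore) in this and other
experiments.  Cluster membership can finally be compared against a
genome-wide transcription-factor target ranking split into an upregulated
(Class I) top block and a downregulated (Class II) bottom block.

## The two rank-sum statistics

Let a ranking place all G genes at 1-based positions, position 1 the most
upregulated.  For an evaluated gene set with position sum `real`, and
reference sums `best` and `worst`,

    score = 100 − 200 · (real − best) / (worst − best).

* **UpRegScore** of a set of n ranked genes: `best = 1 + … + n`,
  `worst = (G−n+1) + … + G`.  100 means the set occupies the very top of
  the ranking, −100 the very bottom, 0 is the random expectation.
* **CoRegScore** of m predicted genes relative to an n-hit block:
  `best = (n+1) + … + (n+m)` (a perfect prediction fills the positions
  immediately below the hit block), `worst` the bottom m positions.

Genes absent from a ranking are omitted and both reference sums are
recomputed with the reduced n; no penalty position is imputed.  Positions
are 1-based — this is what makes the extremes land exactly on ±100.
One deliberate departure from a strict [−100, 100] range: when an evaluated
gene outranks the ideal block (possible for random-control hit lists whose
"ideal" block is defined against a hypothetical hit block they do not
occupy), the formula exceeds 100 and is reported as computed.  Clamping or
rejecting such lists would censor the upper tail of the null distribution
and overstate significance.

## Significance

Observed scores and connectivity metrics are calibrated against 100 random
gene lists of the same size drawn uniformly without replacement from all
genes in the expression table; each list runs through the identical
analysis.  The report gives the null mean and sample standard deviation,
the Z-score, and a one-tailed normal p (upper tail for upregulation and
enrichment, lower for downregulation), plus an empirical tail rank as a
secondary output.  No multiple-testing correction is applied across
clusters; p-values are raw by design and should be read accordingly.
Small gene lists (below ~20 genes) have visibly wider nulls, so their
scores carry less significance at the same magnitude.

## Network details

* `considered_pairs = |hits with a DB entry| · (K+1)²` counts enumerated
  slots whether or not an edge is materialized; 250 hits at K=40 give
  420,250.  Hits missing from the database stay as isolated nodes flagged
  `-`.
* Edge weights: within one neighborhood, a pair contributes the product of
  the two members' multiplicities (the neighborhood's own hit counts 1);
  weights sum over all neighborhoods containing the pair.  With all
  multiplicities 1 this reduces to counting neighborhoods.  The product
  rule is a modelling choice — the source databases do not specify how two
  multiplicities combine.
* Predicted genes: the m non-hit genes with the largest summed
  multiplicities across hit neighborhoods, m = 50 by default; ties break
  lexicographically, as everywhere in the package.
* Clusters: connected components of at least `min_size` (default 3) nodes,
  numbered by decreasing size.  With `refine_clusters` the components are
  split further by weighted greedy modularity maximisation; unassigned
  nodes adjacent to two or more numbered clusters get a `+`-joined label
  (e.g. `1+2`).  Curated assignments can be forced through an override
  file.  Refinement matters whenever random hit-to-hit collisions fuse
  distinct programs into one giant component — the modularity split then
  recovers the heavy-edged planted modules.

## Defaults

| parameter | default | rationale |
|---|---|---|
| n_hits | 250 | hits retained per direction |
| K | 40 | partners per gene from the database (100 for sparse, proteome-style hit lists) |
| m_predicted | 50 | prediction block just below the hit list |
| n_null_lists | 100 | random lists per null distribution |
| min_cluster_size | 3 | smallest component reported as a cluster |
| seed | 1 | mandatory; all sampling flows from it |

Standard deviations everywhere use the sample (n−1) estimator, with sd = 0
by convention for a single replicate.  Non-protein-coding genes are
dropped *after* the top-n truncation and the list is not refilled.  The
five node-color bins use thresholds ±0.25 and ±1 on the mean log2
difference, boundary values assigned to the weaker bin.

## The synthetic world

The generator replaces microarray downloads and the partner database with
a ground-truthed world: G genes, disjoint planted modules with per-module
regulation effects (a mean log2 shift, possibly different per experiment
so clusters can be shared or unshared between experiments), Gaussian
replicate noise, an optional per-replicate response-strength multiplier,
per-experiment missing-gene masks, and a consistent partner database in
which a member's K slots hold co-members with probability f (the module's
coexpression fidelity) and uniform random genes otherwise; multiplicities
are uniform on 1..3.

A module may carry a *halo*: genes that share the module's coexpression
pool but respond at only a fraction (default 0.5) of the core effect.
This mirrors how real transcriptional programs behave around an arbitrary
hit cutoff — coexpressed genes with weaker induction rank just below the
strongest hits — and it is what gives the prediction score something real
to find: a world whose regulated genes are all inside the hit list leaves
nothing for CoRegScore to predict.

Two presets: a 2,000-gene world (three 60-gene modules with 50-gene
halos; sub-second tests) and a genome-scale world of 26,959 genes with a
single 60-gene module (effect +3, noise sd 1, fidelity 0.9, 100-gene
half-effect halo) analysed with 250-gene hit lists at K=40.  At the
genome-scale preset the pipeline recovers ≥ 90% of the planted module in
the top-250 hits, the planted network is essentially fully connected
while random same-size lists are mostly isolated, and the prediction
score sits far above its 100-list null.

What the world does **not** emulate: probe-level noise and normalisation
artifacts, correlated (non-independent) noise across genes, scale-free
degree structure in the partner database (non-module partners are
uniform), or biased missingness.  Passing tests therefore demonstrate the
pipeline's arithmetic and its statistical behaviour under a clean planted
model, not performance on any real compendium.  One regime note: in small
universes (G ≈ 2,000) a 250-gene hit list covers an eighth of the genome,
so uniform partner lists make even random hit lists look well connected —
the inclusion percentage saturates and only the summed connection weights
separate planted from random.  The genome-scale preset does not have this
problem.

## Numerical and degenerate-input conventions

* Ranking ties break by lexicographic gene id; determinism is required
  for byte-identical reruns.
* Scores are undefined (rejected, and dropped with a count inside null
  estimation) when no evaluated gene is ranked, and when `best = worst`
  (the ranking has no room to distinguish placements).
* A null with zero standard deviation is a hard error for the Z-test.
* Missing replicate values are skipped per gene; all-missing genes are
  excluded from summaries with a warning.
* All emitters and the pipeline are pure functions of (parameters, seed);
  manifests carry no timestamps so reruns are byte-identical.

## Known limitations

* Cluster assignment substitutes a deterministic rule (components +
  optional modularity refinement) for what is, in interactive practice, a
  manual grouping over a force-directed layout; override files exist to
  inject curated labels.
* The binomial enrichment test treats cluster genes as independent draws;
  coexpressed genes are not independent, so its p-value is optimistic for
  tightly coexpressed clusters.
* The normal-tail p assumes the 100-list null is adequately Gaussian;
  the empirical tail rank is reported alongside for skeptics.
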