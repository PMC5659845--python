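# coexnet

Coexpression-network clustering and rank-sum regulation scoring for
differential-expression hit lists.

## What it does, and for whom

Given a gene × replicate table of log2 expression differences (e.g. the
output of RMA-normalised microarrays or a quantitative proteomics
comparison), `coexnet` organises the strongest-responding genes into
coordinately regulated clusters using a *precomputed* coexpression
database — a mapping from each gene to its top-K coregulated partners
across many public experiments (modSEEK/SPELL/COXPRESdb style).  It is
aimed at systems-biology analyses that need to split a hit list into
independent transcriptional programs, validate that split statistically,
and ask whether the same programs move in other experiments or under a
particular transcription factor.

The pipeline: average replicates → rank genes → take the top-n per
direction (protein-coding only) → enumerate, for each hit, the
(K+1)×(K+1) connection slots over its database neighborhood → keep
hit-to-hit edges weighted by pair multiplicity → clusters, connectivity
statistics, Cytoscape-ready SIF/attribute export.  Validation uses two
rank-sum statistics on the genome-wide expression ranking (1-based
positions, `real`/`best`/`worst` position sums):

```
score = 100 − 200 · (real − best) / (worst − best)
```

* **CoRegScore** — how well the non-hit genes most connected to the
  network ("predicted" genes) rank just below the n-hit block:
  `best = Σ(n+1 … n+m)`, `worst` = bottom m positions.  100 = perfect
  prediction, −100 = worst possible.
* **UpRegScore** — how far toward the top of an experiment's ranking a
  gene set (typically one cluster) lies: `best = Σ(1 … n)`.  100 = the
  set occupies the very top, −100 = the very bottom.

Both are calibrated against 100 same-sized random gene lists run through
the identical analysis (null mean, SD, Z-score, one-tailed p).  A
genome-wide target ranking with Class I (top, factor-upregulated) and
Class II (bottom, factor-downregulated) blocks supports enrichment tests
of each cluster via an exact binomial test against the genome-wide target
fraction.

A fully ground-truthed synthetic-world generator (planted coexpression
modules with tunable fidelity, effects, halos, replicate noise, missing
genes) makes every stage testable without any download; see
`docs/methods.md`.

## Worked example

Genome-scale synthetic world: 26,959 genes, one planted 60-gene module
(effect +3, replicate noise sd 1, coexpression fidelity 0.9) with a
100-gene half-effect halo; 250-gene hit list, K = 40.

```python
import coexnet as cx
from coexnet.significance import significance as calc_significance

world   = cx.generate_world(cx.paper_scale_params(), seed=1)
db      = cx.emit_partner_db(world)
table   = cx.emit_expression(world, "main")
ranking = cx.rank_genes(cx.average_replicates(table), "up")
hits    = cx.select_hits(ranking, 250, table.coding)

core = set(world.members("up_module"))
print("module recovery:", len(core & set(hits.genes)) / len(core))

predicted, _ = cx.predict_genes(hits, db, 50)
obs = cx.co_reg_score(predicted, ranking, n_hits=250).score

def null_metric(genes):
    rpred, _ = cx.predict_genes(genes, db, 50)
    return cx.co_reg_score(rpred, ranking, 250).score

null = cx.null_distribution(
    null_metric, cx.random_gene_lists(world.genes, len(hits), 100, seed=3)
)
res = calc_significance(obs, null)
print(f"CoRegScore {obs:.1f}, null {null.mean:.1f}±{null.sd:.1f}, "
      f"z={res.z:.1f}, p={res.p:.1e}")
```

prints

```
module recovery: 0.9833333333333333
CoRegScore 82.3, null 3.0±8.5, z=9.3, p=5.6e-21
```

98% of the planted module is pulled back out of the 27k-gene universe by
plain hit selection, and the network's predicted genes rank far better
(score 82) than predictions from random gene lists (3.0 ± 8.5) — the
planted transcriptional program is both recovered and validated.  The
same world gives a planted-module network with 100% hit inclusion versus
~14% for random same-size lists.  Cluster-level regulation profiling
across experiments behaves the same way: in the small test world a module
planted as upregulated in two experiments scores UpRegScore 96 and 100 in
them, while a module private to one experiment scores −7 in the other.

The full pipeline is also available from the shell:

```sh
coexnet synth --config world.yaml --out-dir inputs/ --seed 1
coexnet run   --config run.yaml
coexnet score upreg --set cluster1.txt --ranking expression.tsv
```

`coexnet run` writes per-direction networks (`.sif`, edge/node attribute
TSVs), significance reports, the cluster × experiment UpRegScore profile,
target-class enrichment, and a `manifest.json`; identical configs and
seeds reproduce byte-identical outputs.

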