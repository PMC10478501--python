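# hybridaction

Additive vs dominant gene action in parent–F1 hybrid transcriptome panels.

When two *Arabidopsis thaliana* accessions are crossed, each gene's
expression in the F1 can sit at the mid-parent value (MPV, the arithmetic
mean of the parental log₂ TPM — **additive** gene action) or deviate
systematically toward one parent (**dominant** gene action, in hybrids
overwhelmingly *below* the MPV).  This package implements the full
statistical pipeline for panels of many parent–parent–F1 trios:

* **Additive calling** — per gene, ordinary least squares of the F1
  expression value on the MPV across trios; additive if slope > 0.5 and
  R² > 0.4 (or, in the treatment/batch-corrected mixed-model design,
  slope > 0.4 and residual σ < 0.6).
* **Dominant calling** — per gene, a population-wide MPV null is built
  from the arithmetic means of all C(n, 2) pairwise combinations of
  inbred accessions, and a two-sided two-sample Kolmogorov–Smirnov test
  asks whether the F1 values were drawn from it; Benjamini–Hochberg
  q < 0.001 calls dominance, with direction (above/below MPV) from the
  median difference and a signed-D dominance score.
* **Size covariation** — k-means clustering of dominant genes and a linear
  mixed model per cluster, `GeneExpression ~ IsHybrid + ns(Size) +
  ns(Size):IsHybrid + (IsHybrid | LibraryBatch)`, with 95% credible
  intervals from 10,000 draws of the approximate posterior.
* **Treatment response** — per gene,
  `GeneExpression ~ Treatment * IsHybrid + (1 | PlantBatch)` with an
  empirical p-value from permuting treatment labels within plant batch
  (default 10,000 permutations), BH-corrected.
* **Heterosis covariation classes** — per-trio expression MPH
  (F1 − MPV) and rosette-size MPH, per-gene natural-cubic-spline curves of
  size MPH against expression MPH, Dunn-index-constrained two-round
  clustering, sorting into positive/negative/quadratic/none classes per
  treatment, and the extreme-sample Wilcoxon validation procedure.
* **Rare-allele burden** — counts of rare (MAF < 0.05) SNPs in strand-aware
  1 kb upstream windows per accession (F1 = parental mean), their relation
  to expression rank (LOWESS trends, top/bottom-decile Wilcoxon) and to
  hybrid growth advantage, plus SNP Hamming genetic distances.
* **Synthetic panels** — a generator that plants all of the above
  structures (additive/dominant fractions, cis alleles, treatment and
  batch effects, size model, rare-allele burdens) with a ground-truth
  table, so every stage is verifiable without the original sequencing
  data.

## Worked example

```python
from hybridaction import (SimConfig, simulate_panel, center_nuisance,
                          DominanceModel, AdditiveModel)

panel = simulate_panel(SimConfig(n_genes=1000, n_inbreds=40, n_trios=25,
                                 seed=7))
adj = center_nuisance(panel.expression, panel.meta)

dom = DominanceModel(adj, panel.meta, panel.trios).fit()
print(dom.summary())
```

```
Dominance calls (two-sample KS vs pairwise-MPV null)
  genes tested: 1000   null size: 780 pairs, 25 F1 values per gene
  dominant (q < 0.001): 80
  below MPV: 75 (93.8% of dominant)
```

With 40 inbred accessions the null holds 780 pairwise MPVs per gene; 80
genes reject it at q < 0.001 and 93.8% of them sit below the MPV — the
hallmark asymmetry of expression dominance in these hybrids.  Against the
panel's truth table, 75 of the 80 planted dominant genes are recovered.
The regression screen on the same panel:

```python
add = AdditiveModel(adj, panel.meta, panel.trios).fit()
print(add.summary())
```

```
Additive gene-action calls (SHB1 design)
  genes tested: 1000
  thresholds:   slope > 0.5, r2 > 0.4
  called additive: 141 (14.1%)
```

(The 141 regression hits include the uniformly shifted dominant genes —
slope 1 at a constant offset — which is why `call_gene_action` gives
dominance precedence when it assigns the final per-gene verdict.)

The command line mirrors the stages:

```bash
hybridaction simulate --out panel/ --seed 1
hybridaction call-action --expr panel/expression_log2.tsv \
    --trios panel/trios.tsv --samples panel/samples.tsv --out calls/
hybridaction run --config pipeline.yaml      # all stages + manifest
```

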