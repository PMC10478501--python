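# Methods

This note documents the statistical models behind `hybridaction`, the
defaults and why they were chosen, what the synthetic panels do and do not
emulate, and the numerical decisions that affect results.

## Working scale and preprocessing

All tests operate on log₂(TPM + 1).  The pseudocount of 1 on the TPM scale
is configurable; it exists because zeros occur in real abundance matrices.
Gene filtering removes organellar compartments (ChrC/ChrM), rDNA,
transposable elements, pseudogenes and transcripts with effective length
below 150 nt, then re-estimates TPM over the survivors so every sample sums
to 10⁶.  Sample filtering removes libraries under 2 × 10⁶ mapped reads and
whole-transcriptome PCA outliers, operationalised as more than 4 SD from
the centroid on PC1 or PC2 of the gene-centred log₂ matrix ("extreme
outlier" needs a reproducible rule; 4 SD keeps only gross failures).
The summary-statistic filter keeps genes with trimmed mean log₂ > 0.3
(10% trimmed from each tail by default; the trimming fraction is not
dictated by the thresholds themselves and is exposed as `trim_frac`) and
coefficient of variation > 0.15.  CV is computed on the log₂ scale — the
same scale as the mean filter; computing it on linear TPM would retain a
different gene set, and the choice is exposed so users can compare.  All
threshold comparisons are strict inequalities.  Filters are idempotent and
outputs are sorted by identifier, so reruns are byte-stable.

## Additive calling

For each gene, the mid-parent value MPV = (log₂ parent A + log₂ parent B)/2
is computed per trio, and the F1 value is regressed on the MPV across
trios (≥ 3 complete trios required; incomplete trios are dropped per gene,
never imputed).  The simple design ("SHB1") calls additive at slope > 0.5
and R² > 0.4; the treatment/batch design ("SHB2") regresses per-sample F1
values on the same-treatment MPV with a fixed treatment effect and a
random intercept per plant batch (statsmodels MixedLM), calling additive
at slope > 0.4 and residual σ < 0.6.  With a single batch or treatment
level, SHB2 degrades to fixed effects with a logged warning; per-gene
convergence failures fall back to OLS.  `intersect_common_additive` gives
the genes called in both designs.

## Dominance calling

The dominance null for a gene is the multiset of arithmetic means of log₂
expression over all C(n, 2) unordered pairs of distinct inbred accessions
— the distribution an additive F1's value would be drawn from if its
parents were a random pair.  A two-sided two-sample Kolmogorov–Smirnov
test compares the F1 values to this null; BH-adjusted q < 0.001 calls
dominance.  The exact two-sample KS distribution is used when
n_F1 × n_null ≤ 10⁴, the asymptotic one otherwise.  Direction is the sign
of median(F1) − median(null); an exact tie is classified below-MPV (the
majority class) with a logged flag.  The dominance score is the KS D
signed by direction; a perfectly additive gene scores 0 in expectation and
additive genes rank below dominant genes when sorted by |score|.

Two package-level choices matter for power and calibration:

* **Nuisance centering.**  Before calling, per-gene mean offsets of
  library batch, plant batch and the treatment main effect are removed
  (`center_nuisance`).  This leaves genotype-level signal untouched — a
  treatment or batch effect shifts parents and F1s alike and is pure
  noise for the F1-vs-MPV comparison — and lets genotype means pool all
  replicate samples across both arms, roughly halving their noise.
* **Dominance precedence.**  `call_gene_action` assigns one verdict per
  gene: dominant if the KS test rejects, else additive if the regression
  screen passes, else neither.  A gene whose F1 sits at a constant offset
  below the MPV has slope 1 and high R², so the regression screen alone
  cannot distinguish additive from uniformly dominant genes; the KS test
  is the instrument that does.

A Fisher combination of per-treatment-arm KS tests was evaluated and
rejected: the two arms share the genotype-level deviations of the same
F1s, so the arm p-values are strongly dependent and the combination is
anti-conservative.

## Size-covariation splines

Dominant genes are clustered by k-means on per-gene z-scaled profiles
(25 restarts, fixed seed; k = 13 reproduces the study-scale choice, and
`k='auto'` takes the elbow, defined as the k maximising the second
difference of the within-cluster sum of squares over k ∈ [2, 25]).  Each
cluster's mean expression is modelled as

    GeneExpression ~ IsHybrid + ns(Size, df=4) + ns(Size, df=4):IsHybrid
                     + (IsHybrid | LibraryBatch)

with GeneExpression the z-scaled log₂ values, Size the z-scored rosette
area (mm²), and ns() a natural cubic spline (df = 4, knots at size
quantiles as placed by the basis).  The random structure degrades
(IsHybrid | batch) → (1 | batch) → none whenever the optimizer fails to
converge or the coefficient covariance is ill-conditioned; every
degradation is logged.  95% credible intervals are percentile intervals
over draws from the multivariate-normal approximation to the posterior at
the fitted optimum (default 10,000 draws) — a normal approximation, not
MCMC; singular covariances fall back to an eigenvalue square root.

Because the spline-by-hybrid interaction basis is not centred, the raw
IsHybrid coefficient is the hybrid offset only where the basis vanishes.
`SizeSplineResults.hybrid_effect()` therefore reports the identifiable
quantity: the mean hybrid-minus-inbred fitted difference over the observed
size distribution.  Note that a *natural* cubic basis reproduces linear
signals exactly but not general cubics (its second derivative is pinned to
zero at the boundary knots); the exact-reproduction guarantee is
accordingly stated, and tested, for signals of degree ≤ 1.

Per-cluster size correlations (Pearson r of cluster-mean expression with
rosette area) should be computed within one treatment arm — the treatment
itself changes plant size several-fold and otherwise dominates r.

## Treatment response

Per gene the model is `GeneExpression ~ Treatment + IsHybrid +
Treatment:IsHybrid + (1 | PlantBatch)` and the test statistic is the
Gaussian likelihood-ratio for dropping both treatment terms.  The default
engine absorbs the plant-batch intercepts as fixed effects, which makes
the statistic a pair of least-squares projections that vectorise across
genes; 10,000 permutations of a whole panel stay tractable on one core.
A per-gene MixedLM engine is available (`engine="mixed"`); since the null
distribution is generated by permutation, the empirical p-value is valid
for either statistic, and the fixed-effect statistic is the one the
permutations actually recompute.

Permutations shuffle treatment labels within plant batch, preserving each
batch's label multiset; batches carrying a single treatment level are
unpermutable and left fixed with a warning.  The empirical p uses add-one
smoothing, p = (1 + #{null ≥ observed}) / (B + 1), so p ∈ [1/(B+1), 1] and
BH is well-defined.  Two caveats follow from the design rather than the
implementation: (i) with strong genotype effects the within-batch
permutation is conservative, because observed labels are balanced within
genotype while permuted ones are not; (ii) library-batch effects are
shared across genes, so a single realised treatment–batch alignment shifts
all genes' statistics coherently — per-gene p-values remain calibrated,
but cross-gene uniformity diagnostics must use batch-free null data.
Note that q < 0.001 is attainable only when B is large relative to the
number of discoveries (p_min = 1/(B+1) must undercut the BH line); with
the default B = 10,000 this is unproblematic, with heavily scaled-down B
it is not.

## MPH covariation classes

Expression MPH (F1 log₂ value − MPV) and size MPH (F1 area − mid-parent
area, mm²) are computed per trio, treatment and replicate, members matched
by (genotype, treatment, replicate).  Per gene and treatment, a natural
cubic spline (df = 3) of size MPH on z-scored expression MPH is fitted and
evaluated on a fixed grid of 7 points spanning z ∈ [−1.2, 1.2]; the grid
evaluation expresses every gene's curve in one common basis (a fixed
linear transform of the spline coefficients), making curves directly
comparable for clustering.  Genes with degenerate expression-MPH spread
(range < 10⁻⁸) are dropped.

Clustering is two-round k-means on the mean-centred curves: the k-scan
picks the highest Dunn index subject to the rule that at most 25% of
clusters hold fewer than 5% of the genes (unconstrained Dunn maximum as a
logged fallback); clusters labelled none-none are removed and the
survivors re-clustered identically.  Class labels replace the original
study's manual curation with a reproducible rule: with δ = 0.25 × SD of
size MPH (configurable), a cluster-mean curve is *positive* if its
endpoint difference exceeds +δ with no step below −δ/4, *negative*
symmetrically, *quadratic* if the midpoint deviates from the chord by more
than δ with near-equal endpoints, else *none*; the class is the mock label
joined to the BTH label.  The vocabulary is the full 4 × 4 product of
per-treatment labels (a given dataset typically populates only part of
it).

The validation test takes, per gene, the mean size MPH of the `n_extreme`
(default 4; a decile mode is available) records with the lowest and
highest expression MPH and compares them across the genes of a cluster
with a Wilcoxon signed-rank test — one-sided in the labelled direction for
monotone clusters, two-sided for none, and two one-sided tests of each
extreme against the median-expression group for quadratic clusters (the
direction taken from the sign of the mid deviation).  The exact signed-rank
distribution is used up to 25 nonzero pairs, the continuity-corrected
normal approximation beyond; zero differences are removed (Wilcoxon's
method), and an all-zero cluster reports p = 1 with a degenerate flag.
Bonferroni correction spans all tests performed (one per monotone cluster
per arm, two per quadratic).

Cliff's delta is (#{aᵢ > bⱼ} − #{aᵢ < bⱼ}) / (|a||b|), computed via sorted
binary search and verified against O(nm) brute force.

## Rare-allele burden and genetic distance

The upstream window is strand-aware and excludes the TSS: positions
[TSS−1000, TSS−1] for + genes and [TSS+1, TSS+1000] in genomic coordinates
for − genes.  Rare sites are biallelic SNPs with MAF < 0.05 (an INFO MAF
field is preferred when present, otherwise panel MAF); burden counts sites
at which the accession carries at least one alternate allele (a dosage
mode sums alleles instead).  F1 burden is exactly the mean of the two
parental counts.  Missing genotype calls count as reference and are
logged.

Rank profiles: within a stratum (inbreds or F1s × mock or BTH), samples
are ranked per gene by expression (average ranks for ties; constant genes
excluded), per-rank burdens are averaged across the gene list, the trend
is LOWESS-smoothed (span 0.5, 2 robustness iterations), and burdens in
the top and bottom expression-rank deciles are compared with a
Mann–Whitney rank-sum test (the deciles are independent groups, so the
rank-sum form is the deliberate reading of the procedure).  Because these
are rank statistics, the whole profile is invariant to monotone
transforms of expression.

For the growth-advantage analysis, F1s are ranked by the *gene-list
average* of the mean parental rare-allele count and the Pearson r between
the rank-ordered burden and size-MPH profiles is reported.  Ranking by
single-gene burdens was evaluated and rejected: upstream burden is sparse
(mostly zero per gene), per-gene rankings are tie-dominated, and the
statistic degenerates to noise.

Genetic distance is the SNP Hamming distance (count of differing genotype
calls) over biallelic sites with MAF > 0.2, optionally restricted to gene
body + 1 kb upstream windows of a gene list; it is symmetric,
zero-diagonal and satisfies the triangle inequality.

## The synthetic generator

The generator emulates the structure the analysis assumes, with every
planted feature recorded in a truth table.  Defaults describe the
reference panel: 60 inbred accessions, 40 trios (parents may recur across
crosses; unordered pairs stay distinct), 5,000 genes, 6% additive, 8%
dominant of which 92% below MPV, dominance shift 1.0 log₂, residual noise
0.3 log₂ per sample, 3 replicates per genotype per treatment, mock and
BTH arms, 3 library batches (effect SD 0.2, per-gene scaling), 4 plant
batches (SD 0.15).

Gene baselines are N(4, 1.5²) log₂ TPM.  Non-dominant genes get Gaussian
accession effects (SD 0.5).  Dominant genes carry a large-effect biallelic
cis polymorphism — a low-expression allele at frequency U(0.3, 0.7) with
effect U(2, 4) log₂ and within-allele spread 0.25 — the
presence/absence-like variation that produces below-MPV dominance in
*A. thaliana*; this is also the only regime in which the noise-free
invariant "every dominant gene deviates by exactly the dominance shift"
can hold, because the F1 is clamped at the extreme parent and smoothly
varying accession effects would leave the clamp binding almost surely.
Additive genes put the F1 at the MPV; dominant-below at
max(lower parent, MPV − shift); dominant-above symmetrically; "neither"
genes give each F1 an idiosyncratic level whose spread matches the
pairwise-MPV null.  BTH adds a per-gene N(0, 1) effect to responsive
genes (15% by default).

Two planted clusters of dominant-below genes share one low-allele carrier
pattern each (a co-regulated upstream haplotype); rosette area is
intercept 120 mm² + 8 mm² per log₂ of the positive cluster's centred mean
expression − 8 mm² per log₂ of the negative cluster's, + 30 mm² hybrid
offset, − 0.15 mm² per rare allele of the mean parental genome-wide
burden (hybrids only), + N(0, 10 mm²) noise, all scaled by 0.6 under BTH.
Upstream windows carry Poisson(1) rare SNPs (1–2 carriers out of 60, so
panel MAF < 0.05) whose carriers are drawn with Gamma(2, 0.5) per-accession
load propensities — accession totals therefore vary realistically — plus
3 common upstream and 2 gene-body SNPs (MAF ≥ 0.25) for distance
computation.  Each rare allele carried depresses that gene's expression by
0.5 log₂ in the carrier.

All randomness flows from one seed through named SeedSequence spawn keys
(annotation/genotypes/trios/expression/phenotypes), so every stage and the
whole panel are byte-reproducible.  What the generator does **not**
emulate: read-level sampling noise (abundances are drawn on the log scale
directly), length/GC biases, linkage between SNPs, dominance that varies
per trio, population structure among accessions, and heteroskedastic
mean–variance relationships.  Passing recovery tests therefore shows the
pipeline identifies the planted structures under the stated noise model,
not that it is robust to every artefact of real RNA-seq.

## Problem sizes used for verification

The recovery and calibration runs use the reference panel (5,000 genes,
60 inbreds, 40 trios) for gene action and its all-additive twin for null
calibration; 200 pure-noise genes × 1,000 permutations for permutation
calibration; 100 simulated datasets of 200 samples for spline recovery
and interval coverage; 22 planted clusters of 20 genes for the
covariation classes; 400–500-gene panels for the burden analyses, with
null panels at 100 trios so the |r| < 0.3 bound is informative relative
to sampling noise; and a 300-gene panel for the end-to-end byte-identity
check.  Larger runs only tighten the same estimates.

## Known limitations

* The KS dominance test compares a finite F1 sample to a finite null
  multiset whose values share accessions; p-values are treated as
  independent inputs to BH, which is the field's standard practice but
  not exactly justified under the pairwise-sharing dependence.
* SHB2 fits one MixedLM per gene and is slow on full panels; the
  treatment-response default engine is the vectorised fixed-effect LRT.
* The posterior for spline coefficients is a normal approximation at the
  optimum; heavy-tailed posteriors would be summarised optimistically.
* Class sorting replaces manual curation with a threshold rule; the δ
  parameter trades sensitivity against the none-cluster false-label rate
  (≤ 5% at the default).
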