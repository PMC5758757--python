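# Methods

## The two-stage balanced-ensemble estimator

The estimator assigns every gene a probability of being a functional gene
of idiopathic dilated cardiomyopathy (DCM) as the product of two calibrated
classifier outputs: P'(disease-functional | all genes), trained on genes
linked to any disease versus the rest of the genome, and
P'(DCM | disease-functional), trained on DCM-linked genes versus the
remaining disease-linked genes.  The hierarchical factorization matters
because the second contrast — what distinguishes a DCM gene *among* disease
genes — is invisible to a single classifier trained on DCM versus
everything: features that mark disease genes in general dominate that
contrast.  The test suite checks this directly (the two-stage
cross-validated AUC exceeds a stage-1-only ablation on data where the two
signals live on disjoint feature subsets).

**Class imbalance.**  Both stages are heavily imbalanced (roughly 3k
positives vs 23k negatives; 200 vs 3k).  Each stage is therefore an
ensemble over balanced subsamples: per iteration, a negative set of exactly
the positive-set size is drawn uniformly without replacement, the
classifier is fitted on the balanced sample, and *all* genes are scored.
Per-gene scores are aggregated across iterations with a trimmed mean that
removes floor(trim_fraction x n_iterations) values from each tail (k = 5 of
100 at the defaults, so the aggregate is the mean of the central 90
values).  Trimming guards the aggregate against the occasional pathological
subsample without the bias of a median.

**Base classifier.**  The default is an RBF-kernel SVM (C = 1, kernel width
1/n_features) wrapped in Platt-style sigmoid probability calibration fitted
by internal cross-validation on the balanced training sample.  The
interface is pluggable; a logistic-regression backend gives the same
contracts at a fraction of the cost and is used for the large repeated
simulation studies in the tests and the acceptance script.  Classifier
choice is a free parameter of the method, not part of its definition.

**Determinism.**  One master seed; per-iteration substreams are spawned
with `numpy.random.SeedSequence`, and every stochastic sklearn component
receives a derived `random_state`.  Identical seed, configuration and input
produce bit-identical potential tables.

**Feature standardization** is per-iteration z-scoring with that
iteration's training statistics (required for kernel SVMs); features
constant in a training sample are dropped for that iteration with a
warning.

**Ranking.**  Genes are ranked by descending potential; ties break by
ascending gene identifier so ranks are reproducible.  Probe-level tables
collapse to gene level by keeping the probe with the maximum potential;
both stage probabilities travel with that probe, since the alternative
(mixing components from different probes) could produce a potential no
probe actually attains.

## Missing-data imputation

Feature tables may have missing cells.  The default imputation alternates
between a rank-`n_components` truncated-SVD approximation of the
column-centered matrix and refilling only the missing cells, starting from
column means, until the largest refill change drops below `tol` (defaults:
rank 5, tol 1e-6, max 200 sweeps).  Observed cells are never touched.  On
an exactly low-rank matrix this recovers deleted cells to numerical
precision (tested against the closed-form rank-1 oracle).  A single-pass
feature-median fallback is provided for degenerate inputs.

## Evaluation

Cross-validation is stratified k-fold (default 5) over DCM positives
versus the rest of the universe, repeated with reshuffled folds.  Within a
fold, both stages are retrained from scratch on the training genes only
(10 balanced iterations each), held-out genes are scored by the probability
product, held-out scores are pooled across the folds of a repeat, and one
AUC is recorded per repeat.  Pooling (rather than averaging per-fold AUCs)
uses every held-out positive in a single ranking, which is the stabler
choice with few positives per fold.  ROC-AUC is the normalized
Mann-Whitney pair count (ties count one half); an independent brute-force
pair-counting oracle verifies this on a thousand random instances.

The differential-expression baseline scores each gene by -ln p of a
two-sided Wilcoxon rank-sum test of case versus control expression, with
direction from the median difference.  Method comparison bootstraps the
positive set (100 draws with replacement, negatives fixed as the
universe-minus-positives complement, resampled positives keeping
multiplicity), evaluates both score vectors on shared resamples, and
compares the AUC vectors by rank-sum.

## eSNP-based risk prediction

The eQTL scan is the simple additive model: expression regressed on dosage
(0/1/2), slope t-test, Benjamini-Hochberg q-values over the caller-supplied
(SNP, gene) family.  Covariates are deliberately out of scope; the
synthetic cohorts contain none.  Missing dosages are mean-imputed per SNP.
Per-gene features are the mean dosage over the gene's q < 0.1 eSNPs; genes
with no passing eSNP are reported and dropped.  Risk classification is
repeated stratified 5-fold CV with pooled held-out probabilistic scores and
one AUC per repeat.  To avoid circularity when the ranking itself feeds
gene selection, `FeatureTable.drop_categories({"genetic"})` removes
eSNP-derived features before re-ranking.

## Network proximity

Shortest paths are unweighted breadth-first distances (edge confidences
are used only for stringency thresholding; the weighted-path variant is a
non-goal).  For each query gene the mean and minimum distance to the
top-ranked set and to a comparison set are computed; unreachable targets
are excluded from means and reported, never coded as infinity, so the
rank-sum comparison stays well defined while reachability bias stays
visible.  The co-expression-matched null bins the foreground genes'
correlation summaries (default: maximum absolute Spearman correlation with
the functional set — the conservative confound summary; mean-absolute is
available) into 20 equal-width bins and draws the pool quota per bin by
largest-remainder rounding, without replacement.

A practical calibration note: the proximity rank-sum test treats query
genes as independent, but on a single graph their distances share the
chance geometry of the top/bottom sets, so with small sets the test is
anticonservative (we measured ~14% rejections at the 5% level with 15-gene
sets on 150-node graphs).  With the analysis-scale set size of 100 on
500-node graphs of density 0.04 the test attains its nominal level
(~5%); the null-calibration tests use that regime.

## Drug-reversal selection

Count matrices from (naive, offending drug, offending + mitigating drug)
triplets are tested for differential expression with a self-contained
negative-binomial engine: median-of-ratios size factors, pooled
within-group moment estimate of the dispersion phi (Var = mu + phi mu^2),
a 1/mean dispersion trend fitted across genes, and shrinkage of tagwise
toward trended dispersion with prior weight 10.  The log-fold-change Wald
statistic is referred to a moderated t distribution with residual + prior
degrees of freedom — with 3 + 3 replicates a plain residual-df reference
discards the information borrowed by shrinkage and has essentially no
power.  Fold changes use a 0.5 pseudo-count.  On a simulated null
(2000 genes, dispersion 0.1, 3 vs 3) the engine calls under 2% of genes at
q < 0.1; the interface also accepts precomputed DE tables from any other
engine.

A gene is a reversal hit in a triplet iff its naive-vs-offending call is
significant and matches its DCM direction, and its naive-vs-both call is
either non-significant or significant in the opposite direction (the
"opposite" arm requires a significant call at the same q < 0.1 family, not
merely an opposite-signed fold change).  Genes with hits in at least two
cell-line/drug-pair combinations form the selected set; the up-regulated
subset joined with potential ranks gives the candidate table.

## Stratification

Case patients are clustered on z-scored profiles (expression of top-ranked
genes, or their eSNP dosage features) by Ward linkage on Euclidean
distances, cut at k = 2; label A is the smaller subgroup.  A silhouette
below 0.2 triggers a warning that the split may be an artifact — a
near-balanced split of a homogeneous cohort is otherwise indistinguishable
from real structure.  Binary phenotypes are tested by Fisher's exact test,
continuous ones by two-sided Wilcoxon rank-sum; raw p-values are the
primary output and BH-adjusted q-values are reported alongside.  PCA on
column-centered expression of a gene subset provides the separation
diagnostic.

## Synthetic data: what it emulates, and what it does not

The generators plant every signal the pipeline is supposed to detect, on
standardized scales so behaviour is portable across problem sizes:

- **Feature table** (default 2000 genes x 60 features in five categories;
  100 disease / 25 DCM positives): background N(0,1); disease genes
  shifted by Delta1 = 1.5 on ten declared stage-1 features; DCM genes
  additionally shifted by Delta2 = 1.5 on ten disjoint stage-2 features;
  2% of cells missing completely at random.
- **Expression study** (77 cases / 136 controls, mirroring the cohort
  structure the method was designed for): Gaussian log-scale expression;
  30% of genes differential, drawn preferentially from planted functional
  genes, 76% of them down-regulated in cases — the direction asymmetry a
  failing-heart transcriptome shows; |log-FC| ~ N(1, 0.2).
- **Genotypes**: Hardy-Weinberg dosages at MAF U(0.05, 0.5); three eSNPs
  per eQTL gene, each adding beta = 0.5 per allele to its gene's
  expression (per-SNP R^2 ~ 0.1 at typical MAF); case liability is the sum
  of causal-gene expression plus noise scaled to heritability h^2 = 0.5,
  thresholded at the case fraction; per-SNP GWAS chi-squares are
  Cochran-Armitage trend statistics computed from the generated data.
- **Network**: Erdos-Renyi background with U(0.2, 1) edge confidences;
  planted high-confidence (U(0.85, 1)) edges put query genes within the
  configured hop distance of functional genes, so stringency sweeps retain
  the planted structure.
- **Count triplets**: negative-binomial counts (log-normal baselines,
  dispersion 0.1); the offending drug moves planted genes 4-fold in their
  DCM direction; the mitigating arm restores a `reversal_fidelity`
  fraction of them.
- **Stratified cohort**: 77 cases split 32/45; subgroup-tagging SNPs with
  allele frequency 0.1 vs 0.9 by subgroup drive subgroup-gene expression
  (beta = 1), so expression-based and genotype-based clustering should
  recover the same split; LVEDD/LVESD-like phenotypes shift by 1.5 sd and
  a drug-usage phenotype changes frequency between subgroups, alongside
  null phenotypes.

What the generators deliberately do **not** emulate: the real mixture of
feature types and their correlation structure, linkage disequilibrium
between SNPs, batch and confounder structure in expression, population
stratification, and realistic library-size variation in counts.  Passing
tests therefore demonstrate that the machinery is correct and calibrated
under its stated model — not that the method attains any particular
accuracy on real cohort data.

## Numerical and design choices

- TSV floats are written with `%.17g` and parsed with round-trip precision,
  so write-read cycles are bit-exact for observed values.
- Rank ties break by ascending gene id; subgroup "A" is the smaller
  cluster (ties by lexicographically smallest patient-id set).
- Wilcoxon rank-sum tests delegate to `scipy.stats.mannwhitneyu`
  (exact when feasible without ties, asymptotic with tie correction
  otherwise); Fisher's exact test and BH correction come from
  scipy/statsmodels and are verified against enumeration oracles in the
  test suite.
- Null calibrations that depend on a whole simulated dataset (pure-noise
  CV, permuted-label risk CV) average over independent datasets or
  permutations: a single dataset carries an irreducible chance offset that
  refolding cannot remove.
- Problem sizes in tests and the acceptance script (hundreds to a few
  thousand genes, 10-50 ensemble iterations, logistic backend for repeated
  CV studies) are chosen so the whole suite reruns in a couple of minutes
  while every planted effect remains comfortably detectable; the shipped
  defaults reflect the study-scale conditions.

## Known limitations

- The eQTL scan has no covariate model; on real cohorts population
  structure would inflate associations.
- The NB DE engine is a moderated Wald test, adequate for its calibration
  contract but less powerful than full likelihood machinery at very low
  counts; genes with single-digit baseline counts and few replicates are
  essentially untestable by any engine.
- The proximity test inherits the graph-level dependence of its inputs;
  its p-values are calibrated at analysis-scale set sizes but grow
  anticonservative as the compared sets shrink.
- Gene identifiers are opaque strings; no symbol normalization or
  cross-reference mapping is attempted.
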