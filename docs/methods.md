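# Methods

`mammaging` implements the computational analysis of a two-age-group mouse
mammary single-cell RNA-seq atlas (3 young and 4 aged animals profiled at
diestrus) as a reusable, tested pipeline, together with a synthetic-data
generator that emulates the study's statistical structure so that every
stage can be exercised — and its error rates measured — without any data
download.

## Count model and the synthetic atlas

Counts are modelled as zero-inflated negative binomial (ZINB): with
probability `pi` an observation is a structural zero, otherwise it is
NB with mean `mu` and variance `mu + phi * mu^2` (gamma–Poisson mixture).
`pi` is independent of the mean; `phi -> 0` degenerates to Poisson. The
generator draws, per cell:

* a cell type from the age group's proportion vector (planted shifts
  emulate the reported compositional changes: epithelium 45% → 82% of all
  cells, alveolar (AV) cells 26% → 69% and hormone-sensing (HS) cells
  53% → 9% of the epithelium);
* a library size `~ lognormal(8.5, 0.35)` (median ≈ 4,900 UMI, matching
  the droplet-scale depth the QC windows assume);
* gene means `mu_gc = L_c * q_g / sum(q)` where the program `q` is a
  gamma(0.5) baseline times an 8× marker factor for the cell type's
  markers, a `2^log2FC` factor for planted age-DE genes in aged cells,
  and a per-sample × gene lognormal(0, 0.1) random effect emulating
  inter-animal variation;
* a ZINB count with `phi = 0.4`, `pi = 0.1` (conventional droplet-scale
  values; the study reports no per-type dispersions, so these are design
  choices, not fits).

A hybrid type (emulating the rare HS-AV luminal population) expresses both
parents' marker programs at 0.6× amplitude plus a private program of its
own. Ten `mt-` genes carry 5% of baseline mass with a per-cell
lognormal(0, 0.5) multiplier, so a realistic tail of cells (~5%) exceeds
the 10% mitochondrial QC cutoff. Optional doublets are sums of two cells'
draws, flagged in the ground truth. Declared marker and planted-DE genes
have their baseline floored at the median baseline: the recovery benchmark
is meant to measure the testing procedure, not the detection floor, so
planted effects sit at detectable expression.

Three canonical configurations are provided. `recovery_config` (the
default benchmark: 4 cell types, 1,200 cells/sample, so ~300 cells per
type per sample; 30 age-DE genes per type at |log2FC| = 1) is sized for a
single-CPU desk run. `study_config` (13 cell types at the reported
compartment proportions, 1,200–2,800 cells/sample) reproduces the
composition analysis at atlas scale. `null_config` has one cell type, no
planted effects, **and no per-sample random effects**: pooled two-group
tests are only expected to be uniform under their own iid null, and the
sample-effect term deliberately violates that assumption (it is what makes
the per-sample criterion non-trivial). Calibration is therefore assessed
against the engines' own null model; robustness to inter-sample variation
is assessed separately through the recovery benchmark's false-discovery
rate.

### What the generator does not emulate

Ambient RNA, batch/chemistry effects, UMI collisions, mean-dependent
zero inflation, and cell-cycle structure. Passing recovery tests therefore
shows that the procedure behaves as intended under its own model
assumptions plus lognormal inter-sample variation — not that those
assumptions hold for any particular real data set.

## QC

Cells are eliminated when UMI total < 1,000 or > 60,000, detected genes
< 500 or > 2,500, or mitochondrial UMI fraction > 10%. The elimination
rules are strict inequalities, so a cell exactly at a bound is **kept**
(tested explicitly). "Detected" means raw count ≥ 1. Medians use linear
interpolation for even counts (configurable to the lower-median
convention). Mitochondrial genes are identified by the `mt-` prefix
(mouse convention) unless a gene list is supplied.

## Normalization and fold changes

Expression is normalized per cell to 10,000 counts and `log1p`-ed.
All fold changes are ratios of **de-logged** normalized group means with a
pseudocount: `fold = (mean_A + c) / (mean_B + c)`, `c = 0.01` normalized
units. The pseudocount guards zero denominators; it attenuates folds of
genes whose mean expression is near `c`, which is intentional shrinkage at
the detection floor.

## Consensus differential expression

For each cell type, young vs aged, restricted to genes detected in ≥ 10%
of cells of either age group:

1. **Grouped criterion** — fold ≥ 1.5 (either direction, boundary
   inclusive) and BH-adjusted p < 0.05 (strict), required separately for
   the Wilcoxon engine and the ZINB engine. One BH family per engine per
   comparison.
2. **Per-sample criterion** — fold ≥ 1.25 in the same direction in every
   young × aged sample pair (12 pairs for 3 × 4 samples). A sample with
   fewer than 3 cells of the type yields a missing fold, which fails the
   gene. No p-value is involved.
3. **Cross-method criterion** — the consensus list is the conjunction of
   the two grouped calls, the per-sample call, and direction agreement.

The consensus list is a subset of the engines' intersection by
construction, and raising any threshold can only shrink it (both are
tested).

### Wilcoxon engine

Rank-sum with midranks. Combined n ≤ 12: exact enumeration of all group
assignments (valid under ties); larger: normal approximation with
tie-corrected variance and a 0.5 continuity correction. A zero-variance
comparison returns p = 1. The vectorized path used on grouped comparisons
is the tie-corrected normal approximation (group sizes there are
hundreds of cells).

### ZINB engine

A two-stage procedure in the spirit of weighting zero-inflated counts for
an NB test:

* **Stage 1 (EM weights).** Per gene, EM on
  `pi * delta_0 + (1 - pi) * NB(s_c * beta_group, phi)` with size factors
  `s_c` proportional to library size. The E-step gives each zero a
  posterior NB-membership weight (positive counts have weight exactly 1);
  the M-step updates `pi` from the structural-zero mass, the group means
  by weighted averages, and `phi` by a weighted method of moments floored
  at 1e-8. Nonzero-entry contributions are constants, so each iteration
  touches only zero entries (sufficient-statistics implementation).
  Convergence: largest (relative, for scale parameters) update < 1e-6, or
  100 iterations.
* **Stage 2 (weighted LRT).** Group means are re-fitted as weighted NB
  maximum-likelihood estimates by Fisher scoring (≤ 50 iterations;
  non-convergence yields NaN, excluded from the BH family), with the
  dispersion profiled under the alternative and shared by both models.
  The statistic `2 * (ll_alt - ll_null)` is scaled by the per-gene mean
  weight — the effective-sample-size fraction — and referred to
  chi-square(1). The scaling matters: without it the test is measurably
  liberal under the null (≈ 6% rejections at the 5% level in our
  calibration runs); with it both engines pass KS uniformity checks. With
  no detected zero inflation the weights are identically 1, the scale is
  exactly 1, and the engine collapses to a plain NB LRT (tested to 1e-6).

Per-gene method-of-moments dispersions are deliberately simple; an
optional halfway shrinkage toward a loess mean-dispersion trend is
available (`DEConfig.shrink_dispersion_trend`) but off by default. Exact
replication of any particular published implementation's internals is a
non-goal.

## Cell typing and signatures

Clustering is standard: dispersion-based highly-variable-gene selection
(2,000), scaling, PCA (30 components), kNN graph (k = 20), Leiden at
resolution 1.0, all seeded. These defaults are exposed because no single
setting suits both an atlas and a toy; tests use resolutions matched to
the planted structure. Clusters are annotated by the best-scoring marker
program (bin-matched module scores, 25 bins, 50 controls per gene); a
declared hybrid label is assigned when a cluster's top two programs are
the hybrid's parents and the runner-up is within a 25% relative margin.
All-non-positive scores yield "unassigned". Cell-cycle phase calls take
the larger of the S and G2M scores (G1 when both are non-positive), with
exact ties broken toward S — the tie rule is arbitrary but documented and
tested. Mouse-cased copies of the standard S/G2M gene lists ship with the
package.

One-vs-each signatures: a gene joins type T's signature only when its fold
over **every** other type strictly exceeds 1.25 with BH-adjusted Wilcoxon
p < 0.05, the BH adjustment applied within each pairwise comparison
independently (not pooled). This conjunction makes signatures disjoint
across types. The hybrid signature requires ≥ 1.25-fold higher (or lower)
than *both* parents with adjusted p < 0.05 in both comparisons and the
same direction in both — a gene above one parent and below the other is
not a marker. Macrophage-style pairwise markers use |fold| ≥ 2 with
adjusted p < 0.05.

## Composition

Each type is tested with a 2×2 table (type vs rest-of-compartment ×
young vs aged), pooling cells across samples within an age group, by
Fisher's exact test (two-sided probability-mass rule — the sum of tables
whose point probability does not exceed the observed one) and Pearson
chi-square (1 df, no continuity correction by default). The odds ratio
and fold change are oriented aged-over-young. Because within-compartment
proportions sum to one, a genuine expansion of one type mechanically
depresses all others' proportions; replicate-aware compositional models
(e.g. Dirichlet-multinomial) are deliberately not implemented, matching
the pooled-count testing design this pipeline reproduces.

## Over-representation

Hypergeometric upper tail per gene set, BH across the collection, sets
with FDR < 0.05 reported ranked by p up to a top-30 cutoff. The universe
defaults to the genes that passed the detection filter in the originating
DE comparison (the statistically defensible choice; configurable). Sets
reduced below 3 genes by universe intersection are skipped. Mouse→human
homolog translation goes through a user-supplied two-column table;
unmapped genes are reported, never silently dropped. Up- and
down-regulated genes are tested jointly by default (splittable by
direction).

## Numerical and design notes

* Boundary semantics follow the quoted procedure literally: "at least"
  thresholds are inclusive (fold = 1.5 passes), significance cutoffs are
  strict (adjusted p = 0.05 fails).
* NaN p-values (undetected folds, non-convergent fits) propagate through
  BH without counting toward the family size and always fail criteria.
* All randomness flows from integer seeds; the same configuration and
  seed reproduce byte-identical outputs, which the pipeline manifest
  records as content digests.
* Problem sizes in the test-suite and acceptance runs (the four-type
  recovery atlas, 20 null runs of 700 cells × 300 genes, a 60-gene ×
  2,000-cell ZINB recovery panel) were chosen as the smallest designs at
  which the measured quantities are stable single-CPU desk checks.
* Known limitations: the ZINB engine's `pi` is mean-independent; the
  dispersion has no empirical-Bayes trend shrinkage by default; pooled
  composition tests treat cells as independent, so their p-values are
  anti-conservative with respect to animal-level replication; exact
  cluster-count reproduction of any real atlas is not a goal (annotation
  operates on whatever partition the clustering yields).
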