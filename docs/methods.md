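# Methods

`cytoshift` reimplements, as a tested library, the statistical core of a
two-group single-cell leukocyte comparison: which cell clusters change in
compositional abundance between patient groups, how strongly macrophage
clusters express the classical (M1) and alternative (M2) polarization
programs, and the cohort-level statistics used to compare groups on derived
per-sample quantities.  Upstream steps that produce the inputs — alignment,
integration, graph clustering, cell-type annotation — are out of scope:
cluster labels and per-cell sample assignments are inputs here.

## Differential abundance of clusters

Each sample (patient) contributes one composition vector: the fraction of
its cells in every cluster.  For cluster $k$ the test statistic is

$$T_k = \bar p_{k,\mathrm{large}} - \bar p_{k,\mathrm{small}},$$

the difference of group means of per-sample proportions.  The null
distribution is obtained by permuting the *sample-level* group labels.
Patients, not cells, are the exchangeable units: cells within a patient are
correlated, and permuting cells would badly overstate the effective sample
size.  Two-sided p-values use the add-one estimator
$p = (1 + \#\{|T^*| \ge |T|\})/(1 + B)$, which is a valid finite-sample
p-value for any number of random permutations $B$ (default $B = 10{,}000$;
an `exact=True` mode enumerates all label reassignments and is used to
validate the sampler at 3 vs 3 samples).  Benjamini–Hochberg adjustment is
applied across clusters.

The effect size is Cohen's h on pooled per-group proportions,
$h = 2\arcsin\sqrt{p_1} - 2\arcsin\sqrt{p_2}$, the standard
variance-stabilized effect size for two proportions ($|h| \le \pi$).  The
permutation statistic deliberately uses per-sample means (robust to unequal
cells per sample) while h is reported on pooled proportions as an
aggregate-scale effect size; both per-group summaries appear in the output.

## Module scores with expression-binned controls

The per-cell polarization score of a gene set $S$ is

$$\mathrm{score}(c) = \frac{1}{|S|}\sum_{g \in S} x_{gc}
 - \frac{1}{|C|}\sum_{g \in C} x_{gc},$$

where $x$ is log-normalized expression
($x_{gc} = \log(1 + 10^4\, n_{gc} / n_{\cdot c})$) and $C$ is a pooled
control draw: genes are ranked by mean expression over all cells and cut
into `nbin = 24` near-equal bins (ties broken by gene symbol so the map is
deterministic), and for every set gene `nctrl = 100` controls are drawn
from its bin, excluding set genes, with replacement when a bin is small.
Matching controls on average expression removes the depth/expression
component that a raw set mean would carry.  The control subtraction also
cancels, to first order, any uniform per-cell shift — including the library
inflation a strongly induced program causes — which is why the score is
approximately additive in a planted log-scale effect.  `nbin` and `nctrl`
follow the convention of the widely used single-cell toolkits; both are
configurable.  The control draw is seeded and the seed is recorded in the
result.

Scores are computed once on the full normalized matrix (not per group), so
they are comparable across groups and clusters.

One known bias is documented and tested: the bins are built from overall
mean expression, which includes any cluster carrying a planted program.  If
that cluster holds a fraction $s$ of all cells, controls sit about
$s\cdot\delta$ above the set's baseline, so the planted cluster scores
roughly $(1-s)\delta$ and all other cells roughly $-s\delta$.  Cluster
*activities* (differences in mean score) are unaffected.

## Cluster-level activity and the four-way call

For each cluster the activity of a signature is the mean score inside the
cluster minus the mean in all other cells, with a label-permutation p-value
(cluster membership shuffled over cells; add-one correction; default
10,000 permutations).  This is a deliberately simple, self-calibrated
stand-in for parametric gene-set machinery; the decision thresholds of the
original analysis are retained.  A signature is "positive" for a cluster
when activity > 0 and p < 0.01; M1-positive only → M1-like, M2-positive
only → M2-like, both → Mixed, neither → Neither.  No magnitude cutoff is
applied to the activity because none is published; positivity of the
fold-change direction plus significance is the rule.

Category proportions per sample (percent of a sample's cells in clusters of
each category, all four categories always present) feed the cohort-level
comparison of categories between groups.

## Markers and pseudobulk differential expression

Marker detection is one-vs-rest per cluster with the Wilcoxon rank-sum test
on log-normalized values, BH-adjusted across genes *within* each cluster,
significant at q < 0.01.  Group-level differential expression first
averages log-normalized expression over each sample's cells (pseudobulk;
mean rather than sum so the aggregate is invariant to cells-per-sample),
then applies the same rank-sum test across samples, BH across genes,
q < 0.05.  The rank-sum test uses exact enumeration when the pooled sample
has ≤ 12 observations and no ties, and the normal approximation with tie
and continuity corrections otherwise; a constant gene returns p = 1 by
convention.  The reported log2 fold-change is the difference of mean
log-normalized values rescaled to log2 — a reporting convenience;
significance is rank-based.

## Quality control and normalization

Cells are retained when the number of observed genes lies in the inclusive
window [1,000, 10,000] and the mitochondrial read fraction (MT- prefixed
genes) is strictly below 0.22.  Inclusivity of the gene window is a
recorded choice (the usual reading of "between"); the mito cap is strict by
its wording ("less than").  Both thresholds are parameters.  Normalization
is library-size scaling to 10,000 counts followed by log1p; the original
study's variance-stabilizing transform with covariate regression is
intentionally replaced by this plain normalization because the downstream
scoring is control-subtracted and the tests are rank- or
permutation-based.

## Cohort statistics

Group comparisons on derived per-sample quantities (demographics, category
percentages) follow a normality-gated rule: Lilliefors-corrected
Kolmogorov–Smirnov tests on each group (estimated-parameter correction via
the Dallal–Wilkinson approximation; the naive KS null would be
anticonservative), and if both groups pass at p > 0.05, an equal-variance
two-sided Student's t-test, otherwise a two-sided Mann–Whitney U test.
Cohen's d with the pooled SD is always reported.  The equal-variance t
branch is a recorded choice: on the packaged demographics table it
reproduces the published BMI comparison exactly (p = 0.0552, d = 0.92),
whereas Welch's t gives p ≈ 0.066.  Groups smaller than 4 cannot be gated
and fall back to Mann–Whitney with a warning.  Ordinary least-squares
regression (slope t-test, n−2 df) covers covariate analyses such as cluster
percentage against BMI.

The packaged demographics table (20 patients, 10 per group; age, BMI,
prostate volume) is stored verbatim as printed, and the packaged M1
(106 genes) and M2 (58 genes) signature lists are stored verbatim,
including the entry `SNF789` (almost certainly a typo for ZNF789 in the
source) — fixtures mirror their source exactly and matching is exact by
default.

## Synthetic cohorts

The generator produces the structure the analyses assume, with ground
truth:

- **Composition.** Group-level cluster proportions; the "large" group is
  `baseline_props × abundance_fc`, renormalized.  Per-sample proportions
  are Dirichlet around the group vector with concentration
  `dirichlet_conc` (default 200); cells are assigned multinomially.  This
  Dirichlet-multinomial layering mirrors what the sample-label permutation
  test assumes: patient-level variability over and above counting noise.
- **Counts.** Negative binomial per gene and cell with
  variance $\mu + \mu^2/r$ (dispersion r, default 2), per-cell library
  factor log-normal(0, 0.35), per-gene base means log-normal.  Marker genes
  of a cluster have their mean multiplied by $2^{\text{marker\_log2fc}}$ in
  that cluster.
- **Programs.** A signature program multiplies the mean of *every* gene in
  the chosen printed signature(s) by $e^{\delta}$ for cells of that
  cluster.  Signature genes are given moderately high base expression
  (log-normal around 5 counts) so that the multiplicative effect carries
  through log1p normalization approximately additively and a planted
  δ = 1 yields a module score near 1 — the property the fidelity tests
  check.
- **Mitochondrial reads.** A per-cell target fraction f ~ Beta(2, 18)
  (mean 10%, typical of filtered tissue data) is realized by adding
  `round(T·f/(1−f))` counts spread over the 13 MT- genes.
- **Reproducibility.** One seed; a hierarchical seed-sequence split gives
  each sample an independent stream, so cohorts are bit-reproducible.

Defaults are at study scale (10 samples per group, 5,000 cells per sample,
13 clusters).  What the generator does *not* emulate: batch effects,
doublets, ambient RNA, cell-cycle structure, gene–gene correlation beyond
the planted programs, or realistic gene-universe size (tests run with a
few hundred to a few thousand genes).  Passing tests therefore demonstrate
calibration and power of the statistical machinery under the assumed
sampling structure, not robustness to those artefacts.

## Problem sizes in tests and the acceptance script

Replicate studies run at reduced scale, chosen so the statistical
conditions that matter (10 samples per group, Dirichlet concentration 200,
fold-change 2, δ = 1, α = 0.01) are preserved while simulations stay small:
abundance calibration/recovery use 300-cell samples and a 250-gene
universe (composition tests do not need many genes); module-score fidelity
uses 300-cell samples with 800 genes and the program planted on a ~4%
cluster (small share keeps the bin-contamination bias, ~s·δ, well inside
the ±0.15 check); classification replicates use 150-cell samples;
the end-to-end category-shift study uses 400-cell samples, enough that
multinomial counting noise does not dominate the Dirichlet patient-level
variability it is meant to sit under.  Permutation counts are 2,000
(abundance) and 500 (activity tests; the attainable p floor of
1/501 ≈ 0.002 is below the 0.01 threshold).

## Numerical and degenerate-input conventions

- Constant pooled data in any rank test → p = 1 (rather than NaN).
- Add-one permutation p-values never return 0; exact enumeration includes
  the identity relabeling.
- Division-by-zero guards: zero-total cells are rejected at normalization
  (QC must run first); zero pooled SD raises unless the means are equal.
- Duplicate gene symbols on input are disambiguated deterministically
  (`GENE`, `GENE.1`, …) and logged.
- Quantile binning ties are broken by gene symbol, making the gene→bin map
  independent of input order.

## Known limitations

- The activity permutation test treats cells as exchangeable under the
  null; with many cells it will flag arbitrarily small systematic score
  differences as significant, as any cell-level test does.  Calls should be
  read together with the activity magnitude.
- Cohen's h is computed on pooled proportions and can in principle differ
  in sign from the per-sample-mean statistic in edge cases with very
  unequal sample sizes.
- Exact gene-symbol matching means outdated or mistyped signature entries
  (e.g. `SNF789`) simply do not match and are dropped with a warning.
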