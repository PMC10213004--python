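# Methods

This note documents the statistical procedures implemented in `mirshift`,
the assumptions behind them, and the design choices made where the
procedure admitted more than one reasonable reading.

## Scientific setting

A microRNA (here mmu-miR-132-3p, `UAACAGUCUACAGCCAUGGUCG`) represses its
mRNA targets, so perturbing the miRNA in vivo — knockdown (KD) with an
antagomiR or overexpression (OE) with a mimic — shifts target abundance in
the *anticorrelated* direction: targets rise under KD and fall under OE.
Because individual miRNA effects are subtle, single-dataset significance
testing is underpowered; the package instead nominates targets by
intersecting orthogonal evidence: in silico prediction plus AGO-CLIP
support, bulk proteomics of the perturbed tissue, and per-cell-type
single-cell differential expression. Downstream, it characterizes the
nominated targets' 3'UTR seed sites and analyzes perturbation-dependent
shifts in microglial cell states.

## Seed-site model

Canonical site classes derive from the miRNA seed: the 6mer is the
reverse complement of miRNA positions 2–7 on the target strand, the
7mer-m8 extends the match to position 8, and the A1 variants append an
adenosine opposite position 1 (7mer-A1 = 6mer+A, 8mer = 7mer-m8+A). The
scanner reports each locus once under its most specific class (precedence
8mer > 7mer-m8 > 7mer-A1 > 6mer): a candidate whose interval is contained
in an already-accepted interval is suppressed, so an 8mer never also counts
as the three weaker classes nested inside it. Non-nested sites may still
overlap. Offset-6mers and non-canonical (seedless / 3'-compensatory) sites
are deliberately out of scope; the 6mer class covers positions 2–7 only.
`N` never matches; other IUPAC ambiguity codes are rejected rather than
guessed at. Coordinates are 1-based inclusive on the given sense-strand
UTR; DNA input is mapped T→U before matching.

The census reports, per target group, mean ± SEM of total sites per target
(zero-site targets contribute zeros) and mean ± SEM of per-target site-type
proportions (zero-site targets are excluded there, since their proportions
are undefined). SEM uses the ddof=1 standard deviation; empty or singleton
groups yield NA.

## Target nomination cascade

1. **Predicted set** — a gene passes if at least `min_predictors` (default
   2) of the seven prediction algorithms flag it AND its CLIP evidence
   count is at least `min_clip`. The CLIP threshold defaults to 3
   supporting experiments; the source databases' "high confidence" tier is
   not defined numerically, so the cutoff is configurable.
2. **Top-fraction selection** — features are ranked by logFC and the top
   `ceil(q·N)` taken (`q` = 0.05), ascending for "down", descending for
   "up". Ceiling is used because it reproduces the canonical counts
   306/6116 and 300/5995. Boundary ties break by smaller p, then
   lexicographic id, making the set deterministic. The ranking is taken
   over the full table, not only features with the favorable sign.
3. **Single-cell selection** — significant DEGs (adjusted p < 0.05) whose
   sign is anticorrelated with the miRNA change (up under KD, down under
   OE), per cell type.
4. **Nomination** — selected ∩ predicted, per dataset; bookkeeping then
   reports the union, a membership matrix, pairwise intersections, and the
   (proteomic union) ∩ (transcriptomic union) common set.
5. **Cell-type annotation** — multi-label consensus annotations are
   tallied one unit per (gene, label); percentages sum to 100.

Identifiers are matched exactly and case-sensitively; no ortholog mapping.

## Proteomics differential analysis

Proteins must be observed (non-missing) in at least 75% of the samples of
*every* group; survivors are RPM-normalized (each sample's non-missing
intensities sum to 1e6) and log2(RPM+1)-transformed. The +1 offset is
negligible at the simulated intensity scale (RPM values O(100–1000)) and
guards log2 at zero. Missing values are explicit NaN throughout — a zero
is data, an NaN is absence — which is what gives the presence filter its
meaning. Outlier-sample exclusion is a caller decision
(`AbundanceMatrix.drop_samples`), not automated, since it reflects
judgment about a PCA plot.

Two tests are provided. `welch` is the textbook unequal-variance t.
`moderated` shrinks each protein's pooled variance toward a prior
estimated from all proteins: writing z = log s² and correcting for the
per-protein chi-squared contribution digamma(df/2) − log(df/2), the excess
variance of z over trigamma(df/2) estimates trigamma(d0/2), inverted
numerically (Brent) for the prior df d0; the prior scale s0² follows from
the mean of z. The posterior variance (d0·s0² + df·s²)/(d0+df) feeds a t
statistic with df+d0 degrees of freedom. This is the standard
empirical-Bayes construction, written from the method-of-moments identities
rather than ported from any package; a test cross-checks it against
limma's `eBayes` on a complete matrix (log-p correlation > 0.999). With
homogeneous true variances the fitted d0 → ∞ (full shrinkage), which is
correct behavior but means moderated and Welch p-values converge only
when per-protein variances are heterogeneous. BH adjustment runs over
testable proteins only (≥2 observations per group); untestable proteins
report NaN and do not inflate m.

## Single-cell pipeline

QC removes cells with fewer than 500 expressed genes, mitochondrial UMI
fraction above 15%, or doublet score above 0.25 — all strict inequalities,
so a cell exactly at a threshold survives. The mito fraction is taken from
metadata when present, else computed from `mt-`-prefixed genes.
Normalization scales each cell to 10,000 total counts and applies
ln(1+x); raw counts persist in `layers["counts"]`.

Differential expression within a cell type uses the two-sided Wilcoxon
rank-sum test. When both sides have at most 12 cells the permutation
distribution of the rank sum is computed exactly — a subset-sum dynamic
program over the doubled midranks, which handles ties without
approximation; above that, the normal approximation with tie and
continuity corrections (via `scipy.stats.mannwhitneyu`). The exact cutoff
at 12 keeps the DP cheap while covering every regime where the asymptotic
approximation is questionable. Fold changes follow the Seurat convention:
natural log of pseudocounted means of de-logged normalized values,
ln((mean expm1+1)_A / (mean expm1+1)_B), so the marker thresholds
(screen 0.25, marker 0.5 natural log) are on the familiar scale.
The default multiplicity correction is Bonferroni, with BH behind a flag;
where results-style and methods-style conventions disagree, Bonferroni is
the default because it matches the stricter claim. Genes tested are those
expressed in at least one cell of the subset; a flag widens m to all genes.
Markers are one-vs-rest per cluster, prefiltered at logFC > 0.25, called
at logFC > 0.5 and raw p < 0.05. Pseudobulk concordance inner-joins
pooled single-cell and protein logFC vectors and reports Pearson r.

## Cell-state analysis

Module scores use the binned-control construction: genes are cut into 24
equal-occupancy bins by mean expression, and each signature gene draws 100
controls from its own bin (with replacement if the bin is small); the
score is mean(signature) − mean(controls) per cell. Bin-matching removes
the depth/abundance confound; an explicit `ctrl_pool` override exists and
with the signature itself as control the score is identically zero.
Scores are deterministic given the seed. Cells take the argmax-scoring
state; ties break lexicographically by signature name (hence invariant to
column order) and are flagged. Shipped signature lists
(`data/microglia_signatures.gmt`: homeostatic, DAM, IRM, CRM, cycling,
exAM) are 10-gene editable placeholders drawn from the standard marker
literature and meant to be replaced with a user's curated lists.

Composition shifts are tested on the 2×2 table (state vs all others, by
condition) with the Pearson chi-squared statistic N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)),
1 df, no Yates correction (configurable at the call site via permutation);
a label-permutation p (≥1000 shuffles, add-one estimator) is available
since asymptotic and resampling conventions both circulate for this test.
Fractions are normalized within condition against the total cells of the
major cell type.

Pseudotime is an input, not computed. Trends are sliding-window means on a
fixed grid of 50 window centers over [0,1] with half-width one grid step
(overlapping windows); windows with fewer than 5 cells are linearly
interpolated from populated neighbors and flagged, so curves are always
complete but the flags record where data were thin.

## Enrichment, BH, ddCt

Set enrichment is the one-sided hypergeometric upper tail P(X ≥ overlap)
on the in-set × in-query table, BH-adjusted across sets; a set passes at
adjusted p < 0.05 *and* overlap ≥ 1% of the query. The default universe is
all annotated genes ∪ query (an explicit universe can be supplied); plain
Fisher is used, not the EASE-penalized variant. A Jaccard grouping
(threshold 0.5) is offered as a convenience for collapsing redundant
pathways and is labelled as an automation of what is otherwise a manual
curation step. ddCt normalizes each sample's Ct by the arithmetic mean of
the housekeeping Cts (geometric mean of expression), takes
ΔΔCt = mean ΔCt(treated) − mean ΔCt(calibrator), and reports
fold = 2^(−ΔΔCt) plus per-sample folds for dispersion. The fold change is
invariant to global Ct shifts and inverts under group swap.

## Synthetic data generator

The generator plants a known truth in every artifact so each pipeline
stage has a construction oracle. Default scale: 2,000 genes, 50 true
targets repressed by 1 log2 unit; 7 predictors at sensitivity 0.9 /
specificity 0.95; CLIP counts Poisson(6) for targets vs Poisson(0.5)
otherwise; 10 proteome samples per group with residual SD 0.5 log2 units;
1,500 cells per condition over three microglial states (homeostatic 80%,
DAM 10%, IRM 10% in control; DAM doubling to 20% under perturbation) with
state programs of 50 genes at strength 2 on the softmax-logit scale.

Choices worth recording:

- **Streams.** One integer seed spawns an independent RNG stream per
  artifact type (`SeedSequence(entropy=seed, spawn_key=...)`), so changing
  the UTR count cannot perturb the cell simulation. Byte-identical outputs
  for identical configs are a tested invariant.
- **UTRs** are i.i.d. background at the requested GC with sites placed by
  rejection so planted sites never overlap; truth records exact positions.
  Background can create extra sites, so recovery checks assert "at least
  the planted count".
- **Proteome** intensities are lognormal (log2 baseline N(20, 2)); KD
  shifts targets +r log2, OE −r. Missingness is preferentially
  low-abundance (logistic in log2 intensity, ceiling 25% near the 10th
  percentile, ~3% overall) — enough to exercise the presence filter
  without dominating it, consistent with typical DIA completeness. RPM
  normalization of a matrix where 2.5% of proteins double introduces a
  small compositional bias in logFC (~0.03 log2 units at default scale);
  this is a property of RPM itself, not an implementation artifact.
- **Single-cell counts** are gamma-Poisson (NB mean/dispersion 0.3,
  log-normal library sizes, median ≈ 3,000 UMIs) with disjoint state
  programs drawn from non-target genes so repression and state signal
  never collide. All cells carry one major cell type ("MG") with the
  planted states as sub-states; per-cell-type operations are exercised on
  that type. Perturbation scales target means by 2^(+r) under KD and
  2^(−r) under OE — the same anticorrelated-direction convention as the
  proteome. Doublet scores are Beta(1.5, 15) (~5% above the 0.25 cutoff)
  and mito fractions uniform in [0.01, 0.10].
- **Not simulated:** ambient RNA, batch effects between runs, spectral-
  level proteomics. Passing tests therefore demonstrate correctness of the
  statistical machinery on data satisfying the stated model, not
  robustness to those real-data artifacts.

## Problem sizes used in checks

The packaged checks run the scanner-vs-oracle comparison on 1,000 random
500-nt UTRs, the exact rank-sum comparison on 200 random instances with
group sizes ≤ 7, nomination recovery over 20 simulation seeds at the
default scale, composition calibration on 2,000 null and 500 alternative
label-simulated replicates at 1,500 cells/condition, and module-score
separation on ~1,000 cells. These sizes give stable rates while keeping
the whole suite interactive.

## Known limitations

- The moderated-t prior fit assumes a common variance prior across
  proteins; strong variance clustering (e.g. abundance-dependent) would
  call for a trended prior, which is not implemented.
- The exact rank-sum path is quadratic in total rank sum and is capped at
  12 cells per side by design.
- The published supplementary tables (predicted-target list, proteomics
  rankings) are not redistributed; checks that reproduce the published
  intersection counts require the user to download them, and run on
  synthetic data otherwise.
- State assignment by argmax of module scores assumes signatures are
  roughly balanced in size and scale; wildly unequal signatures would
  bias the margin.
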