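# Methods

This note documents the models, parameter choices, numerical conventions
and limitations of `tmeomix`. Empirical statements below are limited to
what the test suite and `scripts/acceptance.py` themselves compute.

## Study design and data model

Three molecular layers are analyzed on the log₂ scale as molecules ×
samples matrices: mRNA, miRNA and protein. Samples belong to six
cell × condition groups — liver sinusoidal endothelial (E), Ito (I) and
Kupffer (K) cells, each from control (C) or tumor-colonized (T) livers —
plus optional primary-tumor (TP) and liver-metastasis (TM) groups that are
used descriptively only and never enter differential contrasts. Replicate
plans per group: mRNA 4; miRNA 3, except 2 for EC and KT; protein
9/7/6/6/5/5 for EC/ET/IC/IT/KC/KT. Protein data carry structural
missingness; missing values are represented as empty TSV cells, parsed as
NaN, and never imputed.

## Preprocessing

**Quantile normalization.** Columns are mapped to a common reference
distribution, the mean of per-sample order statistics. Ties within a
column receive the mean of the reference values over their rank span (the
standard convention; the underlying study protocol is silent on ties).
Partially observed columns (protein layer) are ranked among observed
values only and mapped onto the reference quantile function by linear
interpolation; missing values stay missing. On complete data the
operation is idempotent and every column ends with an identical sorted
multiset.

**Probe collapsing.** When multiple probes map to one gene, the probe
with the highest variance across all samples is retained; exact variance
ties break to the lexicographically smallest probe id so the result is
deterministic.

**PCA.** Covariance PCA on the row-centered matrix (no unit-variance
scaling, matching common microarray practice; whether the original
analysis autoscaled is not documented, so centering-only is a recorded
package decision). Sample coordinates come from the SVD of the centered
matrix; variance-explained fractions sum to 1.

**Hierarchical clustering.** UPGMA (unweighted average linkage) on
1 − Pearson-correlation distances, delegated to
`scipy.cluster.hierarchy.linkage`; an independent hand implementation
serves as the oracle in tests. Zero-variance vectors are rejected by name.

**RT-qPCR.** Relative expression by 2^−ΔΔCt with a reference gene and a
control condition.

## Differential expression

Equal-variance two-sample Student's t per molecule (the pooled-variance
form, not Welch), two-sided p, Benjamini–Hochberg adjustment across all
tested molecules of a contrast, and a joint selection rule:
|Δ log₂ mean| ≥ θ **and** q ≤ α. Defaults: θ = 4 (mRNA, miRNA), θ = 2
(protein), α = 0.001. θ is interpreted as a difference of log₂ means
(i.e. 16-fold / 4-fold linear); a linear-fold reading is config-selectable
(`theta_scale="linear"`) because the source convention is ambiguous.
Contrasts are (reference, test) with mean_diff = mean(test) −
mean(reference), so T-vs-C contrasts report tumor-minus-control.
Molecules with fewer than two observed values on either side are reported
untested and excluded from the BH family. With 2-replicate groups the
t-distribution has 3 degrees of freedom, which caps how small p can get;
this is a property of the design, not of the implementation.

Shared responses across the three cell types are set intersections of
passing molecules per direction, scored by −log₁₀ of the mean raw p over
the three contrasts (underflowed p = 0 is clamped to the smallest positive
float before the log). Over-representation uses the one-sided
hypergeometric tail P(X ≥ overlap) over a caller-supplied universe, BH
across sets.

## miRNA-target consensus

Four database dumps are parsed from simplified, project-defined dialects
(real dumps are versioned and out of scope; the dialects differ in column
order, header presence and comment syntax, and identical logical content
parses identically from all four). Standardization: miRNA species
prefixes matching `^[a-z]{3}-` (case-insensitive) are stripped once —
except `mir-`/`let-`, which open unprefixed miRNA names — and a leading
`mir` is canonicalized to `miR`; gene names map through an alias table to
official symbols, with unmapped names retained (conservative union) and
counted. Pairs are deduplicated within each database, then unioned; each
pair records the set of asserting databases. The consensus count is that
set's cardinality; incidence matrices per gene have row sums equal to the
counts by construction. Queries return miRNAs at a minimum consensus
(default 1, the pure union, since no stricter threshold is documented for
the original network), sorted by count then name.

## Ring network

The focal gene sits at the center with its six group means; ring 1 holds
the miRNAs targeting it at the chosen consensus (restricted to miRNAs
present in the miRNA table, because every node must carry a six-group
payload); ring 2 the ring-1 targets present in the protein table; the
outer double ring the ring-1 target genes with |mean(ET) − mean(EC)| <
0.3 log₂ (read as an absolute group-mean difference; exposed as
`ring_filter`), excluding the focal gene. Node order is canonical (ring,
then name), so serialization is deterministic; JSON round-trips
losslessly. The distribution summary partitions each layer's *tested*
molecules into network (targeted by — or being — a focal-targeting miRNA;
the 0.3 filter is treated as a display reduction and not applied here, so
the partition is exact) versus background, and reports count, mean and
quartiles of tumor-minus-control differences per direction.

## Cascades and activation

A transcript is "up" along sequence (a, b, c) in condition X when
mean(bX) − mean(aX) ≥ step and mean(cX) − mean(bX) ≥ step (boundary
inclusive; default step 2 log₂). Down requires ≤ −step at both
transitions, which makes the down list of (a, b, c) equal the up list of
(c, b, a); only three of the six sequences are therefore tested by
default. Cascades operate on transcripts/probes without gene collapsing,
so multi-probe genes contribute each probe separately. Group means (not
medians) are used; the cross-condition check flags transcripts whose mean
over all T samples strictly exceeds the mean over all C samples.

Activation profiling categorizes group means of a gene set as
low/mid/high against cutpoints, by default the 1/3 and 2/3 quantiles of
the full-matrix value distribution (the qualitative "low/high" of the
source analysis has no numeric cutoff; quantile terciles are a declared
package convention, overridable by explicit log₂ cutpoints). "Last
activated" genes are low in every C group and high in every T group, and
are only reported when at least half of the set's present genes are high
in both conditions, so the switch stands against an already-active
background.

## Protein–gene integration

Gene and protein layers have different replicate plans and no documented
run-to-run correspondence, so pairing is at the (cell type, condition)
group-mean level per shared official symbol; NaN protein group means are
dropped. Fits: ordinary least squares; robust IRLS with Tukey bisquare
weights (tuning constant 4.685, MAD-based scale re-estimated per
iteration, convergence |Δslope| < 1e-8, at most 100 iterations; the IRLS
is hand-written to this contract and cross-checked against statsmodels
RLM in tests); total least squares via the principal axis of the centered
2-D cloud, with per-point projections, signed perpendicular residuals,
and a bias profile (mean signed residual in 10 equal-count bins along the
axis). The orthogonal fit is symmetric under axis exchange (slope ↦
1/slope).

When checking recovery of the generator's planted slope, the standard
error is clustered by symbol: each protein's baseline offset is shared by
its six group-mean points, so the points are not independent and the
naive OLS standard error would be too small.

## Clinical association

Pearson's χ² on timing-group × co-expression-status count tables
(scipy's `chi2_contingency`; Yates continuity correction off by default
and exposed as a flag, since the original software's choice is not
documented). Zero margins are rejected before the test. The per-patient
immunostaining scoring that produces the counts is out of scope.

## Synthetic-data generator

The generator emulates the study design, not any particular dataset.
Per-molecule baselines are Gaussian (mean 8, between-molecule SD 2 log₂);
within-group replicate noise is iid Gaussian with SD 0.3 by default — the
source provides no noise-scale estimates, so the default was chosen once
as a plausible post-normalization microarray scale. Planted structures:
differential shifts per (molecule, contrast); monotone cascades
(per-step increments applied to the T groups of an ordered cell triple);
miRNA→gene suppression (targets move opposite to their planted-up miRNA,
scaled by a suppression coefficient); an activation set with always-high
members and switch members (low 2, high 14 log₂); focal-gene correlation
partners mixed to a target Pearson r; and a linear protein-vs-transcript
trend (slope 0.11, intercept 6) applied to realized mRNA group means,
plus per-protein offsets (SD 0.5) and missing-completely-at-random
dropout (rate 0.10). In the default study scenario the shared miRNA
shifts are −12 log₂ (an on/off switch on array scale): with only 2
replicates in EC and KT, df = 3 makes smaller shifts statistically
unrecoverable at α = 0.001, and the scenario is meant to contain
recoverable shared miRNAs. Four target-database fixtures are written with
controlled per-database membership per planted pair plus decoy pairs with
random membership; a third of gene mentions use an upper-case alias and
miRNA names carry the `mmu-` prefix so standardization is exercised end
to end. All randomness flows from one integer seed; equal seeds produce
byte-identical files.

What the generator does **not** emulate: probe-level array structure and
dye effects, peptide-level proteomics, group-dependent detection limits
(protein dropout is MCAR), correlated noise between molecules, and batch
effects. Tests passing on this generator therefore demonstrate
correctness of the statistical machinery under the declared model, not
robustness to real-data artifacts.

## Problem sizes and defaults

Default generator sizes are 400 genes × 150 miRNAs × 120 proteins — the
package's chosen desk scale for routine runs of the full pipeline and the
acceptance script. The acceptance script uses 50 seeded simulations for
differential and cascade recovery, 100 random p-vectors of length 1000
for the BH oracle, exhaustive enumeration up to universe 12 plus 10⁵
Monte-Carlo draws for the hypergeometric oracle, and 100 null simulations
at 1000 genes for the false-call calibration.

## Known limitations

- The original study's headline counts derive from deposited array and
  proteomics data; reproducing them requires downloading those accessions
  and matching undocumented preprocessing details. The pipeline can run
  such data through the same stages (the series-matrix reader and
  probe-map collapsing exist for that purpose), but no external data are
  fetched or bundled.
- The equal-variance t-test is used deliberately (matching the source);
  no moderated/shrinkage variance estimators are provided.
- The robust-regression literature reference behind the original fit is
  not reproducible verbatim; bisquare IRLS is the package's documented
  choice.
- Network visualization aesthetics (angular layout, color legends) are
  out of contract; exports are JSON/GraphML structures.
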