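# Methods

This note records the models, conventions and numerical choices behind
`phmrikit`, and what the synthetic-data generators do and do not emulate.

## Voxel-wise BOLD activation

Per subject, each voxel's percent change is
Δ% = 100·(mean(response) − mean(baseline))/mean(baseline), with acquisition
windows given 1-based inclusive (defaults 5–45 baseline, 150–200 response,
so "acquisitions 150–200" is 51 time points). Internally all coordinates
are 0-based half-open; the conversion lives in `types.window_slice`.
Voxels with zero baseline mean are excluded and counted in the QC log
rather than failing the run.

Significance per voxel is a Welch (heteroscedastic) two-tailed t-test of
response vs baseline acquisitions. Zero-variance degenerate voxels use an
exact convention: equal means → p = 1, unequal → p = 0.

The false-positive filter operates per region: with the region's V
p-values ranked ascending, the largest rank i with P_(i) ≤ (i/V)·q·c(V)
admits all smaller ranks (step-up; tied p-values share the better rank).
Defaults q = 0.2, c(V) = 1. This is exactly Benjamini–Hochberg at level
q·c(V), and the test suite verifies equivalence against a brute-force
enumeration. Surviving voxels with |Δ%| ≥ 1 are classified positive or
negative; both thresholds are inclusive.

Regional negative/positive voxel counts are compared across dose groups
with Kruskal–Wallis (mid-rank H with tie correction; all-identical data
defines H = 0, p = 1). The effect size is the rank form
Ω² = (H − k + 1)/(n − k), floored at 0 — the published tables name Ω²
without a formula, so this documented stand-in (ε²-style) is used and is
swappable; bundled Ω² values are not recomputed from it, since rank
statistics need the raw per-subject counts. The ranked table keeps rows
with p < 0.05 (strict) sorted by (p, region name) for deterministic ties,
and reports an across-region Benjamini–Hochberg step-up summary as the
FDR figure.

Composite maps pull each subject's Δ% map through the inverse of its
subject-to-composite affine, sampling with trilinear interpolation
(`scipy.ndimage.map_coordinates`, order 1); composite voxels outside a
subject's grid receive no contribution from it, and the composite value is
the mean of contributions.

## Resting-state connectivity

Band-pass: zero-phase Butterworth, order 4 by default, 0.01–0.1 Hz,
applied forward-backward after demeaning (so the realised magnitude
response is the squared single-pass response). Nuisance regression is OLS
against the supplied regressors plus an intercept; rank-deficient designs
fall back to the pseudoinverse with a warning. Motion scrubbing adds one
spike regressor per censored frame, so residuals at censored frames are
exactly zero; censoring > 50% of frames raises a QC flag.

Connectivity is Pearson over all unordered node pairs (zero-variance nodes
QC-flagged, their edges NaN), Fisher-Z transformed with |r| = 1 clipped to
1 − 1e-7. Group edge maps come from edge-wise one-sample t-tests of the
subjects' Z values against 0; t is converted to a standard-normal
equivalent through the two-tailed p with the sign of the mean, capped at
|Z| = 10 for zero-variance edges (flagged). The binary graph keeps
|Z| ≥ 2.3 (inclusive); degree centrality is the row sum of the adjacency
matrix. Node count is never hardcoded; pair counts are C(n, 2) of the
supplied registry.

Node clustering: profiles are rows of the connectivity matrix, distances
Euclidean by default. Two nodes link when each is among the other's k
nearest neighbours (k = 5 default), with tie-inclusive neighbourhoods so
identical profiles cluster together; a node whose neighbourhood is never
reciprocated is attached to its single nearest neighbour (mutual-kNN
otherwise leaves occasional spurious singletons). Clusters are the
connected components. Group degree comparison is paired over the nodes of
a subregion — the only pairing consistent with independent animal groups —
gated by Shapiro–Wilk on the differences (p > 0.05 → paired t, else
Wilcoxon signed-rank; all-zero differences report p = 1).

## Lipidomics

Outlier exclusion is a single pass: sample mean and SD computed on all of
a group's values, anything > 2 SDs away dropped, no re-iteration. With
n ≤ 5 the rule is vacuous by algebra (max |x − mean|/s = (n−1)/√n < 2),
which is a property of the published rule itself; groups of n < 3 skip the
rule with a QC note. The group test is the pooled-variance two-tailed
Student t (the spreadsheet "type 2" convention), with the same
zero-variance conventions as above.

Heatmap cells are encoded per lipid × compartment: detection status first
(BDL when nothing is detectable anywhere; BAL when any group has fewer
than `n_required` = 3 detectable samples, configurable), then outlier
exclusion per group, then the t-test and the fold change computed from the
post-exclusion means. Fold is expressed as a magnitude ≥ 1 plus a
direction; equal means tie-break as "increase" with fold 1. Arrows:
[1,1.5)→1, [1.5,2)→2, [2,3)→3, [3,10)→4, ≥10→5 (bin edges belong to the
higher bin). Shade: p < 0.05 dark, 0.05 ≤ p < 0.1 light (the boundary
p = 0.05 is light), else none. CNS-combined analysis sums a lipid across
the six brain compartments per subject (subjects missing a compartment are
dropped and logged) before testing, so n is unchanged. The plasma dose
curve uses a one-way ANOVA with Fisher-LSD pairwise t-tests on the pooled
MSE, reported only when the omnibus p < 0.05.

## Behavior

Open-field and tail-flick measures use the classical one-way ANOVA
(F with (k−1, n−k) df). Post hocs default to Tukey HSD with Fisher LSD as
an option. The investigation ratio is novel/(novel+familiar); zero total
investigation time leaves IR undefined and the subject is excluded and
logged. IR is tested against chance 0.5 with a one-sample two-tailed t.
Session length is a validation parameter, not an assumption.

## Synthetic-data generators

The generators' defaults mirror the study design they emulate: 250
acquisitions at TR 6 s (25 min), baseline 5–45 and response 150–200, four
dose groups (vehicle/3/10/30 mg/kg) with n = 4/4/6/5 imaging subjects,
n = 6 behavior groups and n = 5 lipid groups.

BOLD: baseline signal is a constant 100 arbitrary units so percent change
is numerically transparent; effects are a step over the response window
(the analysis only compares window means, so richer hemodynamics would add
nothing testable); noise is i.i.d. Gaussian per acquisition with SD in
percent of baseline. Responder voxels are drawn once per region from the
design seed, so the injected responder count is shared across subjects and
recoverable. The synthetic atlas is a small 3D slab partition
(24×24×8, 8 regions by default, configurable) standing in for a full
173-region atlas. Not emulated: temporal autocorrelation, motion,
physiological noise, scanner drift — so passing recovery tests demonstrate
correctness of the analysis chain, not robustness to real-scanner
artifacts.

Resting state: node series are multivariate normal draws from a block
correlation matrix (within/between block r); positive semi-definiteness is
checked and violations are reported with the offending r values. Real
spectral content (1/f, hemodynamic filtering) is not modelled.

Lipids: log-normal draws parameterised by group mean and cv (so cv = 0
reproduces means exactly and E[X] equals the specified mean); censoring
flags records below a configurable detection limit (left-censoring, the
BDL semantics); injected outliers sit ~4 generating-model SDs above the
group mean — at n = 5 the sample-SD rule retains them by the algebra
above. Behavioral measures are clipped normal draws per group with
non-zero default SDs.

Determinism: all generators derive their randomness from
`numpy.random.SeedSequence(seed)`, and identical seeds plus specs give
bit-identical outputs.

## Reference scenarios and problem sizes

`phmrikit.scenarios` fixes the end-to-end runs used by the tests and the
reproduction script: activation recovery on the full 24×24×8 grid with
4 × 5 subjects and 250 acquisitions; an inverse dose–response scenario with
magnitudes −1.8/−1.3/−1.1% straddling the 1% threshold so detected volumes
of activation fall with dose; two-block connectivity with 16 nodes,
6 subjects, 150 frames, within-block r = 0.8; and a null lipid calibration
of 500 tables × 8 cells. The null calibration uses cv = 0.1: the t-test's
nominal level is exact under normality, and at mild cv the log-normal model
is effectively normal, making 0.05 the correct reference for the dark-cell
rate; at larger skew the pooled t is known to be slightly conservative at
n = 5, which would test the t-distribution's small-sample behaviour rather
than this pipeline.

## Known limitations

- Ω² is a documented stand-in; published Ω² values cannot be reproduced
  from group summaries alone.
- The across-region FDR summary is Benjamini–Hochberg; other FDR variants
  would give different thresholds.
- The mutual-kNN clustering variant (k, metric, singleton attachment) is
  one concrete choice from a family of "k-nearest-neighbour clustering"
  methods; k is configurable.
- Preprocessing contracts (band-pass, nuisance regression, scrubbing)
  assume atlas-registered inputs; registration, slice timing and motion
  estimation are upstream concerns.
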