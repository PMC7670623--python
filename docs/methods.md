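# Methods

`methresp` analyses two-timepoint (T0/T18) lifestyle-intervention cohorts
profiled on beta-value methylation arrays, asking two questions: which
genomic regions are differentially methylated between subjects who respond
to the intervention and those who do not, and whether baseline methylation
predicts the intervention's success. This note records the models, the
parameters that matter, the numerical choices, and the limits of what the
synthetic validation shows.

## Data model

A methylation measurement is a beta value β ∈ [0, 1], the fraction of
methylated signal at one CpG in one sample. The central container is a
probe × sample beta matrix with an optional detection-p companion (the
per-measurement evidence that signal exceeded background). A probe manifest
carries 1-based genomic coordinates, cross-reactive and SNP-overlap flags,
and gene annotations; a phenotype table carries one row per sample
(subject, timepoint, sex, age, intervention arm, weight trajectory, BMI).

## Quality control and normalization

A probe is excluded when its detection p-value exceeds 0.01 in strictly
more than 1% of samples; the boundary case (exactly 1%) is retained.
Cross-reactive and SNP-overlapping probes are never dropped — they are
flagged and the flags travel through every result table, so readers can
discount them without the pipeline deciding for them.

Normalization is plain column-wise quantile normalization of the beta
matrix: each sample's k-th order statistic is replaced by the across-sample
mean of k-th order statistics; ties within a sample receive the mean of
their tied ranks' reference values. Probe-chemistry-stratified variants are
deliberately not modelled — probe type is not part of the data model — so
this is a simplification relative to array-specific preprocessing stacks.
Missing betas are rejected by default (quantile normalization is
ill-defined on ragged columns); an optional within-probe mean-imputation
helper is provided.

## Cell-type deconvolution and composition adjustment

Whole blood is a mixture of leukocyte subtypes with strongly divergent
methylomes, so bulk differences can reflect composition, not regulation.
Per sample, subtype proportions w are estimated by constrained projection
of marker-probe betas onto reference mean profiles: non-negative least
squares followed by renormalization onto the simplex (w ≥ 0, Σw = 1). This
constrained-projection estimator is deterministic and exact on noiseless
mixtures. Composition change between timepoints is tested per cell type
with paired Wilcoxon signed-rank tests (zeros dropped; exact null for ≤ 25
informative pairs, normal approximation with continuity correction above).

Composition adjustment residualizes each probe on (intercept + all-but-one
proportion columns), adds back the probe's grand mean, and clips to [0, 1].
Per-probe means are therefore preserved exactly (before clipping).
Latent-factor adjustment (surrogate variables) is out of scope; the
adjustment uses only the estimated known composition. Note the usual
caveat: when group membership and composition are strongly collinear,
residualization absorbs part of the group effect — the validation quantifies
this with a moderately confounded design, not a pathological one.

## Responder/non-responder DMR discovery

Subjects are ranked by relative weight change, 100·(w_T18 − w_T0)/w_T0;
the n most negative (default 10) are responders, the n most positive
non-responders, restricted to males by default (the source cohort is ~92%
male and age/BMI behave differently by sex). Age balance between the groups
is checked post hoc (flagged above a 5-year mean difference), not enforced
by matching. Both timepoints of each selected subject can be pooled as
replicates; no dependence correction is applied in that mode and a caveat
is logged.

Candidate regions are maximal runs of same-chromosome probes with
consecutive gaps ≤ 1000 nt (boundary inclusive) and ≥ 3 probes. Each run is
refined by recursive binary segmentation of the per-probe group-difference
signal: split at the boundary maximizing the difference of the two
sub-segments' mean differences, accept the split only if a child's |deltaM|
exceeds the parent's, stop below 2 × min_probes. This is a transparent
stand-in for published region callers whose exact stopping rules differ;
region callers are known to disagree, and the segmentation is exposed so it
can be switched off.

Each candidate region is tested with a two-dimensional two-sample
Kolmogorov–Smirnov statistic on (position, beta) point clouds — one point
per probe per sample, positions min–max scaled within the region so the
axes are comparable (scaling is a switch). D is the maximum, over all data
points of both sets and the four axis-aligned closed quadrants anchored
there, of the difference in empirical quadrant fractions; D ∈ [0, 1], 0 for
identical multisets, 1 under complete quadrant separation.

P-values default to a sample-level permutation test — all points of one
sample move together, since within-sample points are dependent — with
p = (1 + #{D_perm ≥ D_obs})/(n_perm + 1). A Fasano–Franceschini large-n
approximation is available for scans where the permutation floor
1/(n_perm + 1) is limiting (e.g., few true regions among thousands of
candidates under multiple-testing correction). The region effect size
deltaM is the difference between groups of the mean (over probes) average
(over samples) beta. Benjamini–Hochberg adjustment runs across all
candidates.

**Known property: the permutation p-value is super-uniform.** Because all
samples share the probe-position lattice, D is heavily discretized and the
permuted statistic ties the observed one with non-trivial probability
(~5–25% per region). Counting ties as exceedances — required for a valid
test — makes the null p-value stochastically larger than uniform (measured
mean null p ≈ 0.54–0.62). The test is conservative, never anti-conservative:
rejection at α stays at or below α. The cost is power, not false positives,
and a Kolmogorov test against the continuous uniform will detect the
deviation at a few hundred null regions. This is intrinsic to the
tie-inclusive estimator on lattice point clouds, not an implementation
artifact; the validation suite asserts the one-sided validity bound and
documents the failed two-sided uniformity check.

Single-CpG analysis regresses each probe's betas on the outcome (two-group
coding reduces to the two-sample t; paired mode is a one-sample t on
within-subject differences); zero-variance probes are flagged with p = 1.

## EWAS against relative weight change

Per baseline CpG, both Pearson r (linearity) and Spearman ρ (monotonicity)
against relative weight change are computed, each with a two-sided p. The
combined p is the geometric mean √(p_P · p_S), computed in log space so
p < 1e-300 survives; it always lies between the two component p-values.
The combined correlation is reported as the arithmetic mean (r + ρ)/2 —
the source convention is not defined, so this choice is explicit and
configurable — with a flag when the signs disagree (the row is kept).
Pearson p uses the t transform with n − 2 df. Spearman p is exact by full
permutation enumeration for n ≤ 9 without ties in the scalar path; the
vectorized scan uses the t approximation throughout (EWAS n is ~120, where
the two are indistinguishable). The scan uses baseline (T0) samples only,
one per subject. Threshold tiers (10⁻², 10⁻³, 10⁻⁴) are reported as set
memberships.

Features are annotated with genes whose intervals, extended 1500 nt
upstream of the TSS on the gene's strand (clipped at position 1), overlap
the feature (1-based inclusive arithmetic; BED I/O converts to and from
0-based half-open).

## Prediction of weight-loss success

Four predictor CpG sets are formed by correlation sign × combined-p
threshold (10⁻³, 10⁻⁴). A sample's methylation score is the unweighted mean
beta over the set; negative-correlation sets are oriented so a higher score
predicts greater loss. Success is responder-group membership (the source
gives no numeric cutoff; a percent-loss cutoff is available). ROC curves
use every cut-point with the midpoint convention for ties; AUC is the
trapezoidal area, identical to the Mann–Whitney concordance.

The clinical baseline is a linear score x·age + y·BMI. Since a linear
score's ROC depends only on its direction, the coefficients are found by
an exhaustive angle grid (721 directions on [0, 2π)), reporting the
AUC-maximizing direction rescaled to x = −1 for comparability.

**These AUCs are in-sample.** CpG selection and evaluation share the same
subjects, so the methylation AUCs (≈ 1.0 on planted cohorts) measure
separation plus selection bias, not generalization — mirroring the design
limitation of the source analysis, which lacked a held-out set. The
pipeline quantifies the bias instead of hiding it: maximizing the age/BMI
direction on label-shuffled data at n = 20 yields AUC ≈ 0.7, and the
comparison table carries an explicit circularity note.

## Chromatin-state annotation and gene-set enrichment

Features are intersected with user-supplied chromatin-state segmentations
(BED, 0-based half-open; validated non-overlapping per tissue); per tissue
group the majority state by summed bp overlap is reported, ties
multi-reported. No external segmentations or ontologies are bundled.

Gene-set enrichment of hit probes corrects the probe-per-gene abundance
bias of methylation arrays by resampling probes, not genes: null draws of
|hits| probes uniformly from the manifest reach heavily-probed genes
proportionally often, so a set of such genes is not spuriously enriched
(a naive gene-level hypergeometric is, and the test suite demonstrates the
contrast). p = (1 + #{null overlap ≥ observed})/(n_resample + 1), BH across
sets.

## Synthetic cohorts and what they do (not) show

The generator emulates the study conditions: 120 subjects × 2 timepoints,
110/120 male, relative weight change ~ N(−4.0%, 5.8²) (matching a
−3.65 ± 5.2 kg change on a 90.3 kg baseline), ten responder-tail subjects
near −16% and ten near +2.4%, gap-clustered manifests, planted regional
effects |deltaM| ≈ 0.04–0.13, planted baseline CpGs with |r| ≈ 0.34–0.42,
and six-cell-type mixtures (granulocyte-dominated Dirichlet). Truth labels
for responder groups are assigned to the *realized* extremes among males
with the same ranking and tie rule the selection operation uses, so planted
effects always coincide with the groups a caller will select.

Betas are built on the logit scale — reference-mixture or baseline mean,
plus planted effects, plus Gaussian noise (default SD 0.10, chosen so
Table-scale effects are detectable at n = 10–120; the real array's noise
is not estimated here) — and mapped through the inverse logit, keeping
values strictly inside (0, 1). Planted regions set group means to
logit(c ± deltaM/2) so the beta-scale difference equals deltaM up to a
small Jensen attenuation. Weight-correlated CpGs add c·z (z = standardized
weight change) with c = σ·r/√(1 − r²), giving closed-form control of the
target correlation. Cell references are block profiles (markers at ~0.85
for the owning type vs ~0.08–0.25 elsewhere), making deconvolution
identifiable by construction.

What passing tests show: the statistics are implemented correctly (oracle
equivalences), calibrated under the generator's null, and powerful at the
planted effect scales. What they do not show: robustness to probe-chemistry
artifacts, batch effects, sex-chromosome composition, real cell-reference
misspecification, or real-data noise spectra — none of which the generator
emulates.

## Problem sizes and defaults

Validation runs use deliberately modest sizes chosen to exercise each
property: null calibration on a 120-subject, 10,000-probe cohort (250
regions × 200 permutations for the region test; twenty 2,000-probe cohorts
at 100 permutations for the zero-DMR scan); signal recovery with 50 planted
regions among ~2,500 probes and a planted r = 0.42 CpG among 5,000 nulls
across 20 cohorts; prediction on twenty 120-subject cohorts. The headline
end-to-end run uses the default 6,000-probe cohort with asymptotic region
p-values (eight planted regions among ~1,500 candidates sit below any
desk-scale permutation floor after BH).
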