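# Methods

This note records the models, parameter choices and numerical conventions
behind `lfqcohort`, and what the synthetic cohorts can and cannot show
about real data.

## The synthetic cohort model

The generator emulates the statistical structure of a large ion-current
LFQ study of donor tissue: two donor groups (MGS1 controls, MGS2 early
disease), pooled-QC injections at fixed run intervals, a wide protein
abundance range, and a minority of samples compromised by blood
contamination or aberrant total intensity. All draws come from a single
seeded `numpy` generator, so a configuration is reproduced bitwise from
its seed.

**Base abundances.** Protein base abundances are uniform in log10. The
non-marker exponents are affinely rescaled so the design span equals
`dynamic_range_log10` exactly (default 7.3): with thousands of uniform
draws the realized extremes fall short of the interval ends, and the
published span is a realized, not a nominal, quantity. The 16 blood
marker accessions are pinned near the top of the range — as hemoglobin
and albumin are in practice — capped at the non-marker maximum and split
near-equally so that their pooled share matches the clean-sample baseline
(`baseline_marker_share`, default 4.3%) without extending the span.

**Variability.** Biological variation is one mean-1 log-normal factor per
(protein, sample) with CV `biological_cv` (default 0.40, matching the
~40% intra-group CV typical of donor tissue). No distributional form is
published for this variation; log-normality is this package's modelling
assumption. Technical noise is a second mean-1 log-normal factor whose CV
is interpolated linearly in log10 base abundance between
`technical_cv_low` (0.18, anchored at the lowest abundance decile) and
`technical_cv_high` (0.10, anchored at the top quartile), clipped outside
the anchors — a two-anchor stand-in for the monotone decreasing
CV–intensity relation seen on pooled-QC replicates.

**Group effects.** A fraction `ap_fraction` (default 0.022) of non-marker
proteins carry a true effect: group-2 intensities are multiplied by
`2^effect` with |effect| drawn uniformly from `ap_log2_effects`
(default [0.25, 1.0]) and a random sign. Effects below 0.25 in magnitude
are disallowed for true positives so that planted truth and the
fold-change category threshold cannot straddle each other.

**Contamination.** Spiked samples have their marker-class rows rescaled so
the class's share of the sample total equals the configured share, then
the whole column is rescaled back to its pre-spike total. This
*compositional* convention reflects a fixed-load LC-MS injection: extra
blood protein displaces tissue signal. It is what makes contaminated
samples genuinely distorting — every non-marker protein in a spiked
sample is suppressed by the contamination fraction — and hence what
exclusion actually repairs. Aberrant samples are a plain whole-column
scale factor.

**Pooled QC runs.** Each QC column is the per-protein mean of the clean
cohort signal (before contamination and aberrant scaling) plus fresh
technical noise. A real pooled digest averages a random subset of donors,
so individual-donor contamination is diluted roughly by the pool size;
building the pool from the clean signal is the limiting case of that
dilution and keeps QC-based metrics independent of the planted outliers.

**Missingness.** Values below a detection limit are set to 0 ("not
quantified"). The limit is chosen by quantile search on the realized
matrix so the fraction of proteins with no zeros matches
`missing_free_target` (default 0.947). This is deliberate
missing-not-at-random truncation — the dominant LFQ missingness mode —
not random dropout; methods that assume ignorable missingness would look
better on random-dropout synthetic data than they deserve to.

**Run order.** Cohort samples are randomized in run order; one QC
injection opens the queue and repeats every `qc_interval` runs (study
preset: every 20 runs, 5 injections across 77 donors).

**Presets.** `default_study_config()` mirrors the full study scale
(5941 proteins, 32+45 donors, six blood spikes above the 10% threshold,
one ×3 aberrant sample). `desk_config()` is the same model at 600
proteins and 10+12 donors with two spikes and one aberrant sample; it is
the scale used for the Monte-Carlo test experiments, chosen so the whole
suite runs in minutes on one CPU.

**What passing on synthetic data does not show.** The simulator has no
run-order drift, no batch structure, no correlated protein modules (each
protein's noise is independent), no peptide-level interference, and
annotations are assigned independently of the planted effects (so
enrichment tests are exercised under the null, not under planted
enrichment). Results on real cohorts additionally depend on upstream
identification and alignment quality that is out of scope here.

## Rollup

Global normalization equalizes per-sample totals to the median total;
zeros stay zero. The peptide outlier rule is this package's explicit
definition (the upstream pipeline's exact algorithms live in its own
publications): a peptide is excluded when its Pearson correlation against
the per-sample median profile of its protein's *other* peptides — over
samples where both are non-zero, requiring ≥4 shared samples — falls
below `r_min` (default 0.2); proteins with fewer than `min_peptides`
(default 3) peptides are never pruned, and untestable peptides are
retained but flagged. Aggregation is the sum of surviving peptide
intensities: robust to peptide-count differences after outlier removal
and standard for ion-current quantification.

## QC metrics

CVs are computed on raw (not log) intensities — a CV is scale-free and
this is the convention for LFQ QC replicates; a log-scale variant exists
behind a flag. Abundance for stratification is the mean of non-zero QC
intensities; proteins with fewer than 3 non-zero QC values are dropped
and counted. The 75%/25% split is by protein count. Correlations are
pairwise-complete on log10 intensities (zeros are missing, not measured),
with pairs sharing fewer than 10 proteins reported as NA.

## Contamination qualification

The blood threshold is a strict inequality (a share of exactly 10% is not
flagged). The aberrant-intensity rule — total > median + 3·1.4826·MAD,
one-sided — is this package's definition of a criterion the original
workflow applied by inspection; with a 3·MAD cutoff on heavy-tailed
totals it occasionally flags a borderline clean sample, which is the
intended conservative behaviour for cohort QC (inspect, then decide).
Excluded samples are dropped from all downstream stages, never imputed.
Marker fold changes between groups use the ratio of group means
(mirroring bar-style group summaries); a median variant is available.

## Differential testing and enrichment

Welch's test runs on log2 intensities (variance stabilization; the
classifiers use the same scale), while the reported fold change is the
log2 ratio of raw-intensity group means — the plain interpretation of a
"group ratio". Zeros are excluded, not imputed, with ≥3 quantified values
required per group: in a cohort where ~95% of proteins are complete the
impact is marginal, and imputation would add unauditable structure.
Both thresholds (α = 0.05, |log2| cut 0.25) are strict inequalities.
Degenerate zero-variance inputs: equal means give (t=0, p=1); unequal
means give the p→0 limit and are flagged.

Enrichment uses the quantified matrix as the universe (not the whole
annotation database), the hypergeometric upper tail P[X ≥ k], and
Benjamini–Hochberg FDR across tested terms; terms carried by fewer than
3 universe proteins are skipped and listed. BH is implemented directly
(step-up with monotonization, adjusted values clipped to [p, 1], NaN
propagated without counting toward the number of tests) and is
cross-checked against statsmodels in the tests.

## Classification and ordination

Folds are a pure function of (labels, seed); both models see identical
folds. Missing values become NaN on the log2 scale and are imputed with
the training fold's feature medians only — test folds never contribute
to imputation. The SVM kernel is RBF with the median-pairwise-distance
heuristic for the width (the original analysis reports only cost = 1;
kernel and width are recorded in the report and a linear kernel is
available). Random-forest `mtry` defaults to ⌊√p⌋ with the study-scale
override of 106 available in configuration. The accuracy CI is a normal
approximation over the fold×repeat resample accuracies
(mean ± 1.96·sd/√30). TOP-k overlap breaks score ties by descending
score then lexicographic feature id, so the selection is deterministic.
PCA is the SVD of the feature-standardized design; PLS-DA uses two
components against centred class indicators, with explained variance
computed from the X-block deflation. The heatmap z-scores protein rows
(zero-variance rows become all-zero with a warning) and clusters rows
and samples with Ward linkage on Euclidean distances — a common default;
the original figure does not state its parameters.

## Pipeline

Stages run in fixed order (simulate/load → rollup → qc → qualify → diff →
enrich → classify); each writes its TSV atomically (`.partial` then
rename) plus a JSON-lines log entry, and a manifest of parameter+input
hashes makes re-runs resumable. Defaults equal the published analysis
values (α 0.05, fold cut 0.25, panel threshold 10%, simplified 5%,
k = 30, 10 folds × 3 repeats, 1000 trees, cost 1). When exclusions leave
the smallest class below the fold count, the classify stage caps folds at
the class size and logs the cap; it likewise caps the overlap k at the
available feature count.

## Numerical conventions

Missing is exactly 0 in files and in memory; all statistics treat 0 as
"not observed". TSVs print reals at 6 significant digits and NaN as
`NA`; round-trips reproduce values to printed precision. Identifiers are
case-sensitive and matched exactly. Sub-seeds for classifiers are drawn
from a generator seeded by the caller's seed, and all seeds stay below
2³¹.

## Known limitations

The recovery Monte-Carlo at desk scale (10+12 samples, 40% biological
CV) has Welch power ≈ 0.75 on average over planted |log2| effects in
[0.5, 1] — the closed-form calculation (log2-scale sd ≈ 0.59, standard
error ≈ 0.25) matches the measured sensitivity. Detecting ≥80% of such
effects at these group sizes would require either lower biological
variability or larger cohorts; the simulator deliberately retains the
donor-tissue noise level rather than an easier one. Shared peptides,
isoform apportionment, retention-time drift and batch correction are out
of scope.
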