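# Methods

## The model and its assumptions

The unit of analysis is the strain data set: the female and male groups of
one strain for one blood parameter within one project. Per sex the
coefficient of variation CV = SD/mean is computed on the raw measurement
scale (no log transform) with the sample SD (n − 1 denominator). The
per-sex convention cancels in the CV ratio r = CV_f/(CV_f + CV_m), so the
choice of denominator does not affect any downstream quantity; it only has
to be applied uniformly, and is.

The analysis makes no distributional assumption about the measurements
themselves. It assumes that data sets are exchangeable units: the pooled
mean CV ratio weights every data set equally regardless of its group
sizes, matching the data-set-level counting of the published analysis. An
inverse-variance weighting would behave differently for very unbalanced
surveys; it is deliberately not offered.

Under the null hypothesis of no sex-specific variability the CV ratio of
each data set falls above or below 0.5 with equal probability (ties have
probability zero for continuous data), so the counts (n_gt, n_lt) are
binomial with p = ½ and the Pearson chi-squared statistic against the even
split reduces exactly to (n_gt − n_lt)²/(n_gt + n_lt) on one degree of
freedom. No continuity correction is applied; the benchmark count pairs
(5, 16), (1, 9) and (62, 44) keep their significance verdicts under either
choice. No multiple-testing correction is applied across the 25
parameters — the analysis reports per-parameter verdicts and treats
consistency across the two threshold analyses, not adjusted p-values, as
its robustness device.

## Selection and exclusion rules

Animals are eligible when their line is genetically uniform (classical
inbred, CC-derived inbred, F1 hybrid, recombinant inbred), untreated, and
aged 7–26 weeks with inclusive bounds. Rejections carry the first failing
rule in the fixed order strain class → treatment → age, making run logs
deterministic. Ages are checked per animal: a group is only eligible if
every animal in it satisfies the window (the strict reading of an age
criterion applied to "the mice examined"; group-level mixed-age handling
is otherwise ambiguous).

A data set exists where both sexes reach the per-sex group-size threshold
(5 in the primary analysis, 10 in the confirmation analysis; the
threshold-10 pool is by construction a subset). The outlier rule excludes
a data set when the female and/or the male group has CV > 0.5 — a strict
inequality, so a CV of exactly 0.5 is kept — recording which sex
triggered it. The exclusion is a data-cleaning device against technical
artefacts, not a statistical test; the per-strain-family analysis
therefore runs without it.

Degenerate cases are resolved before any division: single-animal groups
(SD undefined) are flagged and cannot pass any threshold ≥ 2; groups with
non-positive means are invalid (every parameter in scope is strictly
positive); a data set with both CVs exactly zero has an undefined ratio
and is dropped as degenerate rather than evaluated as 0/0.

## Aggregation and reporting conventions

Counts above/below 0.5 are strict; exact ties (possible only for
contrived, e.g. integer-valued, inputs) are counted in neither bucket,
excluded from the percentage denominator, and included in mean, SD and
range. Percentages are rounded half-up to integers. Printed ratios use
two decimals, except that a value which would round to exactly "0.50"
is printed with three decimals (0.496, 0.501, ...) so the side of 0.5 is
never hidden by rounding; machine-readable outputs always carry the
explicit boolean (`gt_half`, flag columns) rather than encoding verdicts
in formatting.

The mean-vs-proportion flag marks a parameter whose pooled mean and
data-set majority sit on opposite sides of 0.5 (either quantity exactly at
its neutral point agrees with nothing and never raises the flag); the
single reported flag is the OR over the two threshold analyses, each of
which can also be queried individually. The cross-threshold flag requires
a strict sign flip of (mean − 0.5) between thresholds. The
significant-in-both flag requires the equal-split test to reject at alpha
(default 0.05) at both thresholds. Flags needing an empty summary are
reported as not evaluable, never silently false — except
significant-in-both, which is false by definition when one analysis has no
data to be significant in.

Strain families are assigned by case-sensitive designation-prefix match,
longest prefix winning, so configs may distinguish e.g. C57BL/6N from
C57BL/6. The default six families use prefixes A/J, BALB/c, C3H, C57BL/6,
CBA/ and DBA/2; CBA carries the slash so that unrelated designations
starting with "CBA" do not match, and DBA/2 pools all DBA/2 substrains.

## The synthetic-data generator

The generator emulates the *structure* of a multi-project strain survey:
`n_projects × strains_per_project × parameters` data sets, group sizes
drawn uniformly from 5–30 per sex by default, per-parameter base means at
plausible mouse clinical-chemistry values, and a male CV of 0.2 by default
(mid-range for blood analytes). The female CV is `k ×` the male CV;
`k = 1` is the null and `k = 1.37` mirrors a 37% variability inflation,
giving an expected pooled CV ratio of k/(1+k). Values are lognormal by
default (positive, right-skewed, the natural choice for blood analytes),
with log-scale sigma = sqrt(ln(1 + CV²)) and the log-mean set so the
arithmetic mean hits the target exactly; a truncated normal (negatives
resampled) is available for sensitivity checks. The small-n downward bias
of the sample CV is deliberately not corrected — the analysis uses raw
CVs — and the null stays centred at 0.5 by symmetry regardless of that
bias.

Outlier contamination is injected per data set with the configured
probability; the contaminated side (female / male / both) is drawn with
probabilities 1.1 : 0.6 : 0.6 — the observed composition of excluded
outliers in the survey data, whose total (2.3% of data sets) is the
default of the `with_outliers` scenario — and the affected group's target
CV is drawn uniformly from (0.5, 0.9]. Because the sample CV at survey
group sizes is noisy and biased low, an injected group with target CV just
above 0.5 is not always detectable: empirically ≈ 67% of injected groups
exceed 0.5 at n = 10 and ≈ 95% only at n ≈ 200–500. The tests therefore
assert near-certain detection at large n and majority detection at survey
sizes, and the exclusion-rate check uses binomial bounds that accommodate
the miss rate.

Ground truth (configured n/mean/CV and outlier flag per group; expected
keep/reject per animal) is emitted beside the data, so tests compare
pipeline output against configuration, never against re-derived values.

What the generator does *not* emulate: between-strain or between-project
heterogeneity of means and CVs, correlated parameters within animals,
estrous-cycle or housing structure, litter effects, or measurement-unit
differences between laboratories. Passing tests therefore demonstrate
correctness of the computational pipeline and its calibration under clean
exchangeability — not that real survey data meet those assumptions.

## Validation problem sizes

The calibration and recovery checks run at sizes chosen to make their
tolerances meaningful on a single CPU: 1000 pools of 100 data sets
(n = 5/sex) for the type-I error of the equal-split test (empirical size
≤ 7% at alpha 0.05, the slack covering the discreteness of a binomial
with 100 trials plus Monte-Carlo noise); 500 data sets of 200 animals per
sex for effect recovery (pooled mean within 0.5 ± 0.01 for k = 1 and
within 0.578 ± 0.02 for k = 1.37); and 500 data sets at n = 20/sex for the
contamination check.

## Known limitations

* Cell values of a December-2020 database snapshot are not reproducible
  from this package alone; ingestion is file-based and the bundled
  registry records which parameters (VT ontology terms) the analysis
  covers. The package validates semantics (counts, percentages, flags,
  test decisions) and calibration, not historical table cells.
* Group-summary ingestion cannot re-check animal-level eligibility (age,
  treatment, strain class); callers of that path vouch for it.
* The equal-split test treats data sets as independent; data sets sharing
  a project are in reality weakly dependent through lab effects.
* Detection of designation families is purely prefix-based; no
  nomenclature validation is attempted.
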