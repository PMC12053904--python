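# Methods

This note documents the statistical procedures `tideline` implements,
the defaults it ships, and the design decisions taken where the
methodology was genuinely open.

## Data model

Abundance tables are samples × features matrices of nonnegative reals
(`FeatureTable`), either RPKM — `count / (length_kb × library_reads/1e6)`
— or relative abundances (rows summing to 1). Sample metadata carries
the collection date, its year and month, an analyst-defined temporal
stage (e.g. pre-spill / spill / recovery), and a binary period
(`baseline` vs `post`). Feature maps (genus→family one-to-one,
KO→KEGG-module possibly one-to-many) drive aggregation; in
one-to-many maps a child contributes its full value to every parent,
so each module is self-contained (at the cost of totals not being
conserved across a one-to-many step — conservation holds exactly for
one-to-one maps).

Unassigned or ambiguous features (e.g. reads unclassified at genus
level, reads with multiple KO assignments) are removed before
diversity and modelling via `drop_unassigned`; unmapped features in
strict aggregation are an error rather than silently dropped.

## Alpha and beta diversity

Shannon entropy uses natural logarithms throughout; Pielou evenness is
J = H/ln S, undefined (NaN, never silently 0) when richness S ≤ 1.
Richness counts features with abundance strictly above a configurable
detection threshold, default 0 — RPKM is continuous, so presence means
a nonzero value. Correlations between metrics are Pearson r with
two-sided p from the t distribution on n−2 df, pairwise-complete.

Beta-diversity is Euclidean distance on column z-scores (sample
standard deviation, n−1 denominator; constant columns become zero with
a warning). PCA is computed by SVD of the centered matrix and is
mathematically identical to classical metric scaling of the Euclidean
distance matrix. Component signs are fixed so the largest-magnitude
loading of each component is positive, making PC1 time series
reproducible. Community turnover is the Euclidean distance of each
sample to its immediate temporal predecessor ("nearest-neighbour"
dissimilarity in the temporal sense); the first sample is missing by
construction and duplicate dates require an explicit tie-break order.

## PERMANOVA

One-way PERMANOVA on the squared distance matrix:
`SS_total = Σ_{i<j} d²_ij / n`, within-group sums divided by group
size, `pseudo-F = (SS_between/(k−1)) / (SS_within/(n−k))`. The p-value
permutes labels freely (no strata) and applies the +1 correction in
numerator and denominator, so the smallest attainable p is exactly
1/(n_permutations+1); ties count as exceedances. An exhaustive mode
enumerates all label permutations (no +1 term) for small n — this is
the mode the oracle tests compare against full enumeration.

## The seasonal baseline detector

`SeasonalBaselineModel` fits, per feature, an additive two-factor OLS
of the z-scored abundance on categorical year and month with
sum-to-zero coding. No interaction is included — an interaction term
would absorb exactly the single-year anomalies the detector is meant
to expose. Residuals are invariant to the coding choice; sum-to-zero
makes the reported effects interpretable as deviations from the grand
mean and sum to zero within each factor.

Design decisions:

* **Fit scope.** By default the regression uses *all* samples
  (baseline and post) jointly, while the envelope is computed from
  baseline-period residuals only; this keeps post-period samples from
  needing effects for unseen years. A `baseline_only` mode fits on the
  baseline alone and scores unseen years with a zero year effect
  (logged) for sensitivity analysis.
* **Type II ANOVA.** SS for each factor is the RSS difference between
  the model without that factor and the full model, computed by QR
  projection and vectorised across features; on balanced designs this
  coincides with sequential SS in either order (tested).
* **Envelope.** Empirical type-7 quantiles at (1±level)/2 of the
  retained baseline residuals. Residual distributions of compositional
  abundance data are skewed, so an empirical interval is the default;
  a normal-theory mean ± z·sd interval is available. Baseline
  residuals with *signed* value > 4 (an implausible z-score for a
  well-behaved baseline, indicating a one-off event) are excluded
  from both the density export and the interval; the exclusion count
  is reported per feature.
* **Flagging.** Strictly outside the interval is anomalous
  ("outside" read strictly); equality with a bound is `normal`.
* Fewer than 20 retained baseline residuals warns that the interval
  is unstable; fewer than 2 is an error.

For functional data, per-module residual series are the median of the
member-KO residuals per sample (ordinary sample median, mean of the
central pair for even counts), flagged against module-level envelopes
built the same way.

### Calibration

The empirical-quantile envelope is exact only asymptotically: by
exchangeability, the probability that a new residual exceeds the k-th
of n baseline order statistics is (n−k+1)/(n+1), so the two-sided flag
rate at level 0.95 is ≈ 0.058 with n = 240 baseline points per feature
and ≈ 0.051 with n ≈ 2000. The calibration suite therefore samples the
synthetic baseline densely (≥ 2000 retained residuals per feature) so
the held-out flag rate of an undisturbed year is binomially
indistinguishable from the nominal 5%; with sparser baselines users
should expect the envelope to be slightly anti-conservative. Detection
tests run the detector on log10 abundances, where the generator's
linear structure makes the model exactly specified and the injected
effect is expressed directly in baseline-residual standard deviations;
a pre-build calibration at the shipped configuration measured ≥ 95%
low-flag sensitivity for a 4-sd suppression pulse, frozen in the test
suite as a ≥ 0.5 bound.

## Indicator features (IndVal.g)

For a stage combination C: specificity A = Σ_{g∈C} x̄_g / Σ_{all g} x̄_g
uses per-stage *means* (group-size corrected, the IndVal.g variant);
fidelity B is the fraction of C-samples where the feature is present
(abundance strictly > 0); the statistic is √(A·B). The best
combination maximises the statistic; significance permutes stage
labels with the +1 correction (or exhaustively for small n). The
default combination set is all singletons plus the union of
post-disturbance stages — the minimal set supporting the selection
rule that keeps (i) features indicating a single post-disturbance
stage and (ii) features indicating all post-disturbance stages, at
p < α (no multiplicity correction by default; BH available).

## Responder panels

Panels are data (feature_id, role ∈ {susceptible, responder}), not
code; the shipped default lists picocyanobacteria and SAR11
(*Synechococcus*, *Prochlorococcus*, *Candidatus* Pelagibacter) as
susceptible and documented oil-spill responders (*Halomonas*,
*Owenweeksia*, *Polaribacter*, *Tenacibaculum*, *Roseobacter*,
*Candidatus* Thioglobus) as responders. Operations: per-sample summed
relative abundance of a role; within-panel rescaling to 100% per
sample (zero-total rows flagged missing); mean-centering per feature;
and an all-pairs Pearson screen between susceptible and responder
series with hand-rolled BH step-up adjustment. Missing panel members
warn and contribute zero rather than fail.

## Synthetic data generator

Per taxon: log10 abundance = base + year effect + month effect +
disturbance + Gaussian noise, exponentiated to an RPKM-like scale.
Defaults emulate a decade-scale coastal monitoring series: 11
calendar years (the last one the post period) at 2 samples/month
(264 samples, close to the ~270 of a weekly-to-monthly decade), 120
taxa with base log10 abundance uniform on [0, 2], month effects i.i.d.
N(0, 0.3), year effects N(0, 0.15), noise N(0, 0.25) — month > year
variability, matching the strong seasonality of temperate coastal
communities. Month effects are drawn categorically rather than as
smooth harmonics because the detector models months categorically;
clean categorical truth gives exact recovery tests.

Disturbances are pulse windows targeting one role with a signed
log10 effect, shifted by a configurable lag (default 7 days,
mirroring the ~1-week lag between a contaminant peak and the
community response). The default scenario applies two pulse pairs in
October and December of the final year at ±1.0 log10 (tenfold), i.e.
4 noise-sd. Roles: 10% susceptible, 10% responder, 80% neutral. KO
profiles are sparse nonnegative linear combinations of 3 taxa each
with 10^N(0, 0.1) multiplicative noise, so functional anomalies
inherit taxonomic disturbances through the recorded loading matrix.

What the generator does *not* emulate: temporal autocorrelation
beyond the year/month structure, compositional coupling between taxa
(taxa are independent given effects), detection floors/zeros (values
are strictly positive), count noise (an RPKM-like continuous scale is
produced directly), and covariate-driven dynamics. Passing tests
therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to real-data pathologies such as
zero-inflation or autocorrelated residuals.

Because log values are exactly Gaussian, the detector is exactly
specified in the log domain and only approximately specified on raw
values (skewed residuals); the tests exercise both regimes — raw-scale
in the pipeline tests, log-scale in the calibration and recovery
suites.

## Problem sizes and determinism

Shipped test/verification sizes: calibration 11 years × 17
samples/month × 12 taxa (≈ 2400 held-out evaluations over ≥ 2000
baseline residuals per feature); recovery 11 years × 4 samples/month ×
60 taxa over effect grid {1, 2, 4} sd; permutation-null suites 1000
(PERMANOVA) and 300 (IndVal) replicate datasets at 199 permutations;
the end-to-end run 528 samples × 300 taxa × 2000 KOs at 999
permutations. All randomness flows from explicit
`numpy.random.default_rng` seeds; rerunning any stage with the same
config and seed is bit-reproducible, which the pipeline verifies by
checksumming every output in its manifest.

## Known limitations

* The envelope assumes exchangeable residuals; autocorrelation in
  real series makes the nominal level approximate.
* Year effects for years absent from the fit scope are zero in
  `baseline_only` mode — residuals for such years mix anomaly and
  interannual shift.
* One-to-many KO→module aggregation double-counts shared KOs by
  design; module totals are not comparable across overlapping
  modules.
* PERMANOVA permutes freely; repeated-measures structure (the same
  site sampled through time) is not accounted for.
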