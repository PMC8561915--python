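# Methods

## Scope and data model

The package operates on single-cause burden tables in the long format of
the public GBD results tool: one row per (location, year, sex, age group,
measure, metric) with measures {incidence, prevalence, deaths, YLL, YLD,
DALY} and metrics {count, rate per 100 000}. Hard invariants enforced by
`validate_table`: non-negative values, unique cell keys, age bounds
`lo < hi` (the terminal "95 plus" group is open-ended), and
DALY = YLL + YLD to a configurable relative tolerance (default 1e-6,
appropriate for synthetic data; real extracts rounded to few significant
digits need a looser setting). All ratio indices are computed from
**counts**, never rates, so that aggregation over strata is exact; rates
are only used for reporting per-100 000 figures.

## The score

For each analysis unit the four care ratios (PIR = prevalence/incidence,
MIR = deaths/incidence, DPR = DALY/prevalence, YLR = YLL/YLD) are
z-standardised over the fitting set and the leading eigenvector of their
correlation matrix defines the raw score. Choices made where the design
was genuinely open:

* **Correlation, not covariance.** The four ratios live on wildly
  different scales (MIR in [0, 1], DPR in DALY-years per case); covariance
  PCA would let whichever ratio happens to have the largest variance
  dominate. Standardising first makes the component scale-free, and also
  yields the affine-invariance property verified in the tests: shifting or
  positively rescaling any single index leaves every QCI unchanged.
* **Fitting set.** One model is fitted on country–year–sex
  age-standardised index vectors pooled over the whole period, then used
  to score every unit (including age-specific ones). A single model keeps
  scores comparable across years and sexes; fitting-set membership is a
  parameter (`fit_sexes`, or fit any row subset directly with
  `QCIScorer.fit`).
* **Orientation.** The eigenvector's sign is ambiguous. It is resolved by
  forcing the MIR loading negative — case fatality is the one ratio whose
  direction is unambiguous (lower = better care) — with the YLR loading as
  fallback anchor if the MIR loading is exactly zero. PIR is deliberately
  not an anchor: a high PIR can reflect better survival or merely longer
  disease duration, so its loading sign is left free.
* **Rescaling.** Min–max over the fitting set maps the observed extrema to
  exactly 0 and 100. Out-of-fit units can leave the band and are clamped
  with a warning by default (`transform(clip=False)` disables clamping;
  monotonicity checks use the unclamped scale, since a unit already at the
  fitting minimum would otherwise saturate at 0 and mask a strict
  decrease).
* **Age-standardised QCI.** Two modes are provided because either reading
  is defensible: `asr_mode="scores"` (default) averages age-specific QCI
  with the standard-population weights; `asr_mode="indices"` standardises
  the four ratios over age first and scores the resulting vector. The two
  agree to floating-point noise when the per-age scores are not clamped,
  and differ when clamping binds.

Degenerate inputs: units with a zero denominator get an explicit missing
marker (NaN) and a logged warning, are excluded from fitting (and
counted in `n_dropped_`), and receive no score — epsilon-padding would
silently distort small populations. A zero-variance index or fewer than 5
complete fitting rows is a contract error.

## Disparity, age bands, outliers

GDR = QCI_male / QCI_female with the printed five-band classification:
intervals are left-open right-closed except the first, which is closed at
0.5 — so 0.95 classifies as (0.5, 0.95], 1.05 as (0.95, 1.05] (the optimal
band). A zero female QCI makes the ratio undefined; such units are
reported, not dropped. Life stages partition age as childhood/adolescence
[0, 20), adulthood [20, 65), elderly [65, ∞); putting 65 with the elderly
lets the 5-year bands partition cleanly, and the boundary is configurable.
The six-sigma rule uses the sample standard deviation (n − 1) and the
*open* interval (μ − 3σ, μ + 3σ), so a value exactly at μ ± 3σ is flagged;
σ = 0 flags nothing and logs a warning. Location rankings sort stably with
alphabetical tie-breaks for deterministic output.

## Synthetic worlds

`generate_world` emulates the GBD table shape from a latent care quality
q ∈ [0, 1] per country-year-sex: country baselines are Beta(2, 2), drift
upward linearly (per-country slope uniform on [0, `quality_drift_max`],
default 0.01/year over 1990–2017), and an optional female offset
(`sex_quality_gap`, plus `sex_gap_drift` per year) creates gender
disparity. Incidence rates are lognormal across countries (geometric mean
5 per 100 000, σ = 0.5 — a plausible spread for an uncommon cancer) with a
fixed age profile rising ~5%/year of age; case fatality interpolates
linearly from 0.9 (q = 0) to 0.1 (q = 1); prevalent-case duration from 1
to 10 years; disability weight 0.3; YLL uses a reference-life-table-style
remaining-life curve (87 − age, floored at 2 years). Independent
multiplicative lognormal noise (σ = 0.05 by default) hits incidence,
prevalence and deaths; YLL/YLD/DALY are recomputed from the noisy values
so the DALY identity holds exactly. Counts follow from a fixed stratum
population of 1 000 000; "both"-sex rows are exact sums. SDI-like and
income classes are quintiles/quartiles of each country's mean q.

What the generator does **not** emulate: draw-level uncertainty intervals,
real demographic population structures, non-stationary age profiles,
between-country correlation, reporting gaps, or the estimation machinery
that produces real GBD values. Passing tests therefore demonstrate that
the pipeline recovers a known care-quality gradient under realistic table
shapes and mild measurement noise — not that any particular published
number is reproduced.

Randomness: one seed per config; streams for quality, incidence and noise
are split with `SeedSequence.spawn`, and the validation-covariate stream
uses a disjoint spawn key, so adding a stage never perturbs earlier draws.

## Validation stage

The score is regressed on inpatient/outpatient utilisation,
cause-specific death and prevalence rates, and risk-attributable death —
the first, second and last being noisy linear functions of q in the
synthetic design, the middle two taken from the generated table — with a
per-country random intercept fitted by maximum likelihood (statsmodels
MixedLM). Optimisation tries L-BFGS, then BFGS, then Powell, and a
(near-)perfect linear fit short-circuits to the exact OLS solution with
zero random-effect variance, since the ML likelihood is unbounded there;
genuine non-convergence raises an explicit error. Predictions (fixed part
plus posterior country intercepts) are Pearson-correlated with a reference
access-and-quality series, built in synthetic runs as 100·q + N(0, 10).

## Numerical choices

* Score projection uses fixed-order column arithmetic instead of BLAS
  matmul: BLAS kernels vary with memory alignment and can differ in the
  last ulp between a masked copy and the original array, which would break
  the "fitting extrema are exactly 0 and 100" contract under
  recomputation.
* Burden CSVs are written with pandas' shortest-round-trip float repr, so
  write∘read is the identity cell-for-cell; report CSVs use a fixed
  `%.10g` format for byte-stable artifacts across runs.
* The run manifest omits the output directory so two runs of the same
  config into different directories are byte-identical.
* Standard population: the bundled WHO world-standard 5-year weights,
  normalised to sum 1; user tables are accepted and normalised. A band
  without a weight is a contract error — no silent renormalisation
  (an explicit `renormalise` flag exists for deliberately incomplete
  band sets).

## Problem sizes in tests

Unit and property tests use 4–30-country worlds over 5–10 years; recovery
checks use the default 100-country, 1990–2017 world (per-year Spearman
between QCI and q ≥ 0.90 at 5% noise) and a 100-country × 20-year panel
for the mixed model (slopes within 3 SEs, random-intercept SD within 20%).
These sizes make the whole suite run in well under a minute while keeping
every statistical check adequately powered.

## Known limitations

* The score is relative to its fitting set: adding units changes the
  min–max anchors (and can change the component slightly), so scores from
  differently fitted models are not directly comparable.
* With four indices the component is estimated from a 4×4 correlation
  matrix; tiny fitting sets (near the minimum of 5 rows) give unstable
  loadings.
* GDR is undefined where the female score is 0 — an artefact of the
  min–max anchor assigning 0 to the worst fitting unit, not evidence of
  zero care quality.
* The validation regression assumes a linear mean and a single random
  intercept; it is a plausibility check of the score, not a causal model.
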