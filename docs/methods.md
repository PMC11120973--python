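# Methods

## The assessment model

`hvindex` implements an indicator-based composite vulnerability index in
the exposure / sensitivity / adaptive-capacity framing used for health
sector climate vulnerability and adaptation assessments. Districts are
the unit of analysis. The pipeline is:

1. **Climate variation.** Monthly temperature, rainfall and
   relative-humidity series per district are averaged into calendar-year
   means (incomplete years dropped with a warning); the exposure
   indicator is the total change over the record. Two estimators are
   provided: `trend_total_change` (OLS slope of annual means on year,
   times the number of year intervals — the default, robust to endpoint
   noise) and `endpoint_difference` (mean of the last *k* annual means
   minus the first *k*, default k = 10 clipped to half the record).
2. **Hazard frequency.** Extreme-event records (district, hazard, year)
   are counted per district and hazard inside a closed year window
   (default 1980–2019). The combined extreme-event indicator is the sum
   of the drought, flood and cyclone counts; since min-max normalization
   is invariant to positive affine maps, using the sum is equivalent to
   using the mean.
3. **Imputation.** Province-level indicators (e.g. per capita
   expenditure) are broadcast so every district inherits its province's
   value. A district missing an otherwise district-level indicator
   receives the arithmetic mean of the observed districts in its
   province. If an entire province is unobserved for an indicator the
   national mean of observed districts is used and flagged — an
   extension beyond the two primary rules, needed for robustness on
   sparse inputs. Observed cells are never altered; the operation is
   idempotent.
4. **Normalization.** Y = (X − X_min)/(X_max − X_min) per indicator
   across the analysis table's districts (bounds are data-driven, not
   fixed externally, because the index is a within-assessment
   comparison). Indicators marked `higher_is_less` relative to their
   component (inhabitants per health unit, inhabitants per health
   agent) are reflected, Y ← 1 − Y. A degenerate (constant) indicator
   is zero-filled by default — it carries no discriminating information
   and zero-filling keeps the component's indicator count N stable —
   or dropped with weight renormalization under `drop_indicator`.
   (Composite-index write-ups sometimes print the numerator of this
   formula as X − X_max while still describing a [0, 1] score; the
   standard min-max form above is the one consistent with a [0, 1]
   range and with quintile classification, and is what this package
   computes.)
5. **Sub-indices and composite.** E, S and AC are weighted sums of
   their component's normalized indicators — equal weights (the
   arithmetic mean) by default, with per-component weights configurable
   and validated to sum to 1 within 1e-9. The composite is
   HVI = (E − AC) × S, bounded in [−1, 1], positive exactly when
   E > AC and S > 0. No flooring of (E − AC) at zero is applied: a
   negative value is informative (capacity exceeding exposure).
6. **Classification.** Scores are cut at their empirical 20/40/60/80th
   percentiles (numpy's linear-interpolation estimator by default; the
   estimator is recorded in the run manifest so runs are comparable).
   Intervals are half-open with the lowest closed: class k covers
   [b_{k−1}, b_k), class 5 is closed above, and scores equal to the
   observed minimum are always class 1, so an all-tied vector is
   entirely class 1. Classification is therefore invariant to strictly
   increasing transforms of the scores. Quintiles are computed per
   score vector (overall HVI, each hazard HVI, each sub-index)
   independently.
7. **Exclusion of extremes.** Provincial capitals typically sit at the
   favorable extreme of adaptive capacity and compress the map's color
   scale for everyone else. `exclude_extremes` flags a configurable
   district list (default: the capitals) as `excluded`, retains their
   numeric scores, and recomputes the quintile breaks on the remaining
   districts only (recomputation, rather than inheriting the
   all-district breaks, is the default; both are available).

### Hazard-specific and determinant indices

The hazard-specific HVI replaces the exposure sub-index with an
equal-weight mean of the three climate-variation indicators plus the
*single* selected hazard's frequency indicator (4 terms), keeping S and
AC unchanged. This composition is the minimal one consistent with the
exposure block's structure; it is a design choice of this package, not
a canonical definition, and should be stated when reporting results.
Determinant sub-indices are equal-weight means of a thematic indicator
group (health services, human resources, water and sanitation,
financial resources), usable for any determinant label in the schema.

### PCA cross-check

As a robustness check on the equal-weight composite, all schema
indicators are pooled with adaptive-capacity columns reflected (1 − Y)
so every column points toward vulnerability, standardized
(correlation-matrix convention — the composite-index standard, since
normalized columns still differ in variance), and the first principal
component is extracted (scikit-learn). The component is sign-oriented
so the mean loading of the exposure indicators is positive.
Zero-variance columns are dropped; an all-degenerate matrix is an
error. The report carries Pearson and Spearman correlations against the
HVI, the PC1 explained-variance share, and a quintile-class confusion
matrix — both correlation and class agreement are emitted because
composite-index validation practice varies on which to report.

## The packaged schema

The default schema has 32 indicators partitioned 4 (exposure) / 12
(sensitivity) / 16 (adaptive capacity), spanning climate variation,
extreme events, demography, disease burden, and capacity determinants.
Two adaptive-capacity indicators are inverse (`higher_is_less`):
inhabitants per health unit and inhabitants per elementary health
agent. All exposure and sensitivity indicators are taken as
`higher_is_more`; whether any indicator should be inverted is a
judgement the schema makes explicit per indicator and a user can
override by loading a custom schema file. Per capita expenditure is
marked province-level and enters through the broadcast rule.

## The synthetic generator

The generator exists so that every downstream stage — and the claim
"the HVI recovers true vulnerability" — is testable without any real
data deposit. It emulates the *structure* of a national assessment, not
any country's magnitudes.

**Latent model.** District latent vulnerability is a single Gaussian
factor v_d = r(region) + u_p + e_d: a fixed regional gradient (south
+1.4·`latent_sd`, centre 0, north −1.4·`latent_sd` — vulnerability in
such assessments is strongly geographically structured), a province
random effect (sd 0.6·`latent_sd`) and a district effect (sd
`latent_sd`, default 1).

**Indicators.** Every indicator is a strictly monotone transform
(logistic for percentages, exponential for rates) of v_d plus
indicator-level Gaussian noise (sd `noise_sd`, default 0.3):
sensitivity indicators increase in v_d; adaptive-capacity indicators
increase in the capacity score c_d = −v_d, with inverse indicators
(inhabitants per facility) decreasing in c_d. Sensitivity loadings are
kept modest (demographic shares vary far less across districts than
disease rates), which also keeps the S factor's relative spread
realistic. Capacity indicators are deliberately right-skewed — most
districts at low access/coverage levels — so that after min-max
normalization the rural majority scores low on AC and E − AC is
positive for most districts, the pattern real assessments of
low-income settings report. One capital per province receives an
additive capacity advantage (`capital_ac_boost`, default 2.0), making
capitals the outlying high-capacity districts.

**Climate.** Monthly series are base + seasonal cosine + linear trend
+ noise; trend slopes are proportional to v_d (plus noise), so climate
variation is the deterministic exposure signal. Noise scales per
variable off the single `noise_sd` knob. Spans default to 1970–2016.

**Hazards.** Event counts are Poisson (the standard count model over a
40-year window), with the cyclone rate multiplied for coastal districts
and the drought rate for southern districts — hazard exposure is
geographic, correlated with v_d only through the latent's regional
gradient, and retains irreducible Poisson variation regardless of
`noise_sd`.

**Missingness.** Cells are removed per indicator and province at
`missing_rate` (default 0.05), capped at half of any province's
districts so the province-mean imputation rule always has support.
Province-level indicators are emitted once per province in a separate
table.

The panel is a pure function of (spec, schema); the latent score and
true climate slopes are carried on the panel for validation only.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: spatial autocorrelation beyond the
region/province block structure, multi-factor vulnerability (one latent
factor drives everything, which is also why the PCA cross-check agrees
so strongly here), realistic indicator magnitudes or measurement error
models, reporting artifacts (digit preference, administrative boundary
changes), and non-stationary climate trends.

## Numerical choices and degenerate inputs

- Weight sums validated to 1e-9; oracle-equivalence of the vectorized
  path against straight-line recomputation holds to 1e-12 on small
  tables.
- Quantile estimator: numpy `linear` by default; any numpy method name
  is accepted and recorded in the manifest.
- Degenerate indicators: zero-fill default (see above); under
  `drop_indicator` the component's remaining weights are renormalized,
  and a component losing all its indicators is an error.
- Ties in classification share their value's class; an all-tied score
  vector is class 1 throughout.
- Fewer than 5 districts cannot be classified; fewer than 2 complete
  years cannot yield a climate variation; an indicator observed nowhere
  cannot be imputed — all explicit errors naming the offender.

## Problem sizes

The default panel is 161 districts × 11 provinces with 47 years of
monthly climate (≈272k rows) and ≈2.4k event records; a full pipeline
run takes well under a second. The recovery validation uses 20
independent panels at `noise_sd` = 0.1·`latent_sd`; the test suite's
smaller structural checks use a 30-district, 5-province panel with a
20-year climate record, chosen to exercise identical code paths at a
fraction of the cost.

## Known limitations

- The direction assignment of indicators is schema-declared, not
  data-derived; a misdeclared direction silently flips an indicator's
  contribution.
- Min-max normalization is outlier-sensitive: a single extreme district
  compresses everyone else's scores on that indicator. The capital
  exclusion mitigates the mapping consequence but the sub-index values
  themselves retain the compression.
- Equal weighting is a convention, not an estimate; the PCA cross-check
  measures agreement with a data-driven alternative but does not
  validate either against ground truth.
- The hazard-specific exposure composition (3 climate terms + 1 hazard
  term) is a package design choice; alternative compositions would
  yield different hazard rankings.
- GeoJSON rendering draws polygon exteriors only (holes are filled) —
  adequate for choropleth smoke tests, not cartography.
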