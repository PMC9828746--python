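# Methods

## Tier-1 exposure model

The screening-level model treats a single foliar application (or the
total of repeated applications) to a bee-attractive crop, with bees
foraging and provisioning exclusively from the treated area and no
dissipation or degradation of residues — deliberately conservative
high-end assumptions, as appropriate for a screening tier.

**Concentrations.** In default mode the nectar and pollen concentration
is `EEC = RUD × AR` with RUD = 110 mg/kg per lb a.i./acre for both
matrices (the upper-bound Kenaga/T-REX tall-grass residue unit dose,
used as a surrogate for flowers that are directly sprayed) and AR the
application rate converted at 0.892179 lb/acre per kg/ha. No default
residue estimate exists for royal jelly, so the jelly concentration is
zero unless measured; in empirical mode all three matrix concentrations
come from the residue-study peaks.

**Doses.** Each caste's dietary dose is the consumption-weighted sum of
matrix concentrations (mg/day × mg/kg / 1000 = µg/bee/day). The caste
consumption table follows the public BeeREX v1.0 workbook. Three castes
are *in scope* for the single reported adult/larval quotient — the
nectar forager (292 mg nectar, 0.041 mg pollen per day), the nurse
(140, 9.6) and the 5th-day worker larva (120, 3.6); with equal nectar
and pollen concentrations the nectar forager governs the adult value,
and pollen-dominated residue profiles (pollen:nectar above roughly
16:1) shift governance to the nurse. The remaining castes (cell
cleaner, comb builder, pollen forager, winter worker, drone, queen,
younger larvae, queen/drone larvae) are computed and reported but do
not govern: in particular the queen's all-jelly diet (525 mg/day) is
reported separately because no default jelly EEC exists and a jelly
route would otherwise dominate spuriously under default assumptions.
Adults foraging at application time receive a direct-spray contact dose
of 2.7 µg/bee per lb a.i./acre (the BeeREX v1.0 default); larvae are
comb-bound and have no contact route.

**Quotients.** Acute RQ = dose / LD50 against the 0.4 acute level of
concern; chronic RQ = daily dose / NOED against 1.0. Endpoints that
were only bounded from below ("LD50 greater than the highest dose
tested") are used at face value and flagged, making those quotients
conservative upper bounds. All arithmetic is carried at full precision;
rounding (2 significant figures in rendered reports) happens only at
presentation time.

## Use-report cleaning

Rates are harmonized to kg/ha (records with unparseable units are
dropped and counted). Outliers are rates strictly above the IQR upper
fence Q3 + 1.5 × (Q3 − Q1); quantiles use linear interpolation between
order statistics ("type 7"), the estimator being a documented,
switchable parameter since registry-cleaning conventions differ. Likely
data errors are rates strictly above 10 × the highest commercial label
rate, reviewed on the records remaining after outlier removal (two-pass
order; a record exceeding both thresholds is removed once, as an
outlier). The fence is computed per chemical with all crops pooled —
one defensible rate per chemical is the assessment's need — with
per-crop fencing available behind a flag. The exposure rate is the
maximum over records of neat (unblended) products when any exist, since
blends misstate the surfactant's own rate; otherwise the 90th
percentile of all cleaned rates serves as a conservative neat-material
surrogate.

## Residue post-processing

Matrices group as: pollen input = {forager pollen, bee bread}; nectar
input = {forager nectar, stored nectar}; jelly input = larvae (a
surrogate, as royal jelly itself is rarely sampled). Each exposure
input is the maximum non-censored concentration across its group and
all sampling days, with source matrix and peak day recorded. Values
below the minimum detectable limit are censored; a fully censored group
is substituted at the limit of quantitation (the conservative default),
with half-LOQ, MDL and zero rules available for sensitivity analysis —
inputs are elementwise ordered LOQ ≥ half-LOQ ≥ zero. Untreated-control
samples are validated to be fully censored (a warning is raised
otherwise) and never feed peaks; matrices marked invalid (e.g. failed
storage-stability verification) are excluded. No rounding is applied to
peaks.

## Endpoint statistics

**Trimmed Spearman–Kärber LD50.** Mortality proportions are monotonized
on log10 dose by pool-adjacent-violators, the curve is extended by one
(mean) dose-spacing to 0% below and 100% above the tested range, the
central 1 − 2·trim probability mass is kept, and the mean log-dose of
the implied tolerance distribution is integrated segment by segment.
The default trim is 0 (trim is exposed as a parameter). If no dose
reaches 50% mortality the estimate is reported as unbounded at the
highest dose tested; complete mortality at every dose is rejected as
uninformative. The 95% CI uses a delta-method variance: a central
finite-difference gradient of the full estimator (PAVA + trim +
integration) with per-dose binomial variances p̃(1−p̃)/(n−1). On
seeded log-logistic simulations (5 doses × 10 bees, true LD50 50,
slope 4, 500 replicates) the test suite verifies median relative bias
within 5% and CI coverage between 90% and 98%.

**Williams-type NOED (continuous responses).** Dose means are
amalgamated by PAVA under a monotone-effect assumption and compared
with the (pooled) control sequentially from the highest dose downward,
one-sided, using the studentized amalgamated contrast. Critical values
are not transcribed from the 1971/72 tables: they are the 95th
percentiles of the same statistic under a seeded Monte-Carlo null
(default 10,000 draws) for the exact design at hand, including the
data-driven resolution of the adverse direction, which avoids both
table-transcription errors and direction-selection inflation. The NOED
is the highest non-significant dose; "no effect at any dose" and
"effect even at the lowest dose" are flagged explicitly.

**Cochran–Armitage step-down (monotone quantal).** One-sided trend test
with integer scores and the conditional (permutation) variance; while
significant at α the highest dose is dropped and the test repeated,
the NOED being the highest dose of the first non-significant
configuration. The normal approximation is validated in the tests
against an exact multivariate-hypergeometric enumeration (mid-p
convention).

**Fisher's exact with Holm adjustment (non-monotone quantal).** Per-dose
one-sided Fisher tests against the negative control, Holm step-down
adjusted; the NOED is the highest dose with no significant dose at or
below it.

**Test selection.** Continuous replicate-level data goes to Williams.
Quantal data is screened for monotonicity: monotone iff all nonzero
adjacent differences of the per-dose proportions share one sign and the
Spearman rank correlation of proportion against dose agrees in sign —
a documented stand-in, since published assessments rarely state their
screen. Solvent controls are compared with negative controls (Fisher
for quantal, Welch for continuous, two-sided α = 0.05); absent a
detectable difference the negative control is used downstream. All
NOED tests are one-sided at α = 0.05 (mortality can only be adverse);
α is configurable. Replicate cages are collapsed to totals for quantal
tests; replicate variance is used only by Williams. Under seeded null
simulations (2,000 replicates per procedure) the suite verifies that
each procedure declares an effect at the lowest dose in at most 7% of
replicates (nominal 5% plus Monte-Carlo slack).

## Synthetic data

The generators produce inputs with the structure the analysis assumes,
so the whole pipeline is testable without external downloads.

*Use records*: log-normal rates (μ = 0, σ = 0.5 on log kg/ha — a heavy
right tail typical of self-reported registries, median 1 kg/ha in the
adjuvant range), truncated at 85% of the analytic IQR fence of the
clean distribution; injected outliers are drawn uniformly in
[1.5, 3] × fence and unit errors multiply an upper-half clean rate by
100 (a misplaced-units entry). The truncation/injection margins make
recovery well-posed by construction: the empirical fence of a
contaminated sample of n ≥ 1000 lies between the clean maximum and the
lowest injected value, so flag sets can be compared with truth labels
exactly. Contamination counts are round(fraction × n).

*Residue studies*: per matrix, triplicate concentrations follow
first-order decay C0·e^(−k·day) with log-normal replicate noise
(CV 0.2) and censoring below the matrix MDL; default C0 values put
pollen-type matrices one to two orders of magnitude above nectar, as
field studies show.

*Dose–response*: deaths are binomial with log-logistic mortality
p(d) = 1/(1 + (LD50/d)^slope); the default design (5 doses in
geometric progression spanning the LD50, 30 bees per dose as three
pooled cages of ten) mirrors standard acute bee-test designs.

What the generators do **not** emulate: real registries' crop- and
product-structure in rates (rates here are i.i.d. given the label),
temporal residue autocorrelation between sampling days, between-cage
overdispersion in mortality, and time-to-death structure. Passing
recovery tests therefore demonstrate correctness of the cleaning and
estimation logic under the stated models, not robustness to every
field artefact.

## Numerical and design choices

* Unit conversion constant 0.892179 lb/acre per kg/ha, applied before
  any EEC arithmetic; round-trips to 1e-12 relative.
* PAVA via scipy's isotonic regression; quantiles via numpy.
* The bundled study's empirical-mode inputs are re-derived from the raw
  residue table at run time rather than stored pre-reduced.
* Degenerate inputs are rejected with named errors (unknown units or
  censoring rules, empty matrix groups, missing endpoints identifying
  their route, fewer than 4 rates for a fence, fewer than 2 replicates
  per group for Williams).
* Acceptance-style reproduction of published tables compares at each
  cell's printed precision. One bundled-study cell (acetoxy larval
  acute dietary) computes to 0.0835 at full precision and sits on a
  rounding boundary relative to its printed 0.084; it is asserted to
  one unit in the last printed digit.

## Limitations

* Screening tier only: no foliar dissipation kinetics, no colony-level
  (tier 2+) modelling, no synergy with co-applied pesticides, no
  sublethal endpoints.
* The worker-only governance rule for reported quotients is the
  standard screening convention but is not universal across tools;
  out-of-scope caste doses are reported so users can apply their own
  rule.
* The Williams procedure assumes approximately normal replicate means
  with common variance; heavy-tailed replicate noise will distort its
  Monte-Carlo calibration.
* No probit/logit model fitting is provided; for steep, well-behaved
  curves the Spearman–Kärber estimator is efficient, but GLM fits may
  be preferable when partial kills are sparse.
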