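# Methods

## Exposure model

All geometry is planar, in projected metres; the study area is a single
county, so no geodesic corrections are applied.

**Buffer VKT.** For a residence at point *p* and radius *r* (250 or 500 m),
each road polyline is intersected with the closed disc analytically: for a
linear piece *a → b* the inside parameter interval comes from the quadratic
`|a + t(b−a) − p|² = r²`, clipped to [0, 1]. Vehicle-kilometres travelled per
day is Σ (inside length, km) × AADT over segments. The disc is a Euclidean
buffer of the point (not a network buffer). Zero-length pieces are skipped.
Enlarging the radius can only add length, so `vkt_250 ≤ vkt_500` always.

**Kernel density.** Each segment is discretised into point masses at 10 m
arc-length steps (midpoint placement; the remainder of a piece is carried by
a final shorter step), each of weight AADT × sub-length (vehicle-metres/day).
A mass spreads over raster cell centres by an isotropic bivariate Gaussian
with σ = 100 m, truncated at 300 m and renormalised to unit planar integral
inside the truncation disc; cell values are daily traffic counts per m² on a
50 m grid. Rationale for the constants: the influence distance of 300 m is
the substantive modelling choice (traffic's influence treated as
insignificant beyond it); σ = 100 m puts the truncation at 3σ (98.9% of the
untruncated mass), and the 10 m step is cell_size/5, keeping the combined
truncation + midpoint-quadrature error of the surface's total mass below 2%
(verified by the mass-conservation tests; measured error is ~0.02% on the
default networks). The absolute density scale is convention-dependent (it
depends on the kernel constant); quintile ranks and log-scale regression
effects are invariant to that positive constant. Residences are assigned the
value of the containing cell with no interpolation; a point exactly on a
shared cell edge belongs to the lower-index cell (a determinism tie-break).

## Cohort algorithm

Diagnosis matching is prefix-based: any ICD-9-CM code beginning "493" is
asthma (the three-digit category covers all 493.xx subcodes).

- **Case definition**: ≥ 2 visits, any care setting, with asthma as the
  *first-listed* code, dated ≤ 548 days apart (18 months as deterministic
  day arithmetic).
- **Exacerbation events**: each inpatient or ED visit with first-listed
  asthma is one event; outpatient visits qualify with asthma in any of the
  first three code fields, and a greedy left-to-right scan emits one event
  whenever three qualifying visits fall within a window of < 14 days
  (dates spanning ≤ 13 days), consuming every qualifying visit inside
  14 days of the window start. Greedy earliest-first consumption is a
  determinism choice: overlapping windows are never double-counted and the
  result is invariant to input row order.
- **Tie-breaks chosen where the rules are silent**: a same-day ED +
  inpatient pair collapses into a single hospitalization (an admission via
  the emergency department is one episode); all qualifying acute visits on
  one calendar day collapse the same way. Inpatient/ED events inside an
  outpatient window still count separately (the three event types are
  defined independently). Whether the 2-week window is a strict-14 or
  inclusive-15-day rule, and whether ED visits may seed outpatient
  clusters, are conventions; this package uses strict-14 and
  outpatient-only clusters.

The per-person outcome is `rate = n_events / person_years`; persons with
non-positive person-years are excluded with a logged error.

## Regression analysis

Complete-case analysis (no imputation). Covariates: sex (male = 1), age,
age² and the block-group poverty index (percent of households with
income-to-poverty ratio < 1), all continuous; the traffic metric enters as
its natural log, with zeros floored at half the minimum positive observed
value (deterministic and scale-covariant). Models are fitted by maximum
likelihood via iteratively reweighted least squares (statsmodels GLM):
binomial with logit link for any-event, Poisson with log link and
ln(person-years) as a fixed-coefficient offset for the event count — the
offset formulation is the count-likelihood version of modelling events per
person-year. Pairwise interactions are omitted. Confidence intervals are
Wald (estimate ± 1.96 SE); profile likelihood is out of scope. The per-10%
ratio is `exp(β·ln 1.1)` with CI bounds transformed identically; it is
invariant to any positive rescaling of the raw metric, which only shifts the
intercept. Per-unit-natural-log ratios (`exp(β)`) are reported alongside the
per-10% ratios, since printed ratios in this literature do not always state
the covariate scaling.

Quintile tabulation is rank-based: bin sizes differ by at most one when
values are distinct, and tied values always take the lower bin, so the bins
partition the cohort deterministically under any row order.

## Synthetic-data generator

The generator is the test bed: it produces data with the statistical
structure the analysis assumes, plus a ground-truth sidecar (resolved
coefficients and the materialised event list) that the pipeline proper never
reads.

**Road network.** A 6 × 6 grid of streets in the central 60% of a 5 km
extent (the urban core) with a road hierarchy — alternating local
(mean 800 vehicles/day) and collector (mean 6,000) lines — plus three
arterials crossing the full extent (mean 30,000). AADT values are lognormal
draws capped at 81,000, the busiest-segment count of the emulated county.

**Population.** Sex is Bernoulli(0.44 male); ages are drawn from a banded
mixture with weights 2853/2272/3953/9436/1401 for 0–4/5–9/10–19/20–64/65+,
matching the emulated cohort's published margins; block-group poverty comes
from a banded mixture concentrated in the 1–10% band. The highest-poverty
third of block groups is centred 100–400 m from an arterial (low-income
housing adjacent to high-traffic corridors); a 17% rural fringe lies outside
the core (the county is 83% urban). Residences scatter Gaussian (sd 150 m)
around their block-group centre with a 25 m minimum setback from road
centrelines. Age is drawn once and held fixed (the analysis treats age
cross-sectionally), and each person has one residence for the whole window,
mirroring the single-most-recent-address limitation of such registries.
Person-years are integers in [1, 11]; 55% of the cohort is resident for the
full window, the rest uniform — a round-number stand-in for the ~4–13%/year
migration such counties see.

**Outcome model.** Each person's total exacerbation count is
`Poisson(person_years × baseline_rate × exp(η))` with
`η = β₀ + β_d·ln(density) + β_sex·male + β_age·age + β_age2·age² + β_pov·poverty`.
Defaults: `β_d = ln(1.15)/ln(1.1) ≈ 1.466` (a per-10% rate ratio of 1.15,
the scale of effect reported for density metrics in this literature),
`β_sex = ln 1.29`, `β_pov = ln 1.02` per point, `β_age = 0.02`,
`β_age2 = −0.0005` (curvilinear, peaking near age 20), and
`baseline_rate = 0.065` events/person-year. With `beta0=None` (the default)
the intercept is set so the cohort mean of `exp(η)` is 1, making
`baseline_rate` the cohort-mean rate; any explicit `beta0` is used as given.
The defaults yield ≈ 0.06 events/person-year and ≈ 70–80% of persons with no
event, the scale seen in county asthma cohorts.

**Event materialisation and the round-trip contract.** Each drawn event
becomes one of the three detectable signatures (10% inpatient, 30% ED, 60%
outpatient triple — the mixture is configurable; registry studies rarely
publish this breakdown). Events, and two case-defining first-dx-asthma
outpatient visits per person (≤ 548 days apart), are assigned to *disjoint
30-day slots* within the person's residence window, with all visits of an
item inside days 0–13 of its slot. Items in different slots are therefore
≥ 17 days apart: clusters never merge, acute events never share a day, and
singleton case visits never seed spurious clusters — so the detector
provably recovers the generator's event list exactly, which the tests assert
seed by seed. A person whose Poisson draw exceeds the available slots is
clamped to the slot count (negligibly rare at the defaults) and the sidecar
records the materialised events. Background non-asthma visits
(0.8/person-year) are scattered freely; they are inert to the detector.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: no seasonal, diurnal or year-to-year traffic
variation (a single AADT per segment); no residential moves, visit-coding
errors, care-seeking differences by severity, or asthma visits that are
neither events nor the case pair; event timing is uniform over the window
rather than clustered in exacerbation-prone seasons; and the outcome truly
follows the stated log-linear Poisson model, so the parameter-recovery
results demonstrate correctness of the estimation machinery, not robustness
to model misspecification.

## Numerical and reproducibility choices

- One `numpy` Generator seeded from the configuration drives every draw;
  fixed config ⇒ byte-identical CSV/JSON outputs (tested).
- Raster cells, 6-significant-digit ESRI ASCII output, NODATA −9999,
  north-up row order; grid origin aligned to cell-size multiples.
- Degenerate inputs fail loudly: non-positive buffer radii, rasters not
  covering the network + cutoff, one-class outcomes, all-zero counts,
  metrics with fewer than five distinct values, missing exposure records
  (named by person id).
- Problem sizes used by the test suite and acceptance script: geometry
  oracles at 50 random polylines (0.1 m discretisation); mass conservation
  on 10 seeded networks; round-trip detection on 5 cohorts of 200;
  coverage at 100 replicates × 2,000 persons for each of the injected-effect
  (Poisson) and null (logistic) checks; gradient/ordering at one 5,000-person
  study plus 50 replicates of 1,000. These sizes give stable frequentist
  checks (a 95% CI should cover in ≥ 90/100 replicates) at desk-scale cost.

## Known limitations

- The per-10% ratio comparison *across* metrics is scale-sensitive: a
  coarser metric with compressed log-scale dispersion can show a per-10%
  ratio as large as the finer metric's even when it is the noisier proxy
  (its wider CI, not its point ratio, reflects the attenuation). Under this
  generator's outcome model — driven purely by ln(density) — the fitted
  per-10% ratios of VKT_250/VKT_500 are typically *not* smaller than the
  density ratio, and the corresponding acceptance check fails by design of
  the comparison, not by an estimation defect.
- The logistic model is a working model here: when counts are Poisson, the
  any-event probability is `1 − exp(−μ)`, not logistic in the covariates, so
  logistic coefficients under a nonzero effect have no closed-form truth
  (the null case is exact, and is what the coverage test asserts).
- Absolute density values depend on the kernel convention; only ranks and
  log-scale effects are transferable across implementations.
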