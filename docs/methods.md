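# Methods

`cvclm` implements a registry-based randomized *simulation* study of
scheduled central venous catheter (CVC) removal.  The question it addresses:
would removing every catheter on a fixed day (7, 14 or 21 after insertion)
lower the incidence density of catheter-related bloodstream infection
(CRBSI) compared with usual, unscheduled removal?  Because a true trial of
scheduled removal is impractical, the design randomizes *observed* registry
episodes 1:1:1:1 into three hypothetical-removal arms and a control arm, and
then emulates scheduled removal in the three arms by truncation.

## Reverse landmark truncation

For an arm with landmark day L, every record contributes
`min(dwell_days, L)` catheter days, and a CRBSI whose onset day exceeds L is
erased — the catheter "would already have been removed".  An onset exactly
on day L is retained, because the catheter is still in situ on the landmark
day itself; the rule `onset <= L` is the package's explicit tie convention.
Control records are the observed data, untruncated (the control code path is
the same truncation routine with an unbounded landmark, and the test suite
asserts the equivalence).  This is the *reverse* of a classical landmark
survival analysis, which conditions on survival to the landmark and
discards events *before* it.

Two endpoint families are computed per arm and CRBSI definition class
(definite only, `dCRBSI`; definite plus probable, `dpCRBSI`):

* CRBSI rate = events / catheters, in percent;
* incidence density = events / catheter days × 1000.

Incidence density is the primary scale: it is the comparable epidemiological
key figure for device infections, because truncation changes the person-time
denominator arm by arm.

## Synthetic registry

No real registry ships with the package; the generator draws cohorts whose
*control-arm* statistics match a set of calibration targets, by default:

| quantity | default target |
|---|---|
| episodes | 2984 over 6 centers |
| dwell time | median 14 d, IQR 7–23 d |
| definite-CRBSI incidence | 4.15 / 1000 CVC days |
| probable fraction of CRBSI | 37/87 |
| CRBSI onset day | median 13 d, IQR 10–20.5 d |
| day-7/14/21 platelet quartiles | (25, 72, 123) / (12, 20, 33) / (16, 30, 89) ×10³/µL |

plus covariate marginals typical of a hematology population (41% AML, 93%
jugular insertion, 59% male, 18% neutropenic at insertion, ~10%
antimicrobial-coated catheters) and a CoNS-dominated pathogen mix.

**Dwell times** are log-normal, floored to whole days (minimum 1), because
dwell days count *whole* days contributed to the CVC-day denominator.  The
fit to (q1, median, q3) minimizes squared log-quantile error and is
closed-form: μ is the mean of the three log quartiles, σ = log(q3/q1) /
(2·z₀.₇₅).  A log-normal is log-symmetric, so the asymmetric default targets
(14/7 = 2.0 vs 23/14 = 1.64) are met only in the least-squares sense: the
fitted quartiles are (7.2, 13.1, 23.8).  Tests therefore check that the
generator *realizes its fitted law* (sup-CDF distance < 0.01 at n = 10⁵) and
hits the configured targets to within the fit compromise (~1 day).  A
related consequence: the fitted distribution's mean (≈18.9 d) exceeds the
mean implied by the incidence target (events/incidence ≈ 16.2 d), so the
generated overall CRBSI fraction (incidence × mean dwell ≈ 13.6%) runs
about two points above the ~11.7% of a registry with a lighter dwell tail.
This is an accepted limitation of any two-parameter fit to three quartiles.

**Events.**  Each record may carry a latent infection time T, independent of
its dwell time; an event is recorded iff ⌈T⌉ ≤ dwell_days, with onset day
⌈T⌉ and class probable with probability `probable_fraction`, else definite.
Two families are available:

* `onset_lognormal` (default): T is log-normal and only a calibrated
  *susceptible fraction* π of records carries one (a cure-rate/frailty
  structure).  The (μ, σ) of T are fitted so that the distribution of
  *observed* onsets — the latent density tilted by the dwell survival
  function, since late infection times are censored by removal — matches
  the onset-quartile targets; π is then calibrated to the incidence target
  (incidence is linear in π, so one Monte-Carlo evaluation suffices).
  A rise-then-fall onset density is the empirically right shape here:
  infection hazard peaks during the post-chemotherapy neutropenic window
  one to three weeks after insertion.  No monotone-hazard family can put
  the onset quartiles at (10, 13, 20.5) while a substantial share of
  catheters remains at risk beyond day 30.
* `weibull`: T ~ Weibull(k, λ) with shape k > 1 encoding a monotonically
  rising hazard (default k = 1.5); λ is calibrated to the incidence target
  by bisection with common random numbers (the simulated incidence is then
  a deterministic, monotone function of λ).  This family is retained as an
  option and for the monotone-hazard property tests, but as default it
  concentrates too much hazard late: it cannot reproduce the observed
  onset quartiles, and in replicate studies it yields day-7-arm
  significance in only about half of runs rather than consistently.

Calibration targets *definite* incidence; since probable/definite labels are
independent thinning, the event-time scale is calibrated to
`target / (1 − probable_fraction)` on all events, which is expectation-exact.
Calibrated parameters depend only on the configuration (a fixed internal
Monte-Carlo stream of 2×10⁵ draws), never on the cohort seed, and are
cached, so replicate studies share one calibration.

**Covariates** (sex, disease, site, coating, dressing, neutropenia, age) and
platelet counts are drawn independently of each other and of the event
process; only marginals are targeted.  Real registries correlate these
(e.g. neutropenia with infection risk); joint modeling is out of scope, so
passing tests say nothing about covariate-conditional effects.  Platelet
counts on days 7/14/21 exist only while the catheter is in situ, are
log-normal-fitted to the quartile targets and rounded to the nearest
1000/µL.  Dwell time and infection are also independent — the generator
does not model infection-triggered removal.

## Randomization

Permuted-block randomization (block size 4 by default; 8 and 12 supported),
stratified by center, applied in cohort (insertion-date) order.  Within any
prefix of a stratum the arm counts differ by at most block − 1.  Trailing
incomplete blocks leave arm totals unequal by a few records; an optional
`truncate_to_balance` switch leaves those records unassigned instead, which
forces exactly equal arm sizes (the NNR, defined for equal arm sizes, is
then always computable).

## Inference

* **"N−1" χ² test** for the 2×2 rate comparison: Pearson's statistic scaled
  by (N−1)/N, referred to χ²(1).  Undefined (raises) on a zero margin.
* **Incidence z test**: z = (r₁ − r₂) / √(e₁/d₁² + e₂/d₂²) with rates
  rᵢ = eᵢ/dᵢ — the Poisson normal approximation on the rate difference;
  two-sided p.  The exact conditional-binomial test is the test-suite
  oracle; agreement is within 0.05 in p (the exact test's discreteness at
  double-digit event counts bounds what any continuous approximation can
  achieve) and the α = 0.05 significance call always coincides on
  study-scale inputs.
* **NNR** (number needed to remove) = ⌈ n / (e_control − e_arm) ⌉ for equal
  arm sizes n.  The ceiling is deliberate: it is the unique rounding under
  which all six study-scale NNR values (30, 94, 17 definite; 19, 40, 10
  combined, from events 25/42/4 and 46/68/7 vs 50 and 87 per 746) come out
  of the printed event counts, and it never overstates the benefit.
* **Two-proportion sample size**, normal approximation without continuity
  correction, pooled-variance (classical) or unpooled variant.  For
  p₁ = 0.06, p₂ = 0.03, α = 0.05, power 0.8 the pooled form gives 749 per
  group and the unpooled form 746; the design value of such a study is
  inside that variant band, so both are exposed and the band 743–749 is the
  honest statement of "what the formula gives".

No multiplicity adjustment is applied across the six arm-versus-control
comparisons, matching the single-study design this package models.

Recomputing the N−1 χ² on the study-scale event counts gives p = 0.0031
(25 vs 50 of 746), 0.389 (42 vs 50) and 0.107 (68 vs 87); published analyses
of such tables sometimes print 0.004, 0.38 and 0.10 depending on the exact
test variant and rounding path, so the package reports its computed values
and the test suite asserts agreement to ±0.01 only.

## Numerical choices

* σ of a quantile fit is floored at 10⁻⁹; an all-equal-quartiles fit is
  flagged `degenerate` rather than rejected.
* Onset-day rounding is ⌈T⌉, clamped to [1, dwell]; dwell rounding is
  floor, clamped to ≥ 1.
* Bisection for the Weibull scale runs on a log grid over [10⁻², 10⁷] to a
  relative width of 10⁻¹⁰, after an explicit bracketing check.
* The onset-distribution fit is Nelder-Mead on the tilted-quantile
  log-loss over a 0.05-day grid to 240 days, started at the untilted
  closed-form fit; it is deterministic and cached.
* Statistics are never rounded inside the library; presentation rounding
  happens only in reports.

## Problem sizes in the test suite

Distributional checks run at n = 10⁵ records, property sweeps at 10³–10⁴
random tables/records, the null-calibration check of the χ² test at 10⁴
replicates, and the replication study at 100 full pipelines of 2984 records
(one shared calibration).  These sizes put Monte-Carlo error well inside the
asserted tolerances while keeping the default suite around ten seconds.

## Known limitations

* Marginal-only covariate generation; no covariate-dependent hazards.
* Dwell and infection independent: no infection-triggered removal, so
  control-arm person-time includes post-onset days a real registry would
  not accrue; the overall event *fraction* consequently overshoots (see
  above) even while incidence, dwell and onset targets are met.
* Single catheter episodes only: no patient-level linkage across repeated
  insertions, no femoral sites, no calendar-time drift across a multi-year
  registry.
* The day-level resolution treats the onset-day-equals-removal-day boundary
  by convention; sub-day timing is unmodeled.
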