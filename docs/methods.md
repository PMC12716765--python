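# Methods

## Data model and deduplication

FAERS distributes each quarter as seven "$"-delimited ASCII tables (DEMO,
DRUG, REAC, THER, OUTC, INDI, RPSR) keyed by PRIMARYID, with CASEID grouping
successive versions of one case. Ingestion selects columns by name (the
layout drifted over 2004–2024), counts and logs every malformed line and
every detail row whose PRIMARYID is absent from DEMO, and never silently
drops input. Deduplication follows the FDA-recommended rule: per CASEID keep
the version with the latest FDA receipt date (FDA_DT), ties broken by the
highest PRIMARYID. Partial dates (year or year+month precision) are ordered
by their earliest completion so the rule stays a deterministic total order.
Dedup is applied globally across all loaded quarters, not per quarter.

Age is converted to years from FAERS unit codes (DEC ×10, YR ×1, MON ÷12,
WK ÷52.18, DY ÷365.25, HR ÷8766); values outside [0, 130] years and
unmappable codes become missing with a logged warning. Weight converts to kg
(LBS ×0.453592, GMS ×0.001). Reactions are a *set* of MedDRA preferred terms
per case; occurrence country is preferred with reporter country as
fallback.

## Cohort definition

A case is in the target cohort iff at least one of its drug rows matches the
synonym set (exact match after uppercasing and trimming; substring matching
is opt-in) under an accepted role code — default primary suspect (PS) only,
the designation reflecting the reporter's strongest causal attribution.
Everything else, including cases naming the target drug as concomitant,
secondary suspect or interacting, forms the background, so target +
background partition the deduplicated database. Counting is case-level: a
case with k distinct PTs contributes k PT counts but at most one count per
system organ class. The PT→SOC mapping is a user-supplied two-column file
(MedDRA is licensed and cannot be redistributed); unmapped PTs route to a
sentinel "UNMAPPED" class rather than vanishing.

## The four statistics

All four derive from the per-term 2×2 table built by subtraction from
cohort margins (b = n_target − a, d = n_background − c):

- **ROR** ad/bc with the Wald interval
  exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
- **PRR** a(c+d)/(c(a+b)) with the uncorrected 2×2 chi-squared
  (ad−bc)²N/((a+b)(c+d)(a+c)(b+d)).
- **BCPNN IC** log₂[aN/((a+c)(a+b))], the log₂ observed-to-expected
  reporting ratio. The interval bound IC025 = E(IC) − 2√V(IC) uses the
  closed-form beta-binomial posterior of the original BCPNN formulation with
  unit prior parameters (α₁ = β₁ = γ₁₁ = 1, α = β = 2; the formulas are
  reproduced in the `bcpnn_ic` docstring). A Monte-Carlo alternative —
  the 2.5% quantile of IC under a Dirichlet(a+1, b+1, c+1, d+1) posterior —
  is available as a config option; the two agree for large cells but the
  closed form shrinks small-count cells much more strongly, which is a
  property of its prior, not a defect.
- **EBGM** is the same observed-to-expected ratio aN/((a+c)(a+b)) on the
  natural scale, deliberately *without* the gamma-mixture empirical-Bayes
  shrinkage of full MGPS, with EBGM05 = exp(ln EBGM − 1.96·√(1/a+1/b+1/c+1/d)).
  Consequently IC = log₂(EBGM) exactly on every all-positive table — an
  identity asserted in the tests to 1e-12 and visible at printed precision
  in published signal tables. Implementing full DuMouchel shrinkage would
  change the numbers this closed form produces and is out of scope.

**Joint rule.** A term is a signal when all four pass: ROR lower bound > 1
with a ≥ 3; PRR ≥ 2 with χ² ≥ 4; IC025 > 0; EBGM05 > 2. Published threshold
statements differ between inclusive (≥) and strict (>) boundaries for PRR,
χ² and the count; the inclusive reading is the default and a `strict` switch
selects the other. An undefined statistic fails its test. **Zero cells**
make the Table-level formulas undefined; the default policy reports NaN with
an explicit flag, and a Haldane–Anscombe +0.5 correction on all four cells
is available, both conventions being current in pharmacovigilance. No
multiplicity adjustment is applied (screening practice reports raw values;
the χ² column supports any post-hoc correction).

## Demographics and volcano coordinates

The case table uses half-open bands matching the usual printed labels: age
<18, [18, 65), [65, 85] (boundary 85 inclusive), >85; weight <50,
[50, 100], >100 kg; missing is always its own category, so every block sums
to the cohort size. Percentages are rounded half-up to one decimal,
reproducing printed-table arithmetic (e.g. 944/2954 → 32.0). Outcome counts
take one outcome per case by severity priority DE > LT > HO > DS > CA > RI >
OT, which is what makes a printed outcome block sum to the case total.
Volcano coordinates are x = log₂(ROR), y = −log₁₀ P(χ²₁ ≥ χ²) for every
term with all cells positive.

## Time to onset

Onset is the whole-day difference from the earliest target-drug therapy
start date to the event date. Missing start, missing event, negative
intervals and (by default) dates of less-than-day precision are excluded
with per-reason counts; midpoint imputation (day 15 / July 1) is available
behind a flag that marks imputed records. Bins are half-open [lo, hi) with
default edges 0, 30, 60, 90, 180, 360, ∞, so same-day onset lands in the
first bin; the cumulative incidence curve is evaluated at every distinct
observed onset day and ends at 1 over included records.

## Synthetic generator

The generator emulates the structural hazards of real FAERS — heavy-tailed
PT marginals, duplicate case versions, partial dates, missing demographics —
with exact bookkeeping of what was planted. Each case includes PT j
independently with probability proportional to j^(−1.1), scaled to a mean of
3 PTs per case; a 10% share of cases take the target drug as primary
suspect; a planted signal (pt, ρ) multiplies that PT's inclusion probability
by ρ for target cases (capped at 0.99, infeasible ρ rejected), so unplanted
PTs have true rate ratio 1 by construction and the realized a/b/c/d cells
are recorded per PT. Duplicates re-emit a case under a new PRIMARYID with a
later FDA_DT (the stale version may lack the latest reaction, as real
follow-ups do); onset times mix an exponential early component (mean 8 days)
with a late component offset past day 360 (80/20 by default), matching the
early-dominated, long-tailed onset pattern spontaneous reports show. One
pseudo-random stream per concern is split from the master seed, so identical
configs give byte-identical bundles and adding fields never perturbs earlier
draws.

What the generator does **not** emulate: real MedDRA vocabulary and country
distributions, correlated PT co-reporting (PTs are independent given the
drug), drug polypharmacy structure, reporting-rate drift over calendar time,
and free-text drug-name noise. Passing the simulation suite therefore
demonstrates correctness of the pipeline's accounting and statistics under
a clean independence model, not robustness to real-world coding noise.

## Study sizes and calibration bands

Simulation studies use 20,000-case bundles (≈2,000 target cases — the order
of a single-drug FAERS cohort) over 200 PTs. Null calibration evaluates the
one-sided ROR criterion on PTs with expected a ≥ 10 (the Wald interval is
asymptotic; below that the 2.5% nominal rate is not meaningful) across 5
replicate bundles, judged against a 3σ binomial band around 2.5%; observed
rates run slightly high (3–5%), consistent with the Wald interval's known
mild anticonservatism at moderate counts. Rate-ratio recovery plants ρ = 2,
5, 10 on PTs whose expected signal cell is ≥ 50 and requires the median
pipeline ROR over 20 replicates within 15% of ρ — the ROR estimates an odds
ratio, which exceeds the planted rate ratio by a factor (1−p)/(1−ρp), under
4% at these inclusion probabilities. Onset-mixture recovery requires the
first-bin fraction within ±5 points of the planted 80% at n = 1,000 (the
early exponential leaks ≈2% of its mass past day 30, so the expected
fraction is 78.1%).

## Known limitations

- The unshrunk EBGM is the documented closed form, not MGPS with a fitted
  gamma-mixture prior; for small a it overstates the association relative
  to true empirical-Bayes shrinkage. Published EBGM05 columns computed with
  proprietary shrinkage are not reproducible from this closed form.
- The completeness predicate defining a "complete baseline data" subset of
  a real cohort is configurable rather than fixed; published subset sizes
  depend on unstated field choices.
- No stratified (age/sex-adjusted) contingency tables, no LLT→PT recoding,
  no legacy pre-2004 AERS layout, no download client.
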