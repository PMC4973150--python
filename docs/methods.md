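# Methods

This note documents the modelling choices behind `stageweaver`: the
staging algorithm's rules and the points where a rule had to be pinned
down, the net-survival estimator's numerical conventions, what the
synthetic-data generator does and does not emulate, and known limitations.

## The staging model

A tumour's stage at diagnosis is reconstructed from three source families:
a cancer **registry** (authoritative for person and basic tumour facts), a
**central cancer database** holding clinical (c), pathological (p) and
"integrated" (i) T/N/M codes, node counts, summary stages and (colorectal)
a Dukes stage, and a **clinical audit** holding per-treatment-record
pathological TNM, tumour-constant clinical TNM, and site-specific
investigation variables.  The algorithm has two parts.

### Part 1 — one overall T, N and M per tumour

Each component is resolved by walking a prioritised chain of
(source, variable) steps, shipped as data in
`resources/chains.yaml`.  The ordering principles:

* pathological variables outrank clinical ones for T and N (pathology
  confirms and extends the clinical assessment);
* for M the clinical value is preferred — distant metastasis is rarely
  evaluable at resection of the primary — with one exception: a
  pathologically confirmed M1 from any source overrides a clinical M0
  ("pathological confirmation" rule);
* audit variables outrank central-database ones at the same basis;
* integrated (i) variables, whose construction is not fully documented in
  source systems, are used only after every other option;
* **positive-evidence steps** (serosal involvement/perforation → T4,
  MRI T/N results carried over as categories, positive node count → N1,
  organ metastasis flags and liver CT → M1) act only while the running
  value is missing *or zero*, and only on positive findings.  Negative or
  unknown findings never impose a zero and never stop the walk.  A zero
  replaced by evidence is flagged `zero_upgraded`, which is why a
  variable's completeness can exceed its contribution in the accounting
  tables.

**Treatment-record selection (colorectal).**  Only audit records with a
procedure date within ±30 days of diagnosis (inclusive) contribute
pathological codes — staging further out risks describing restaging or
progression, not stage at diagnosis.  Eligible records are consulted
nearest-first; equal-dated records lowest-TNM-first (the TNM convention of
preferring the lower category in doubt, implemented as the sum of ordinal
ranks of the present pT/pN/pM with missing components ranked last); a
later record is consulted per variable only where earlier ones are
missing or invalid.  Records without a procedure date never contribute
pathological information.  Where the sources are silent on scope we read
serosal involvement and audit node counts from the date-eligible records
only (they are products of the same pathology episode), while MRI, liver
CT and metastasis flags — diagnostic work-up not tied to a procedure —
are read across all of the tumour's records, eligible first.

**Clinical-examination M0 inference.**  If M is still missing after the
whole chain but valid clinical T *and* clinical N codes exist anywhere in
the bundle, M is set to M0: legacy practice (Mx, pM0) frequently encodes
"clinically examined, no metastasis found" as a missing M.  The default
mode requires mere *presence* of the clinical codes; a stricter mode
(`m0_inference="selected"`) additionally requires that the resolved T and
N themselves came from clinical variables.

**Editions.**  Colorectal uses the TNM 5th edition by default (English
colorectal sources follow it, and stage-grouping definitions are unchanged
by later editions); lung uses the 7th, with a per-record audit edition
flag honoured when present.  Codes valid in some other edition for the
site (e.g. T4a/T4b, N1c, M1a under colorectal 5th) are rejected with an
edition-conflict flag; `accept_union=True` validates against the union of
editions instead.  `Mx` and blank codes are "not assessed"; `pM0` is
suppressed (absence of metastasis cannot normally be established
pathologically), so a pathological M variable is informative only when
positive.

### Part 2 — grouped stage I–IV under two strategies

Grouping evaluates M → N → T against the edition's truth table (shipped
in `resources/grouping_tables.csv`, sub-stages collapsed to numerals):
any M1 is stage IV; node-positive M0 disease is stage III at any T for
colorectal, and at N2/N3 for lung (lung N1 needs T to separate stages II
and III, so a missing T with N1 is not gradeable from components).
T0/Tis carry no stage group here and fall through to the fallbacks.

* **Restrictive strategy:** all three components must be present and
  assessed; otherwise the stage is missing.  Grouped summary-stage
  variables are ignored because their component basis cannot be verified.
  An optional dominance relaxation (off by default) lets an assessed M1
  alone grade stage IV.
* **Non-restrictive strategy:** missing N and/or M are imputed to zero
  (recorded per tumour); tumours still ungraded fall back to
  summary-stage variables in the order audit pathological, audit
  clinical, central pathological, clinical, integrated — then, for
  colorectal, Dukes (audit pathological, audit clinical, central), via
  the standard correspondence A→I, B→II, C→III, D→IV.

The imputation is a strong assumption: a truly node-positive or
metastatic tumour with missing N/M is *downgraded*, which the synthetic
tests measure directly (the misclassified set equals exactly the set of
truth-III/IV tumours whose N/M information was removed).

## Record linkage

Patients are matched by an ordered eight-level hierarchy over NHS number,
date of birth, sex and postcode (full agreement first, progressively
weaker combinations later, postcode district at level 7); the first level
with a *unique* registry candidate wins and ambiguous levels fall
through.  Tumours then join within the matched patient by ICD-10
3-character topography prefix and nearest diagnosis date within a 90-day
window (ties to the earlier record).  Both the level definitions and the
window are package fixtures, configurable in the pipeline config; they
are deliberately conservative defaults, not estimates of any national
linkage system.  On uncorrupted synthetic data the defaults link every
source record to its own tumour with no false links.

## Net survival

The Pohar-Perme estimator is computed in counting-process form on a
**daily grid**: each subject's expected cumulative hazard is accumulated
from life-table annual hazards (age × sex × calendar year × deprivation
quintile; annual probabilities converted by h = −ln(1−q)), with attained
age and year advancing in whole 365.25-day years and capped at the table
maxima.  Weights w_i(t) = 1/S_Pi(t) use the expected survival at the
start of the day.  Numerical conventions:

* Net survival is the **product-integral** ∏(1 − dΛ_E) rather than
  exp(−Λ_E).  The two differ by O((h/365)²) per day for the continuous
  expected-hazard part, far below the 1e-6 discretisation tolerance, and
  the product form collapses *exactly* to Kaplan-Meier when the expected
  hazard is zero — a sharp degenerate-limit test.
* The variance of Λ_E is the weighted martingale estimator
  Σ_s Σ_i w_i² dN_i(s)/(Σ_i w_i Y_i(s))², carried to the NS scale by the
  delta method; 95% intervals are normal-scale, floored at 0 (the CI
  construction is this package's choice).
* Deaths on the same day are processed jointly; an emptied weighted risk
  set truncates the estimate, which is carried forward with a warning.
* The estimator may exceed 1 in noise; it is not clipped.

Age standardisation uses the ICSS-1 weights (0.07, 0.12, 0.23, 0.29,
0.29 over ages 15–44, 45–54, 55–64, 65–74, 75–99), renormalised over the
age bands actually contributing subjects; NS_std = Σ w_g NS_g and
var_std = Σ w_g² var_g.  The missing-stage category is analysed as a
stratum like any other.  The "complete" approach is used throughout:
everyone diagnosed in the window contributes, censored at the study end
date, so late horizons rest on the earliest diagnosis years only.

## The synthetic-data generator

`synthetic.generate_cohort` emulates the *structure* of the three-source
staging problem, not English epidemiology.  Defaults define the study
conditions: diagnosis years 2008–2012 with follow-up to end 2013; true
stage distribution (I–IV) = 0.170/0.285/0.302/0.243; age ≈ N(71, 11)
clipped to 15–99; 53% male; uniform deprivation; central-database
coverage 0.97 and audit coverage 0.75; per-variable missingness shaped on
the completeness patterns of English audit/central staging data (sparse
pathological audit codes for colorectal, dominant clinical audit codes
for lung, widespread integrated variables); legacy `Mx` emission at rate
0.06 on M variables; zero-coded-M-contradicted-by-evidence conflicts at
rate 0.10 among truth-M1 tumours; duplicate treatment records (0–2
extras, offsets ≈ N(10, 28) days, straddling the ±30-day boundary) whose
farther records may carry restaged, one-rank-higher pathological codes;
stage-specific excess hazards 0.012/0.035/0.095/0.40 per year added to a
Gompertz-shaped population hazard with sex and deprivation gradients.
Raw codes are emitted in jittered formats ("T2a", "2a", "t2a", "pT2a") to
exercise canonicalisation.  Survival times are drawn by inverse sampling
from the additive population+excess daily hazard, matching the
net-survival framework being tested.

Every tumour carries a truth record, including the expected resolved
category and source per component, computed by an independent
presence-walk over the chains — the oracle the derivation property tests
compare against.

What the generator does **not** emulate: real incidence or survival
levels, geographic or temporal structure, morphology-dependent staging
behaviour, informative missingness (missingness is independent of stage
given the variable), or linkage error beyond simple field
corruption.  Passing tests therefore demonstrate that the *rules* are
implemented faithfully and recover planted truths, not that any
particular real-world completeness or survival figure would be
reproduced.

## Problem sizes and test design

The property suites run at sizes chosen to make binomial/Monte-Carlo
error negligible while keeping the default test run quick: 200 simulated
cohorts of n=1,000 for the strategy-dominance sweep, n=5,000 for exact
recovery, and 500 replicates of n=2,000 for the estimator's
constant-hazard recovery (mean NS(5) within Monte-Carlo error of
exp(−5λ_E)).  `scripts/acceptance.py` re-runs the same checks from
scratch under a caller-supplied seed.

## Known limitations

* No adjustment for neoadjuvant therapy: pathological components
  collected after downstaging treatment are taken at face value, as
  routine sources rarely record neoadjuvant exposure.
* No multiple imputation of missing stage; the restrictive strategy
  deliberately leaves the missing category open for such methods.
* The node-count evidence rule imposes N1 only — counts cannot separate
  N1/N2 thresholds without site-specific node tables.
* Dukes→TNM correspondence (A→I … D→IV) is the standard approximation;
  the two systems are not bijective.
* Life tables must be single-year-of-age; no smoothing or interpolation
  is applied.
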