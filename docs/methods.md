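# Methods

This note documents the models, conventions and numerical choices behind
`ahpdc`, and what the synthetic-data validation does and does not
demonstrate about real claims data.

## Data model and date arithmetic

Claims are three tables joined on an opaque `patient_id`: patients
(sex, birth year-month), diagnoses (ICD-10 code, date, inpatient/outpatient
setting) and prescriptions (product code, date, days supplied, daily pill
count, setting). Dates are calendar dates externally; all coverage and
window arithmetic converts them to integer day offsets from the per-patient
index date, and every window is half-open `[start, start + length)`. This
single convention removes the off-by-one ambiguities that otherwise creep
into coverage computations (a 30-day supply dispensed on day 0 covers days
0–29; the follow-up window `[0, 365)` contains exactly 365 days).

Age at index is computed from birth year-month assuming day 1 of the month,
because claims databases typically store only year and month of birth. The
error is at most one year, always in the direction of overstating age for
births later in the month; at the default minimum age of 20 in a cohort
with mean age around 70 this has negligible effect.

## Drug ontology

Products map to a closed set of antihypertensive classes (CCB, ARB, ACE
inhibitor, β-blocker, α-blocker, thiazide, loop diuretic, aldosterone
antagonist, other). A fixed-dose combination (FDC) is a product with
`n_agents ≥ 2`; it decomposes into all constituent classes for every
coverage and counting purpose. Loop diuretics and aldosterone antagonists
have major indications other than hypertension, so a regimen whose class
union is contained in those two classes is excluded from the cohort; an
FDC spanning an excluded and a kept class keeps the patient in ("solely"
is read literally). The shipped formulary (~29 representative products,
including the marketed FDC patterns CCB+ARB, ARB+thiazide and
CCB+ARB+thiazide) is a synthetic fixture for simulation and testing, not an
authoritative coding dictionary; coding is class-based, with ATC codes
carried as metadata only.

## Cohort selection

Six criteria, applied in a fixed order with exclusions attributed to the
first failure: outpatient hypertension diagnosis (ICD-10 prefix I10);
an outpatient antihypertensive prescription inside the enrollment period
(earliest such date = index date); age ≥ 20 at index; ≥ 1 claim of any kind
in the look-back window `[index − 365 d, index)`; ≥ 1 antihypertensive
prescription in every persistence sub-window of the follow-up; and an index
regimen that is not loop/aldosterone-only. Permuting the criteria changes
only the attribution, never the final cohort, and the attrition table
telescopes exactly (both are tested).

The persistence requirement ("a prescription every 3 months") is anchored
by default to the patient's own follow-up window, quartered as
91/91/91/92 days with the last window absorbing the remainder. An
alternative calendar anchoring (sub-windows of the enrollment period) is
available via `persistence_anchor="calendar"`; the per-patient reading is
the default because adherence itself is measured over the per-patient
follow-up.

## PDC computation

`UNION` (default) is the standard PDC convention: a day is covered if at
least one supply spans it; overlapping supplies are merged and each
calendar day counts once. `SHIFT_FORWARD` treats an early refill as
stockpiled: processed in date order, a supply overlapping the previously
covered span starts the day after that span ends. Shift-forward coverage is
always a superset of union coverage (shifting only defers supply, never
destroys it), which is asserted on random instances. Prescriptions dated
before the index date contribute only the part of their supply that reaches
into the window (with a warning); supplies are clipped at the window end.

Two aggregation modes: `ANY` counts a day covered by any product whose
class set intersects the drugs of interest (used for overall adherence over
all antihypertensive classes); `ALL` counts a day only if every class of
interest is supplied that day, with an FDC supplying all its constituent
classes simultaneously (used for combination-regimen adherence, where
taking only half the regimen should not count as adherent). ALL-mode PDC
never exceeds ANY-mode PDC.

The interval engine is validated against brute-force oracles on thousands
of random prescription sets: a boolean 365-day array for `UNION`, and a
day-by-day pill-stock simulation for `SHIFT_FORWARD`.

Category boundaries follow the conventional integer-percent labels read as
half-open fraction intervals: high `[0.80, 1]`, intermediate
`[0.40, 0.80)`, low `[0, 0.40)` — so every value in `[0, 1]` is classified,
including e.g. 79.5%. Inpatient-dispensed supplies count toward coverage by
default (`inpatient_supply_counts=False` restricts to outpatient).

## Regimen classification

"Drugs" counts active ingredients: an FDC of two agents is two drugs, two
distinct CCBs are two drugs (a `products` basis is available as a config
switch). "Pills" sums daily tablet counts, so pills can exceed drugs only
when some product is taken more than once daily — the pattern that makes
mean pills exceed mean drugs in real cohorts. Duplicate products on the
index date merge with pill counts summed. The studied combination groups
(CCB+ARB, ARB+thiazide, CCB+ARB+β-blocker, CCB+ARB+thiazide) require exact
class-set equality, keeping groups disjoint. FDC exposure is binary: a
regimen containing any FDC is "FDC" (even when redundant), otherwise
"single drug combination". Redundancy means an FDC co-prescribed with a
single agent sharing at least one class with that FDC.

## Statistics

Group means are compared with Welch's unequal-variance two-sided t-test
(Welch–Satterthwaite degrees of freedom); a pooled-variance Student's t is
available as a sensitivity switch since the choice is not determined by the
analysis plan. Degenerate zero-variance groups are handled explicitly
(detected by zero range, not floating-point variance): equal means give
t = 0, p = 1; unequal means give a signed infinite statistic and p = 0.
Displayed percentages and mean PDC round half-up to one decimal;
machine-readable outputs keep full precision. No multiple-testing
correction is applied; the adherence-by-count table tests each bin against
the 1-drug (1-pill) bin only, and comparisons with fewer than two
observations in a group are reported as skipped with a reason.

## Synthetic claims generator

The generator emulates the structure the analysis assumes: hypertensive
outpatients with an index prescription uniformly dated in the April 2014 –
March 2015 enrollment window, age ~ N(70.1, 11.5²) clipped to [21, 99],
57% male, comorbidity diagnosis codes at prevalences 26.1% (diabetes),
59.6% (dyslipidemia), 18.9% (gout/hyperuricemia), 10.0% (renal), 53.2%
(heart disease), 20.2% (cerebrovascular), 17% hospitalized, and 1–4
look-back dispensings dated before the enrollment period but inside the
look-back window (so the index prescription stays the first in-period
dispensing).

Refills follow a renewal process: each dispensing covers `days_supplied`
(default 30) and the next follows after `days_supplied + gap`, where the
gap is a non-negative integer draw with mean *m* and dispersion *d*
(negative-binomial shaped, variance `m + d·m²`; `d = 0` degenerates to a
constant gap). With no discontinuation the long-run covered fraction is
`days_supplied / (days_supplied + m)` — the closed form used for parameter
recovery. Over a finite window anchored at the first fill, realized mean
PDC slightly exceeds this limit (the window opens on a covered run and
tends to close mid-cycle), a start-up excess of order one refill cycle per
window; recovery tests therefore measure over a 50-year horizon with a
tolerance of 3 Monte-Carlo standard errors plus a one-cycle truncation
allowance — the latter being the exact worst-case remainder and the only
nonzero term for dispersion-0 strata, whose sequences are deterministic.

The default adherence mixture — 88% high (gap mean 2 d), 7% intermediate
(25 d), 5% low (60 d, constant) — reproduces the mostly-adherent profile
typical of treated hypertension (~87% of the cohort lands in the high
category; expected coverages 0.94 / 0.55 / 0.33). All default strata have
zero discontinuation and gaps capped at `persistence_window −
days_supplied` (61 d), which guarantees a refill in every persistence
sub-window: a discontinuing or arbitrarily-gapped "compliant" patient would
silently fail selection and break the exact attrition bookkeeping that the
violator-injection design provides. The regimen menu mixes the common
monotherapies with the four studied combinations, FDC usage probabilities
(25% for CCB+ARB, 80% for ARB+thiazide) and redundant same-class
co-prescription at rates of a few to ~25% of FDC regimens, in line with
the patterns such analyses report. All products in a regimen are dispensed
at the same visits, as at a single prescribing encounter.

Violators are generated compliant first, then minimally mutated so each
violates exactly one named criterion (e.g. all in-period outpatient
dispensings switched to inpatient for the no-index-prescription violator;
one follow-up quarter's dispensings deleted for the persistence violator).
This makes the attrition table exactly predictable from the ground-truth
table, which is asserted at the count level.

### What the synthetic validation does not show

The generator does not model dose titration, drug switching, leftover
medication, mid-year regimen changes, seasonal effects, or any correlation
between adherence and demographics/comorbidity beyond what is explicitly
configured. Passing tests therefore demonstrate that the pipeline's
bookkeeping, coverage arithmetic and statistics are correct under known
conditions — not that any particular population-level adherence figure
would be reproduced on a real claims database, which depends entirely on
the source data.

## Problem sizes

Default runs use 1000–4000 synthetic patients (the acceptance script uses
4000 with a 2% per-criterion violator rate), 1000-instance random suites
for the oracle-equivalence and ordering properties, and 500 patients per
stratum for parameter recovery; these sizes give stable estimates with
comfortable statistical margins.

## Known limitations

Which drug set a real analysis uses for "overall" adherence (any
antihypertensive vs. the index regimen) is a reporting choice; both are
computable here (`drugs_of_interest` + mode). The hospitalized flag is any
inpatient claim during observation (look-back through follow-up). Reported
dispersion of mean PDC can be summarized as either s.d. or s.e.; outputs
carry both to avoid ambiguity. Unknown product codes either raise (strict
mode) or map to the residual antihypertensive class with a warning —
mapping unknown codes to a non-antihypertensive category would require a
formulary of all co-medication, which is out of scope.
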