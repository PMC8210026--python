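# Methods

This note documents the analytical model behind `amskit`: definitions,
tunable parameters and their defaults, the design choices made where the
underlying concepts are genuinely open, what the synthetic-data generator
does and does not emulate, and known limitations.

## Therapy-episode linkage

Prescription records are the unit hospitals store; the clinically
meaningful unit is a *therapy episode* — a maximal period of
uninterrupted antibacterial therapy, possibly spanning several
prescriptions and drugs. Episodes are constructed as connected components
of a per-patient graph over eligible prescriptions (status `completed`
unless configured otherwise, ATC code matching an antibacterial prefix,
default `J01`). Two prescriptions are linked when either rule holds, all
comparisons closed (≤):

* **combination** — start times within `combination_window_hours`
  (default 6 h) and overlapping intervals;
* **continuation** — the later prescription starts within
  `continuation_window_hours` (default 36 h) of the earlier one ending.

The 6 h / 36 h defaults follow the conventions of published follow-on
stewardship software; both are configuration fields, and the monotonicity
property (a wider continuation window never increases the episode count)
is enforced by test. Ties on identical start times break on
`(start_time, prescription_id)` so the partition is order-invariant.
Episode boundaries come from administrations (first/last administration,
falling back to the prescription interval with a warning), because
administration records reflect therapy actually delivered. Linkage is
patient-level — episodes may span admissions — and admission attribution
happens afterwards via the first member prescription.

## Consumption metrics

* **LOT** (length of therapy): days between first and last administration
  in the episode; a single administration gives LOT 0.
* **DOT** (days of therapy): over a scope (episode or admission), the sum
  over drugs of distinct calendar days with at least one administration
  of that drug. Combination therapy counts once per drug per day, so
  DOT ≥ days with any therapy and LOT ≤ DOT typically holds per
  admission with combination therapy. DOT is counted from administration
  records rather than prescription durations.
* **DDD**: administered dose converted to grams divided by the drug's
  defined daily dose per (drug, route). Only a small demonstration DDD
  table ships; drugs absent from the table are reported as uncounted,
  never silently zeroed.
* Rates: DOT per 1000 bed-days carries an exact (Garwood/chi-square)
  Poisson interval; LOT and DOT per 1000 admissions are also reported.
  Grouped summaries always include an `all` row equal to the ungrouped
  computation, and groups partition the totals.

## The hourly therapy table and ACD switch criteria

Each episode gets one row per hour from start to end (a zero-length
episode gets a single row). Every marker is computed strictly from
observations at or before the row time (windows are closed `[t − w, t]`);
perturbing any future observation cannot change a past row, and this
no-look-ahead property is tested directly. Missing windows yield nulls,
never imputed values.

Criteria evaluated per row:

* **A** — every temperature in the past 48 h within 36–38 °C, requiring
  at least one reading. The marker-level 48 h window is used rather than
  the looser 24 h phrasing sometimes attached to "afebrile"; the window
  is configurable. Coverage is not required — the criterion asks that no
  out-of-range reading exists, not that readings be continuous.
* **C** — max HR (12 h) < 90, max RR (24 h) < 20, stable systolic BP, WCC
  in 4–12 × 10⁹/L or above 12 with a negative 72 h trend, and CRP below
  its 72 h peak.
  * "Stable blood pressure" has no standard operational definition; here
    it means min SBP over 24 h ≥ 90 mmHg and (max − min) ≤ 40 mmHg, both
    configurable. This captures "no hypotension, no large swings" without
    inventing a shock index.
  * "Falling CRP" means the last value strictly below the 72 h peak; a
    configurable relative-drop threshold (default 0, i.e. any decrease)
    tightens it.
  * The WCC trend is the least-squares slope (per day) over the trailing
    72 h, requiring ≥ 2 observations; no minimum slope magnitude is
    demanded for "falling" since none is clinically established.
* **D** — no admission diagnosis whose ICD-10 code starts with a prefix
  on the high-risk list (endocarditis, osteomyelitis/septic arthritis,
  liver/intracranial/undrained abscess, empyema and cavitating pneumonia,
  *S. aureus* bacteraemia, necrotizing soft-tissue infection,
  chemotherapy neutropenia, infected implants, meningitis/encephalitis,
  mediastinitis, cystic fibrosis/bronchiectasis). The list ships as an
  editable configuration.

Criterion B (ability to take oral medication) cannot be derived from
structured inpatient records and is deliberately absent; "criteria met"
means A ∧ C ∧ D. A missing marker fails its criterion (conservative: the
pipeline will not recommend a switch it cannot substantiate); an
ignore-missing mode exists for sensitivity analysis. Worsening any single
marker can only switch the conjunction off, never on.

**Switch delay.** IV sequences are maximal runs of consecutive IV
prescriptions in episode order. A run followed by an oral prescription is
`converted_to_oral` (conversion time = the oral start); otherwise it is
`continued_to_end`. "Converted in full" is interpreted strictly: a later
IV prescription starts a new sequence. The delay is conversion time (or
sequence end, for never-switched runs) minus the first grid hour at which
A ∧ C ∧ D held; negative intervals (criteria met only after the event)
are undefined rather than clamped to zero. Interleaved IV and oral
combination therapy is resolved purely by start order; simultaneous
mixed-route combinations are rare and mark the table row `mixed`.

## Severity and guideline congruence

URB-65 is CURB-65 with the mental-confusion item structurally absent
(that item is unreliable in routine records), so the total (0–4) is a
lower bound on the full score. Components use the observation nearest to
therapy initiation within ±48 h: urea > 7 mmol/L, RR > 30/min,
SBP < 90 mmHg, age ≥ 65; missing components score zero and are listed.
The printed RR footnote threshold (> 30) is used rather than the BTS
convention (≥ 30); it is configurable.

Congruence compares the initial regimen — the drug set of prescriptions
starting within the combination window of the episode's first start —
by exact set match against guideline strata ordered by severity. Matching
the patient's own stratum yields `recommended` (or
`allergy_alternative`); matching only a higher stratum,
`higher_severity_regimen` (escalation); only a lower one,
`lower_severity_regimen`; otherwise `other`. Own-stratum matches take
precedence, then higher before lower; the categories are mutually
exclusive and exhaustive. The bundled community-acquired-pneumonia
guideline (amoxicillin at score 0–1; amoxicillin or benzylpenicillin plus
clarithromycin at score 2; co-amoxiclav plus clarithromycin at 3+;
doxycycline/moxifloxacin as allergy alternatives) is the worked example,
together with the printed 17-regimen × 2-severity count table it is
evaluated against. In that table's source the text total (2569) disagrees
with the column totals (927 + 1602 = 2529); the printed table rows are
taken as authoritative.

## Culture-before-treatment

A prescription is "cultured" when its episode started with at least one
qualifying specimen collected in `[start − 72 h, start + grace]`.
Defaults: 72 h look-back, zero grace, qualifying groups blood, drains,
respiratory, intravascular devices, CNS, aspirates and tissue/bone, with
a `blood_only` scope for the stricter view. The source material states
the window two ways ("3 days leading up to" initiation vs "within 3 h
of" sampling); the 72 h look-back is the default and the
`grace_hours_after` parameter (set it to 3) reconciles the stricter
reading. Linkage is monotone in the window length.

## Resistance interpretation and profiling

MIC: value ≤ S bound → S, value > R bound → R, else I; disc zones mirror
the comparisons. Only a small demonstration breakpoint table ships —
full interpretive tables are versioned and licence-sensitive, so the
table (and its version year) is a configuration input. A lab-reported
interpretation is used as a flagged fallback when no rule matches.

Profiling follows the standard MDR/XDR/PDR definitions with I counted as
non-susceptible (configurable): MDR = non-susceptible in ≥ 3 categories;
XDR = non-susceptible in all but ≤ 2 tested categories; PDR =
non-susceptible to every tested agent; < 3 categories tested →
unclassifiable. On small panels the literal XDR inequality can hold with
fewer than 3 non-susceptible categories, which would break the
PDR ⇒ XDR ⇒ MDR nesting, so XDR additionally requires the MDR floor. The
classifier is verified against an exhaustive truth table up to 6
categories. An optional per-organism exclusion list (empty by default)
removes intrinsic resistances before counting.

## Indication inference

The harness — not the learner — is the reusable part: categories with
fewer than 50 labelled episodes are reclassified `other`; features are
extracted from initiation-time context only (initial drug set and route,
speciality, admission method, age band, ICD-10 chapter flags, last
WCC/CRP/urea in the preceding 72 h with missingness indicators; the
encoding is stateless, so no fold leakage is possible); evaluation is
repeated stratified 5-fold cross-validation, reporting one-vs-rest
balanced accuracy per class ((sensitivity + specificity)/2) and their
unweighted mean. Any fit/predict estimator can be injected; the default
is a 100-tree random forest reseeded per fold. Validation is by
property — chance-level accuracy on label-independent features, 1.0 on
separable data, monotone improvement with planted signal strength —
because no public labelled audit data exists to benchmark against.

## The synthetic cohort generator

`CohortParams` defaults describe a plausible acute-hospital cohort:
500 patients, 70% emergency admissions, 35% of admissions treated with
antibacterials, 1 + Poisson(0.15) episodes per treated admission,
1 + Poisson(1) sequential prescriptions per episode with a 20% chance of
a combination partner each (≈ 2.4 prescriptions/episode), 70% of
episodes starting IV with 36% of those converting to oral, a lognormal
switch delay with mean 3.6 d (median ≈ 2.2 d), 22% culture sampling, 30%
pneumonia indication with planted URB-65 component rates
(urea 35%, RR 15%, SBP 10%), and resistance categories planted at
60/25/10/5% (susceptible/MDR/XDR/PDR).

Construction guarantees, not estimates:

* within-episode gaps are drawn from (2, 22) h — strictly inside the 36 h
  continuation window — and cross-episode gaps from (72.5, 140) h —
  strictly outside it *and* beyond the 72 h culture look-back — so the
  true episode partition is exactly recoverable and specimens cannot
  bleed across episode windows (specimens are planted only on a
  patient's first episode for the same reason);
* vitals are piecewise "septic then recovering" series sampled every 6 h;
  the last septic observation at offset *g* pins the planted
  criteria-met time to exactly *g* + 49 h (the 48 h afebrile window plus
  one grid hour), which the pipeline recovers to the hour;
* for converted episodes the oral prescription starts exactly the drawn
  delay after the planted criteria time, so recovered delays equal
  planted delays sequence-for-sequence;
* the expected mean LOT follows in closed form from the parameters
  (`CohortParams.expected_lot_days()`, ≈ 5.8 d at defaults) as a mixture
  of converted-IV and chained-backbone episodes.

What the generator does **not** emulate: measurement noise structure of
real vitals (real temperature curves are not two-level processes),
multi-admission patients and episodes spanning admissions, ward
transfers, prescription cancellations and edits, mixed-route combination
therapy, missing-not-at-random laboratory sampling, and organisms beyond
two stylized groups. Passing the recovery tests therefore demonstrates
the *correctness of the analytic machinery under its stated definitions*,
not the robustness of those definitions to real-world data quality.

An adversarial analysis mode is available implicitly: setting
`gap_hours`/`cross_gap_hours` near the 36 h boundary exercises window
sensitivity (the generator refuses distributions that straddle it, so
boundary studies are done through the linkage configuration instead).

## Numerical and degenerate-input choices

* Timestamps are timezone-naive ISO-8601 at minute resolution; one
  implicit timezone per bundle.
* Malformed rows are quarantined to a row-errors table on load, never
  silently dropped; validation is report-only and idempotent.
* Proportions use Wilson 95% intervals (well-behaved at the small
  per-team denominators typical of team-level feedback); means use
  t-intervals with zero width for n = 1 or constant values; empty groups
  are omitted; zero-exposure rates return NaN rather than dividing by
  zero.
* The WCC trend needs ≥ 2 points with distinct times; otherwise null.
* An episode with no administrations falls back to prescription
  intervals with an explicit warning; with neither, LOT is NaN and
  flagged.

## Problem sizes

Tests run on cohorts of 120–500 synthetic patients (≈ 190 episodes at
500), 200 random prescription sets for the linkage oracle, exhaustive
resistance patterns to 6 categories, 1000 simulated groups for interval
coverage, and 300-sample cross-validation runs — sizes at which every
Monte-Carlo check has comfortable power while the whole suite completes
in well under a minute per module.
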