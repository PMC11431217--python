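# Methods

## The validation model

An encounter is **algorithm-positive** when any of its ICD-10 codes starts
with one of the AHI set's 23 include prefixes. Prefix matching is a
deliberate choice: the set mixes three-character categories (`N17`, `E87`,
`R55`) with four-character codes (`T670`…`T679`), and administrative data
record diagnoses at variable specificity, so `N17` must capture `N170`–`N179`.
`E875` is retained verbatim even though `E87` already covers it; the matcher
is unaffected. `W92` (human-made heat: saunas, industrial settings) is
excluded from the includes but never *vetoes* a chart that also carries an
include code — exclusion means "not part of the algorithm", not negation.

The **gold standard** is a conjunction read off the chart: documented
patient-reported heat exposure AND at least one documented heat-related
complaint from a controlled vocabulary (default: syncope, heat stroke, loss
of consciousness, muscle cramps, pain, exhaustion, fatigue, edema; the field
list is open-ended, so the vocabulary is user-extensible, but a closed
default set is required for testability). Unknown terms are an error, not a
silent non-match.

The **two-stage design** estimates PPV from a simple random sample of
algorithm-positive charts (default n = 62) and Sn/Sp/NPV from an independent
simple random sample of the whole cohort (default n = 964). The two samples
are drawn independently, with overlap permitted (whether the original study
excluded stage-A charts from stage B is unstated; independent draws are the
simpler default). PPV is never computed from the stage-B table and the
samples are never pooled. A fraction (default 20 %) of the stage-B sample is
reviewed in duplicate; the paired labels feed an unweighted Cohen's kappa,
and the first reviewer's label is authoritative for the 2×2 (disagreement
resolution was unstated; this rule keeps the 2×2 independent of the second
reviewer).

## Confidence intervals

Two methods are always computed and labelled:

* **Wald**: p̂ ± z·√(p̂(1−p̂)/n), clipped to [0, 1]. This is the method behind
  the "p ± h" presentation of the published results (all four printed
  half-widths — 12.1, 42.4, 0.4, 0.0 percentage points — reproduce it
  exactly), and it is what the worked-example tests assert. It collapses to
  zero width at p̂ ∈ {0, 1}.
* **Wilson with continuity correction** (Newcombe's closed form): the bounds
  solve (|p̂ − p| − 1/(2n))² = z²·p(1−p)/n on either side of p̂, with
  lower = 0 at k = 0 and upper = 1 at k = n. This is the better interval at
  boundary proportions and the recommended one for reporting. The closed
  form is verified against an independent bisection root-finder to 1e-6
  over every k for n ≤ 50.

z is computed from the normal quantile at (1+conf)/2, never hard-coded, so
any confidence level works. Display rounding is one decimal place on
percentages (round-half-even), two decimals for the cohort positivity
(whose natural scale is hundredths of a percent); all internal computation
is full precision.

## Sample sizes

Hajian-Tilaki closed forms with ceilings (never rounding): the PPV branch
n = ⌈z²·P(1−P)/d²⌉, and the Sn/Sp branch n_Sn = ⌈z²·Sn(1−Sn)/(d²·prev)⌉,
n_Sp = ⌈z²·Sp(1−Sp)/(d²·(1−prev))⌉ with the requirement being the larger
component. Both components are always reported because a single "total"
number hides which metric drives the cost. With the standard planning inputs
(Sn 0.40, Sp 0.90, prev 0.10, d 0.10, 95 %) the formulas give 922 and 39.

## Cohen's kappa

Unweighted, two raters, two categories: κ = (p_o − p_e)/(1 − p_e) with p_e
from the marginal products. When both raters are constant with the same
label, p_e = 1 and kappa is undefined — the implementation raises rather
than returning a sentinel, and the pipeline records the condition in the
report instead of a number. This matters in practice: with ~0.4 % gold
prevalence, a 193-chart duplicate subset is frequently all-negative for both
raters, so a study-scale synthetic run often cannot produce a kappa at all,
and when it can, the estimate is dominated by a handful of discordant
charts. No published agreement table exists to reproduce, so no particular
kappa value is asserted anywhere; the implementation is instead checked
against a reference implementation over all small agreement tables.

## Day classes

Two schemes, each assigning every day exactly one class:

* **Fixed bands**: < 20 °C cool, [20, 31) moderate, ≥ 31 °C hot. 31 °C is the
  Ontario heat-warning threshold. The source bands ("20–30 °C" vs "≥ 31 °C")
  leave 30–31 °C unassigned; the half-open moderate band closes the gap.
* **Per-year quartiles**: Q1/Q3 of that year's daily maxima by
  linear-interpolation quantiles (`numpy.quantile` default; the quantile
  algorithm was unstated, so the most common convention is used and
  documented). Below Q1 cool, [Q1, Q3] moderate (closed on both ends, so a
  day exactly at Q3 is moderate), above Q3 hot. Years with fewer than four
  days are an error.

Stratified 2×2 tables over the stage-B sample are emitted only when every
stratum contains at least one gold-positive chart; otherwise the report
records the suppression and which strata were empty. At realistic prevalence
the suppression branch is the norm — matching the field experience that a
964-chart sample cannot support per-day-class validity estimates.

## The synthetic cohort generator

The generator emulates the study population, not any particular patient:

* **Latent truth**: Bernoulli(p_true_ahi) per encounter, independent of
  everything else. Default 0.00156, chosen so that the three published
  population-scale rates hold simultaneously in expectation:
  positivity = prev·Sn + (1−prev)·fp = 0.000637, PPV = prev·Sn/positivity
  = 0.613, Sn = 0.25. (A gold prevalence of 4 per 964 sampled charts is
  mutually inconsistent with those rates at population scale — it would
  imply more truly-coded AHIs than total algorithm positives — so the
  defaults treat the observed 4/964 as an upper-tail draw of a single
  964-chart sample, which it is consistent with at the ~7 % level.)
* **Coding**: a true AHI receives one concrete algorithm code with
  probability p_algo_code_given_ahi (default 0.25, the latent sensitivity);
  a non-AHI with p_algo_code_given_not_ahi (default 0.000247, the latent
  false-positive rate). Every encounter also receives 1–3 background codes
  from a pool of common ED diagnoses, none matching the AHI prefixes, so no
  code list is ever empty.
* **Documentation**: for true AHIs, exposure and a heat complaint are
  documented with probability 1 by default, so the gold label equals latent
  truth; for non-AHIs, exposure documentation defaults to 0 (keeping
  synthetic specificity at 1, as observed) while generic complaints (pain,
  fatigue) appear on 30 % of charts for realism. All four conditional
  probabilities are configurable; raising the non-AHI exposure rate creates
  gold-standard false positives if one wants to study a leaky gold standard.
* **Temperature**: per-year i.i.d. normal with location = the year's
  published median and scale = IQR/1.349, one draw per May 1–September 30
  day (153 days). Only median and IQR are published, so any two-parameter
  location-scale family is admissible; the normal is the conventional
  choice. True-AHI dates are *not* concentrated on hot days by default (the
  association is real but unquantified in the source; a temperature link
  would add a parameter nothing downstream calibrates against).
* **Demographics** (age, sex, triage level, disposition) are sampled from
  the published marginal frequencies of the random-sample arm; they are
  cosmetic, never used by any estimator, and never statistically verified.
* **Seeding**: one master seed; every component (truth, coding, dates,
  documentation, demographics, temperature, each sampling stage) draws from
  its own `SeedSequence`-derived substream keyed by fixed integer tags, so
  adding a field to one component cannot perturb another's draws. Identical
  seeds give byte-identical CSV and report files.

What passing synthetic tests does **not** show: real charts have correlated
comorbidity structure, free-text documentation quality that varies with ED
crowding, coder practice drift, and temperature-dependent case mix. The
generator demonstrates that the *estimators* are correct and the *design*
behaves as expected at the study's operating point — not that any particular
real-world algorithm has these properties.

## Problem sizes

The calibration test draws 300,000 encounters (enough to resolve a 0.064 %
positivity against its 3-standard-deviation binomial band); the
parameter-recovery experiment runs 200 replicate studies at cohort and
stage-B size 10,000 with prevalence 0.004, giving ~40 gold positives per
replicate and a Monte-Carlo standard error on the mean sensitivity of about
0.5 percentage points. The acceptance script uses 50 replicates for the
same experiment. Replicate studies skip stage A (`n_ppv_sample = 0`): at
cohort size 10,000 the binomial count of algorithm positives occasionally
dips below any fixed stage-A quota, and PPV is not the quantity under test
there.

## Known limitations

* No ICD-9 mapping, no validation against an official ICD tabulation, no
  dagger/asterisk conventions; codes are opaque normalized strings.
* Per-code PPVs are out of scope (the study could not support them either);
  the report lists per-prefix positive counts as descriptive scaffolding
  only, explicitly marked non-estimable.
* The kappa of the original abstraction cannot be reproduced (no agreement
  table was published); simulated duplicate review is parameterised by a
  free per-reviewer flip probability (default 0.01) instead.
* Socioeconomic stratification is absent by design.
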