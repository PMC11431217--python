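# heatvalid

Tools for validating ICD-10 case-finding algorithms for **acute heat illness
(AHI)** — heat stroke, heat exhaustion, heat syncope, dehydration — in
emergency-department (ED) administrative records.

Administrative databases code every ED visit with ICD-10 diagnoses, so a set
of heat-related codes can in principle flag AHI visits for surveillance and
research. Whether it *actually* does is an empirical question: the algorithm
must be checked against a gold standard read off the medical chart
(documented patient-reported heat exposure **and** at least one documented
heat-related complaint). `heatvalid` implements that whole validation study
as a reusable pipeline, for epidemiologists and health-services researchers
who want to run or re-analyse such a study — including entirely on synthetic
cohorts, so no real health records are needed to exercise every step.

## What it computes

Given a 2×2 table cross-classifying the algorithm against the gold standard
(TP, FP, FN, TN), the validity metrics are

    Sn  = TP/(TP+FN)    Sp  = TN/(TN+FP)
    PPV = TP/(TP+FP)    NPV = TN/(TN+FN)

each with two confidence intervals: the Wald interval p̂ ± z·√(p̂(1−p̂)/n)
(the familiar "±" presentation, degenerate at p̂ ∈ {0, 1}) and the
continuity-corrected efficient-score (Wilson) interval, which stays
informative at the boundaries. Because algorithm positives are rare
(~0.06 % of encounters), the study uses a two-stage design: PPV from an
enriched random sample of algorithm-positive charts, and Sn/Sp/NPV from an
independent random sample of the whole cohort. Inter-abstractor agreement on
the doubly-reviewed 20 % of charts is summarised by unweighted Cohen's
kappa, κ = (p_o − p_e)/(1 − p_e). Sample sizes follow the Hajian-Tilaki
closed forms, n = ⌈z²·P(1−P)/d²⌉ for PPV and
n_Sn = ⌈z²·Sn(1−Sn)/(d²·prev)⌉ for sensitivity. Days are classed
cool/moderate/hot by fixed bands (<20 °C / 20–31 °C / ≥31 °C, the Ontario
heat-warning threshold) or by per-year quartiles of daily maximum
temperature.

The synthetic-cohort generator draws encounters with latent AHI truth,
imperfect code assignment (latent sensitivity 25 %), chart documentation,
demographics, and per-year May–September temperature series; estimators see
only codes and chart fields, never the latent bit.

## Worked example

The core reproduction: feed the study's random-sample 2×2 through the
statistics module.

```sh
$ heatvalid stats --table 1,0,3,960
TP = 1  FP = 0  FN = 3  TN = 960  (n = 964)
  Sn = 1/4 = 25.0% ± 42.4% (Wald, 95% CI); Wilson-cc CI [1.3%, 78.1%]
  Sp = 960/960 = 100.0% ± 0.0% (Wald, 95% CI); Wilson-cc CI [99.5%, 100.0%]
 PPV = 1/1 = 100.0% ± 0.0% (Wald, 95% CI); Wilson-cc CI [5.5%, 100.0%]
 NPV = 960/963 = 99.7% ± 0.4% (Wald, 95% CI); Wilson-cc CI [99.0%, 99.9%]
```

Only one of four gold-standard AHI charts carried an algorithm code, so the
algorithm is highly specific (no false positives among 960 negatives) but
insensitive — and at four gold positives the Wald "± 42.4 %" is nearly
vacuous, which is exactly why the Wilson interval is printed alongside.

End-to-end on a synthetic cohort of 300,000 encounters:

```sh
$ heatvalid simulate --out-dir sim --seed 1 --n 300000
$ heatvalid validate --encounters sim/encounters.csv --reviews sim/reviews.csv \
    --weather sim/weather.csv --seed 1 --out report
$ cat report/report.txt
Validation study report — code set 'ahi'

Cohort: 300000 encounters; 176 algorithm-positive (0.06%)

Stage A (enriched, n = 62): 40 gold-positive
  PPV = 64.5% ± 11.9% (Wald, 95% CI)
  PPV 95% CI (Wilson, continuity-corrected): [51.3%, 76.0%]

Stage B (random, n = 964): TP = 0  FP = 0  FN = 3  TN = 961
  Sn = 0.0% ± 0.0% (Wald); Wilson-cc CI [0.0%, 69.0%]
  Sp = 100.0% ± 0.0% (Wald); Wilson-cc CI [99.5%, 100.0%]
  NPV = 99.7% ± 0.4% (Wald); Wilson-cc CI [99.0%, 99.9%]
...
```

A positivity of 0.06 %, a PPV near 61 %, perfect specificity, and a stage-B
sample almost empty of gold positives: the synthetic study behaves like the
field study it emulates, including its central difficulty — at realistic
prevalence, 964 reviewed charts pin down Sp and NPV tightly but leave the
sensitivity estimate extremely noisy. Sample-size planning
(`heatvalid samplesize ppv --estimated-ppv 0.80` → 62;
`heatvalid samplesize snsp --estimated-sn 0.40 --estimated-sp 0.90
--prevalence 0.10` → 922) shows the same asymmetry in advance.

The library API mirrors the CLI: `build_ahi_codeset`, `generate_cohort`,
`label_chart`, `run_validation_study`, `wald_interval`, `wilson_cc_interval`,
`cohen_kappa`, `sample_size_ppv`, `sample_size_sn_sp`, `classify_day_fixed`,
`classify_days_quartile`. See `docs/methods.md` for the model and all design
choices.

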