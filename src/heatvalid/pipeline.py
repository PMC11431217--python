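"""Two-stage validation study: sampling, 2x2 construction, day classes, report.

The study estimates the four validity metrics of a case-finding algorithm
with two independent random samples, mirroring how verification cost is
managed when positives are rare:

* **Stage A** — a simple random sample of *algorithm-positive* encounters is
  chart-reviewed; the gold-positive fraction is the PPV.  (An enriched sample
  is the only affordable way to estimate PPV at a positivity of ~0.06%.)
* **Stage B** — a simple random sample of the *whole* cohort is reviewed and
  cross-classified against the algorithm, giving the 2x2 from which
  sensitivity, specificity and NPV are estimated.  PPV is never taken from
  stage B and the two stages are never pooled.

Inter-rater agreement (Cohen's kappa) comes from duplicate abstraction of a
fraction of the stage-B sample.  Days are classed cool/moderate/hot either by
fixed Ontario heat-warning bands (<20 °C / 20–31 °C / >=31 °C) or by per-year
quartiles of daily maximum temperature; stratified 2x2 tables are emitted
only when every stratum contains a gold-positive chart, otherwise the report
records the suppression.
"""

from __future__ import annotations

import datetime as dt
import json
from collections import OrderedDict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._rng import substream
from .codes import CodeSet, encounter_is_algorithm_positive
from .gold import ChartReview, label_chart, simulate_dual_abstraction
from .simulate import Encounter, WeatherDay
from .stats import (
    KappaResult,
    ProportionEstimate,
    TwoByTwo,
    UndefinedKappaError,
    cohen_kappa,
    format_percent,
    proportion_interval,
)

__all__ = [
    "DayClass",
    "StudyDesign",
    "ValidityReport",
    "DesignInfeasibleError",
    "InsufficientDataError",
    "classify_day_fixed",
    "classify_days_quartile",
    "run_validation_study",
    "positivity_rate",
    "estimates_from_table",
    "write_report",
]

_T_STAGE_A, _T_STAGE_B, _T_KAPPA = 101, 102, 103

CI_METHODS = ("wald", "wilson_cc")


class DayClass(str, Enum):
    COOL = "cool"
    MODERATE = "moderate"
    HOT = "hot"


class DesignInfeasibleError(ValueError):
    """The cohort cannot support the requested sample sizes."""


class InsufficientDataError(ValueError):
    """Too few weather days to compute per-year quartiles."""


@dataclass(frozen=True)
class StudyDesign:
    """Sample sizes and review parameters for one validation study run.

    ``n_ppv_sample = 0`` skips stage A entirely (no PPV estimate).
    ``reviewer_flip_prob`` is the per-reviewer mislabelling probability used
    when duplicate reviews have to be simulated from single-reviewer data.
    """

    n_ppv_sample: int = 62
    n_random_sample: int = 964
    duplicate_fraction: float = 0.20
    conf_level: float = 0.95
    reviewer_flip_prob: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_ppv_sample < 0 or self.n_random_sample < 1:
            raise ValueError("sample sizes must be non-negative (stage B >= 1)")
        if not 0 <= self.duplicate_fraction <= 1:
            raise ValueError(f"duplicate_fraction must be in [0, 1], got {self.duplicate_fraction}")
        if not 0 < self.conf_level < 1:
            raise ValueError(f"conf_level must be in (0, 1), got {self.conf_level}")
        if not 0 <= self.reviewer_flip_prob <= 1:
            raise ValueError(f"reviewer_flip_prob must be in [0, 1], got {self.reviewer_flip_prob}")

    @classmethod
    def from_dict(cls, doc: Mapping) -> "StudyDesign":
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown study design keys: {sorted(unknown)}")
        design = cls(**doc)
        design.validate()
        return design


def classify_day_fixed(tmax_c: float) -> DayClass:
    """Fixed bands: <20 °C cool, [20, 31) moderate, >=31 °C hot.

    31 °C is the Ontario heat-warning threshold.  The half-open moderate band
    closes the 30–31 °C gap so every finite temperature gets exactly one class.
    """
    if not np.isfinite(tmax_c):
        raise ValueError(f"tmax_c must be finite, got {tmax_c}")
    if tmax_c < 20.0:
        return DayClass.COOL
    if tmax_c < 31.0:
        return DayClass.MODERATE
    return DayClass.HOT


def classify_days_quartile(series: Sequence[WeatherDay]) -> dict[dt.date, DayClass]:
    """Per-year quartile classes: tmax < Q1 cool, Q1 <= tmax <= Q3 moderate, > Q3 hot.

    Q1/Q3 are linear-interpolation quantiles of that year's daily maxima.
    Years with fewer than 4 days raise :class:`InsufficientDataError`.
    """
    by_year: dict[int, list[WeatherDay]] = {}
    for w in series:
        by_year.setdefault(w.date.year, []).append(w)
    out: dict[dt.date, DayClass] = {}
    for year, days in by_year.items():
        if len(days) < 4:
            raise InsufficientDataError(f"year {year}: need >= 4 days for quartiles, have {len(days)}")
        temps = np.array([w.tmax_c for w in days])
        q1, q3 = np.quantile(temps, [0.25, 0.75])
        for w in days:
            if w.tmax_c < q1:
                out[w.date] = DayClass.COOL
            elif w.tmax_c > q3:
                out[w.date] = DayClass.HOT
            else:
                out[w.date] = DayClass.MODERATE
    return out


def positivity_rate(encounters: Sequence[Encounter], codeset: CodeSet) -> float:
    """Fraction of the cohort flagged by the algorithm."""
    if not encounters:
        raise ValueError("cohort is empty")
    pos = sum(encounter_is_algorithm_positive(codeset, e.codes) for e in encounters)
    return pos / len(encounters)


def estimates_from_table(
    t: TwoByTwo, conf_level: float = 0.95
) -> dict[str, dict[str, ProportionEstimate] | None]:
    """Interval estimates for Sn/Sp/PPV/NPV under both CI methods.

    A metric whose denominator is zero maps to None rather than raising, so a
    report can carry partial results (e.g. no gold positives in the sample).
    """
    out: dict[str, dict[str, ProportionEstimate] | None] = {}
    for metric in ("sensitivity", "specificity", "ppv", "npv"):
        k, n = t.counts_for(metric)
        if n == 0:
            out[metric] = None
        else:
            out[metric] = {m: proportion_interval(k, n, conf_level, m) for m in CI_METHODS}
    return out


@dataclass
class ValidityReport:
    """Everything one validation run computes, ready for serialization."""

    codeset_name: str
    design: StudyDesign
    n_cohort: int
    n_algorithm_positive: int
    positivity: float
    # stage A (enriched sample of algorithm positives)
    stage_a_n: int
    stage_a_gold_positive: int
    ppv: dict | None  # method -> ProportionEstimate, or None when stage A skipped
    # stage B (random sample of the whole cohort)
    table: TwoByTwo
    estimates: dict  # metric -> (method -> ProportionEstimate) | None
    kappa: KappaResult | None
    kappa_note: str
    strata: "OrderedDict[str, TwoByTwo] | None"
    strata_note: str
    #: cohort-level encounter counts per include prefix — descriptive only;
    #: per-code validity metrics are not estimable from this design
    per_code_positive_counts: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)


def _first_reviews(reviews: Iterable[ChartReview]) -> tuple[dict, dict]:
    """Split reviews into authoritative (first per encounter) and duplicates."""
    first: dict[str, ChartReview] = {}
    dups: dict[str, list[ChartReview]] = {}
    for r in reviews:
        if r.encounter_id not in first:
            first[r.encounter_id] = r
        else:
            dups.setdefault(r.encounter_id, []).append(r)
    return first, dups


def run_validation_study(
    encounters: Sequence[Encounter],
    reviews: Iterable[ChartReview],
    design: StudyDesign,
    codeset: CodeSet,
    *,
    weather: Sequence[WeatherDay] | None = None,
    day_class_scheme: str = "fixed_threshold",
    vocabulary: frozenset | None = None,
) -> ValidityReport:
    """Run the full two-stage validation study and return its report.

    ``reviews`` supplies the gold standard: the first review per encounter is
    authoritative; any second review feeds the kappa.  When no encounter has
    a duplicate review, duplicate abstraction of the stage-B sample is
    simulated with ``design.reviewer_flip_prob``.  Fully deterministic under
    ``design.seed``.
    """
    design.validate()
    if not encounters:
        raise ValueError("cohort is empty")
    first, dups = _first_reviews(reviews)

    def gold(e: Encounter) -> bool:
        try:
            review = first[e.id]
        except KeyError:
            raise ValueError(f"no chart review available for sampled encounter {e.id}") from None
        return label_chart(review, vocabulary)

    algo = np.array([encounter_is_algorithm_positive(codeset, e.codes) for e in encounters])
    n_pos = int(algo.sum())
    n_cohort = len(encounters)
    notes: list[str] = []

    # stage A: enriched sample of algorithm positives -> PPV
    if design.n_ppv_sample > 0:
        if n_pos < design.n_ppv_sample:
            raise DesignInfeasibleError(
                f"stage A needs {design.n_ppv_sample} algorithm-positive encounters, "
                f"cohort has {n_pos}"
            )
        rng_a = substream(design.seed, _T_STAGE_A)
        pos_idx = np.flatnonzero(algo)
        a_idx = rng_a.choice(pos_idx, size=design.n_ppv_sample, replace=False)
        a_gold = sum(gold(encounters[i]) for i in a_idx)
        ppv = {
            m: proportion_interval(int(a_gold), design.n_ppv_sample, design.conf_level, m)
            for m in CI_METHODS
        }
        stage_a_n, stage_a_gold = design.n_ppv_sample, int(a_gold)
    else:
        ppv, stage_a_n, stage_a_gold = None, 0, 0
        notes.append("stage A skipped (n_ppv_sample = 0); no PPV estimate")

    # stage B: random sample of the whole cohort -> 2x2 -> Sn/Sp/NPV
    if design.n_random_sample > n_cohort:
        raise DesignInfeasibleError(
            f"stage B needs {design.n_random_sample} encounters, cohort has {n_cohort}"
        )
    rng_b = substream(design.seed, _T_STAGE_B)
    b_idx = rng_b.choice(n_cohort, size=design.n_random_sample, replace=False)
    b_enc = [encounters[i] for i in b_idx]
    b_gold = np.array([gold(e) for e in b_enc])
    b_algo = algo[b_idx]
    table = TwoByTwo(
        tp=int((b_algo & b_gold).sum()),
        fp=int((b_algo & ~b_gold).sum()),
        fn=int((~b_algo & b_gold).sum()),
        tn=int((~b_algo & ~b_gold).sum()),
    )
    estimates = estimates_from_table(table, design.conf_level)
    estimates.pop("ppv", None)  # PPV comes only from the enriched stage-A sample
    for metric, est in estimates.items():
        if est is None:
            notes.append(f"{metric} undefined on the stage-B sample (zero denominator)")

    # kappa from duplicate abstraction of the stage-B sample
    kappa: KappaResult | None = None
    b_dups = [e for e in b_enc if e.id in dups]
    if b_dups:
        pairs = []
        for e in b_dups:
            pairs.append((gold(e), label_chart(dups[e.id][0], vocabulary)))
        kappa_note = f"kappa from {len(pairs)} recorded duplicate reviews in the stage-B sample"
    else:
        dual = simulate_dual_abstraction(
            b_gold, design.reviewer_flip_prob, design.duplicate_fraction, design.seed
        )
        pairs = dual.pairs()
        kappa_note = (
            f"kappa from simulated duplicate abstraction of {len(pairs)} charts "
            f"(flip probability {design.reviewer_flip_prob})"
        )
    if pairs:
        try:
            kappa = cohen_kappa(pairs)
        except UndefinedKappaError:
            kappa_note += "; kappa undefined (both reviewers constant on the duplicated subset)"
    else:
        kappa_note = "no duplicate reviews; kappa not computed"

    # day-class strata over the stage-B sample
    strata: OrderedDict[str, TwoByTwo] | None = None
    if weather is not None:
        day_map = (
            {w.date: classify_day_fixed(w.tmax_c) for w in weather}
            if day_class_scheme == "fixed_threshold"
            else classify_days_quartile(weather)
        )
        counts: dict[DayClass, list[int]] = {c: [0, 0, 0, 0] for c in DayClass}
        for e, is_algo, is_gold in zip(b_enc, b_algo, b_gold):
            if e.date not in day_map:
                raise ValueError(f"no weather record for encounter date {e.date}")
            cell = counts[day_map[e.date]]
            cell[0 if (is_algo and is_gold) else 1 if is_algo else 2 if is_gold else 3] += 1
        gold_per_class = {c: counts[c][0] + counts[c][2] for c in DayClass}
        if all(v >= 1 for v in gold_per_class.values()):
            strata = OrderedDict(
                (c.value, TwoByTwo(tp=v[0], fp=v[1], fn=v[2], tn=v[3]))
                for c, v in counts.items()
            )
            strata_note = f"stratified by {day_class_scheme} day class"
        else:
            empty = sorted(c.value for c, v in gold_per_class.items() if v == 0)
            strata_note = (
                "stratified metrics suppressed: no gold-positive charts on "
                f"{', '.join(empty)} days in the stage-B sample"
            )
    else:
        strata_note = "no weather series supplied; day-class strata not computed"

    # only algorithm-positive encounters can contribute to any prefix count
    per_code = {prefix: 0 for prefix in sorted(codeset.includes)}
    for i in np.flatnonzero(algo):
        codes = encounters[i].codes
        for prefix in per_code:
            if any(c.startswith(prefix) for c in codes):
                per_code[prefix] += 1

    return ValidityReport(
        codeset_name=codeset.name,
        design=design,
        n_cohort=n_cohort,
        n_algorithm_positive=n_pos,
        positivity=n_pos / n_cohort,
        stage_a_n=stage_a_n,
        stage_a_gold_positive=stage_a_gold,
        ppv=ppv,
        table=table,
        estimates=estimates,
        kappa=kappa,
        kappa_note=kappa_note,
        strata=strata,
        strata_note=strata_note,
        per_code_positive_counts=per_code,
        notes=notes,
    )


def _estimate_row(metric: str, est: ProportionEstimate) -> dict:
    return {
        "metric": metric,
        "method": est.method,
        "k": round(est.p_hat * est.n),
        "n": est.n,
        "estimate": f"{est.p_hat:.6f}",
        "lower": f"{est.lower:.6f}",
        "upper": f"{est.upper:.6f}",
        "half_width": "" if est.half_width is None else f"{est.half_width:.6f}",
    }


def _report_rows(report: ValidityReport) -> list[dict]:
    rows = []
    if report.ppv is not None:
        for m in CI_METHODS:
            rows.append(_estimate_row("ppv", report.ppv[m]))
    for metric in ("sensitivity", "specificity", "npv"):
        est = report.estimates.get(metric)
        if est is not None:
            for m in CI_METHODS:
                rows.append(_estimate_row(metric, est[m]))
    return rows


def _report_text(report: ValidityReport) -> str:
    t = report.table
    lines = [
        f"Validation study report — code set '{report.codeset_name}'",
        "",
        f"Cohort: {report.n_cohort} encounters; {report.n_algorithm_positive} algorithm-positive "
        f"({format_percent(report.positivity, 2)})",
        "",
    ]
    if report.ppv is not None:
        w = report.ppv["wald"]
        wc = report.ppv["wilson_cc"]
        lines += [
            f"Stage A (enriched, n = {report.stage_a_n}): {report.stage_a_gold_positive} gold-positive",
            f"  PPV = {format_percent(w.p_hat)} ± {format_percent(w.half_width)} (Wald, "
            f"{w.conf_level:.0%} CI)",
            f"  PPV {wc.conf_level:.0%} CI (Wilson, continuity-corrected): "
            f"[{format_percent(wc.lower)}, {format_percent(wc.upper)}]",
            "",
        ]
    lines += [
        f"Stage B (random, n = {t.total}): TP = {t.tp}  FP = {t.fp}  FN = {t.fn}  TN = {t.tn}",
    ]
    for metric, label in (("sensitivity", "Sn"), ("specificity", "Sp"), ("npv", "NPV")):
        est = report.estimates.get(metric)
        if est is None:
            lines.append(f"  {label}: undefined (zero denominator)")
            continue
        w, wc = est["wald"], est["wilson_cc"]
        lines.append(
            f"  {label} = {format_percent(w.p_hat)} ± {format_percent(w.half_width)} (Wald); "
            f"Wilson-cc CI [{format_percent(wc.lower)}, {format_percent(wc.upper)}]"
        )
    lines.append("")
    if report.kappa is not None:
        k = report.kappa
        lines.append(
            f"Inter-rater agreement: kappa = {k.kappa:.3f} "
            f"(p_o = {k.p_o:.3f}, p_e = {k.p_e:.3f}, {k.n_pairs} pairs)"
        )
    lines.append(f"  [{report.kappa_note}]")
    lines.append("")
    if report.strata is not None:
        lines.append(f"Day-class strata ({report.strata_note}):")
        for name, st in report.strata.items():
            lines.append(
                f"  {name}: TP = {st.tp}  FP = {st.fp}  FN = {st.fn}  TN = {st.tn}"
            )
    else:
        lines.append(f"Day-class strata: {report.strata_note}")
    hit = {k: v for k, v in report.per_code_positive_counts.items() if v}
    if hit:
        lines.append("")
        lines.append("Per-code positive counts (descriptive only; per-code validity not estimable):")
        for prefix, count in hit.items():
            lines.append(f"  {prefix}: {count}")
    for note in report.notes:
        lines.append(f"Note: {note}")
    lines.append("")
    return "\n".join(lines)


def write_report(report: ValidityReport, outdir: str | Path) -> None:
    """Write report.txt, report.csv, two_by_two.csv, strata.csv and log.json."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    (outdir / "report.txt").write_text(_report_text(report))
    pd.DataFrame(_report_rows(report)).to_csv(outdir / "report.csv", index=False)

    t = report.table
    pd.DataFrame([{"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn}]).to_csv(
        outdir / "two_by_two.csv", index=False
    )

    strata_rows = (
        [
            {"day_class": name, "tp": st.tp, "fp": st.fp, "fn": st.fn, "tn": st.tn}
            for name, st in report.strata.items()
        ]
        if report.strata is not None
        else []
    )
    pd.DataFrame(strata_rows, columns=["day_class", "tp", "fp", "fn", "tn"]).to_csv(
        outdir / "strata.csv", index=False
    )

    from . import __version__

    log = {
        "package_version": __version__,
        "codeset": report.codeset_name,
        "seed": report.design.seed,
        "n_cohort": report.n_cohort,
        "n_algorithm_positive": report.n_algorithm_positive,
        "positivity": report.positivity,
        "stage_a_n": report.stage_a_n,
        "stage_b_n": report.table.total,
        "kappa_note": report.kappa_note,
        "strata_note": report.strata_note,
        "notes": report.notes,
    }
    (outdir / "log.json").write_text(json.dumps(log, indent=2) + "\n")
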