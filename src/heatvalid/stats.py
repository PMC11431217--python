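"""Diagnostic-accuracy statistics for 2x2 validation tables.

Implements the estimators a code-validation study reports:

* sensitivity / specificity / PPV / NPV from a 2x2 table of algorithm result
  against gold-standard chart review;
* two proportion confidence intervals — the Wald (normal-approximation)
  interval p ± z·sqrt(p(1-p)/n), and the continuity-corrected efficient-score
  (Wilson) interval of Newcombe;
* unweighted two-rater Cohen's kappa for inter-abstractor agreement;
* closed-form sample sizes for diagnostic studies (Hajian-Tilaki): the PPV
  branch n = z²·P(1-P)/d² and the sensitivity/specificity branch, which
  inflates by prevalence, n_sn = z²·Sn(1-Sn)/(d²·prev).

The Wald interval is degenerate (half-width 0) at p = 0 or 1, which is why a
perfectly specific algorithm prints "100.0 ± 0.0%"; the Wilson interval stays
informative at the boundaries and is the better default for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import norm

__all__ = [
    "TwoByTwo",
    "ProportionEstimate",
    "KappaResult",
    "SampleSizePlan",
    "UndefinedMetricError",
    "UndefinedKappaError",
    "metrics_from_table",
    "wald_interval",
    "wilson_cc_interval",
    "proportion_interval",
    "cohen_kappa",
    "sample_size_ppv",
    "sample_size_sn_sp",
    "format_percent",
    "estimate_table_text",
]

METRICS = ("sensitivity", "specificity", "ppv", "npv")


class UndefinedMetricError(ValueError):
    """A requested metric has a zero denominator in the 2x2 table."""


class UndefinedKappaError(ValueError):
    """Expected agreement is 1 (both raters constant), so kappa is undefined."""


@dataclass(frozen=True)
class TwoByTwo:
    """Counts cross-classifying algorithm result (rows) vs gold standard (columns)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total < 1:
            raise ValueError("2x2 table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    # numerator/denominator pairs for each metric
    def counts_for(self, metric: str) -> tuple[int, int]:
        if metric == "sensitivity":
            return self.tp, self.tp + self.fn
        if metric == "specificity":
            return self.tn, self.tn + self.fp
        if metric == "ppv":
            return self.tp, self.tp + self.fp
        if metric == "npv":
            return self.tn, self.tn + self.fn
        raise ValueError(f"unknown metric {metric!r}")


def metrics_from_table(t: TwoByTwo, metrics: Sequence[str] = METRICS) -> dict[str, float]:
    """Point estimates Sn = tp/(tp+fn), Sp = tn/(tn+fp), PPV = tp/(tp+fp), NPV = tn/(tn+fn).

    Raises :class:`UndefinedMetricError` naming the metric whose denominator
    is zero; never silently returns 0 for an undefined ratio.
    """
    out: dict[str, float] = {}
    for m in metrics:
        k, n = t.counts_for(m)
        if n == 0:
            raise UndefinedMetricError(f"{m} is undefined: zero denominator in table {t}")
        out[m] = k / n
    return out


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with its confidence interval.

    ``half_width`` is populated for the Wald method only (the quantity the
    "p ± h" presentation reports); the Wilson interval is asymmetric, so its
    half-width is not a meaningful summary and is left as None.
    """

    p_hat: float
    n: int
    conf_level: float
    method: str  # "wald" | "wilson_cc"
    lower: float
    upper: float
    half_width: float | None = None


def _zvalue(conf_level: float) -> float:
    if not 0 < conf_level < 1:
        raise ValueError(f"conf_level must be in (0, 1), got {conf_level}")
    return float(norm.ppf((1 + conf_level) / 2))


def _check_kn(k: int, n: int) -> None:
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must satisfy 0 <= k <= n, got k={k}, n={n}")


def wald_interval(k: int, n: int, conf_level: float = 0.95) -> ProportionEstimate:
    """Normal-approximation interval p ± z·sqrt(p(1-p)/n), bounds clipped to [0, 1].

    Degenerate at k = 0 or k = n (half-width exactly 0).
    """
    _check_kn(k, n)
    z = _zvalue(conf_level)
    p = k / n
    h = z * math.sqrt(p * (1 - p) / n)
    return ProportionEstimate(
        p_hat=p,
        n=n,
        conf_level=conf_level,
        method="wald",
        lower=max(0.0, p - h),
        upper=min(1.0, p + h),
        half_width=h,
    )


def wilson_cc_interval(k: int, n: int, conf_level: float = 0.95) -> ProportionEstimate:
    """Continuity-corrected efficient-score (Wilson) interval, Newcombe's closed form.

    The bounds solve (|p̂ - p| - 1/(2n))² = z²·p(1-p)/n on either side of p̂;
    by convention lower = 0 when k = 0 and upper = 1 when k = n.
    """
    _check_kn(k, n)
    z = _zvalue(conf_level)
    p = k / n
    z2 = z * z
    denom = 2 * (n + z2)
    if k == 0:
        lower = 0.0
    else:
        lower = (2 * n * p + z2 - 1 - z * math.sqrt(z2 - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))) / denom
    if k == n:
        upper = 1.0
    else:
        upper = (2 * n * p + z2 + 1 + z * math.sqrt(z2 + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))) / denom
    return ProportionEstimate(
        p_hat=p,
        n=n,
        conf_level=conf_level,
        method="wilson_cc",
        lower=max(0.0, lower),
        upper=min(1.0, upper),
        half_width=None,
    )


def proportion_interval(k: int, n: int, conf_level: float = 0.95, method: str = "wilson_cc") -> ProportionEstimate:
    """Dispatch on ``method`` ("wald" or "wilson_cc")."""
    if method == "wald":
        return wald_interval(k, n, conf_level)
    if method == "wilson_cc":
        return wilson_cc_interval(k, n, conf_level)
    raise ValueError(f"unknown interval method {method!r}")


@dataclass(frozen=True)
class KappaResult:
    """Unweighted two-rater, two-category Cohen's kappa."""

    n_pairs: int
    p_o: float  # observed agreement
    p_e: float  # chance-expected agreement from the marginals
    kappa: float


def cohen_kappa(pairs: Iterable[tuple[bool, bool]]) -> KappaResult:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e) from paired labels.

    ``pairs`` holds one (rater_a, rater_b) boolean pair per doubly-reviewed
    chart.  Raises :class:`UndefinedKappaError` when both raters are constant
    with identical marginals (p_e = 1).
    """
    a = b = c = d = 0  # a=TT, b=TF, c=FT, d=FF
    for la, lb in pairs:
        if la and lb:
            a += 1
        elif la and not lb:
            b += 1
        elif lb:
            c += 1
        else:
            d += 1
    n = a + b + c + d
    if n < 1:
        raise ValueError("cohen_kappa requires at least one pair")
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if p_e >= 1.0:
        raise UndefinedKappaError(
            f"kappa undefined: both raters constant (expected agreement 1) on {n} pairs"
        )
    return KappaResult(n_pairs=n, p_o=p_o, p_e=p_e, kappa=(p_o - p_e) / (1 - p_e))


@dataclass(frozen=True)
class SampleSizePlan:
    """A closed-form diagnostic sample-size calculation (ceilinged)."""

    target: str  # "ppv" | "sensitivity_specificity"
    conf_level: float
    precision_d: float
    n_required: int
    estimated_ppv: float | None = None
    estimated_sn: float | None = None
    estimated_sp: float | None = None
    expected_prevalence: float | None = None
    n_sn: int | None = None
    n_sp: int | None = None


def _check_open_unit(name: str, value: float) -> None:
    if not 0 < value < 1:
        raise ValueError(f"{name} must be in (0, 1), got {value}")


def sample_size_ppv(estimated_ppv: float, precision_d: float, conf_level: float = 0.95) -> SampleSizePlan:
    """n = ceil(z²·P(1-P)/d²) positive charts to estimate a PPV of P to within d."""
    _check_open_unit("estimated_ppv", estimated_ppv)
    if precision_d <= 0:
        raise ValueError(f"precision_d must be > 0, got {precision_d}")
    z = _zvalue(conf_level)
    n = math.ceil(z * z * estimated_ppv * (1 - estimated_ppv) / (precision_d * precision_d))
    return SampleSizePlan(
        target="ppv",
        conf_level=conf_level,
        precision_d=precision_d,
        n_required=n,
        estimated_ppv=estimated_ppv,
    )


def sample_size_sn_sp(
    estimated_sn: float,
    estimated_sp: float,
    expected_prevalence: float,
    precision_d: float,
    conf_level: float = 0.95,
) -> SampleSizePlan:
    """Random-sample size to estimate sensitivity and specificity to within d.

    n_sn = ceil(z²·Sn(1-Sn)/(d²·prev)) and n_sp = ceil(z²·Sp(1-Sp)/(d²·(1-prev)));
    the requirement is the larger of the two, with both components reported.
    """
    _check_open_unit("estimated_sn", estimated_sn)
    _check_open_unit("estimated_sp", estimated_sp)
    _check_open_unit("expected_prevalence", expected_prevalence)
    if precision_d <= 0:
        raise ValueError(f"precision_d must be > 0, got {precision_d}")
    z2 = _zvalue(conf_level) ** 2
    d2 = precision_d * precision_d
    n_sn = math.ceil(z2 * estimated_sn * (1 - estimated_sn) / (d2 * expected_prevalence))
    n_sp = math.ceil(z2 * estimated_sp * (1 - estimated_sp) / (d2 * (1 - expected_prevalence)))
    return SampleSizePlan(
        target="sensitivity_specificity",
        conf_level=conf_level,
        precision_d=precision_d,
        n_required=max(n_sn, n_sp),
        estimated_sn=estimated_sn,
        estimated_sp=estimated_sp,
        expected_prevalence=expected_prevalence,
        n_sn=n_sn,
        n_sp=n_sp,
    )


def format_percent(p: float, decimals: int = 1) -> str:
    """Render a proportion as a percentage string, round-half-even."""
    return f"{100 * p:.{decimals}f}%"


def estimate_table_text(t: TwoByTwo, conf_level: float = 0.95) -> str:
    """Human-readable Sn/Sp/PPV/NPV summary with both interval methods.

    Metrics with a zero denominator are reported as undefined rather than 0.
    """
    lines = [f"TP = {t.tp}  FP = {t.fp}  FN = {t.fn}  TN = {t.tn}  (n = {t.total})"]
    labels = {"sensitivity": "Sn", "specificity": "Sp", "ppv": "PPV", "npv": "NPV"}
    for metric, label in labels.items():
        k, n = t.counts_for(metric)
        if n == 0:
            lines.append(f"{label:>4}: undefined (zero denominator)")
            continue
        w = wald_interval(k, n, conf_level)
        wc = wilson_cc_interval(k, n, conf_level)
        lines.append(
            f"{label:>4} = {k}/{n} = {format_percent(w.p_hat)} "
            f"± {format_percent(w.half_width)} (Wald, {conf_level:.0%} CI); "
            f"Wilson-cc CI [{format_percent(wc.lower)}, {format_percent(wc.upper)}]"
        )
    return "\n".join(lines)
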