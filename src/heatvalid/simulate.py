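"""Synthetic ED-cohort generator with latent acute-heat-illness truth.

Emulates the population a warm-season coding-validation study draws on: one
row per emergency-department encounter between May 1 and September 30 of the
study years, each carrying at least one ICD-10 code, demographics, a visit
date, chart-documentation flags, and a *latent* truth bit saying whether the
visit really was an acute heat illness (AHI).  Estimators never read the
latent bit — they see only codes and chart documentation, exactly like the
real study.

Default calibration targets the published population-scale rates: an
algorithm-positivity of 0.064% of encounters, a positive predictive value of
~61% among flagged charts, and a latent coding sensitivity of 25%
(p_true_ahi = 0.00156, p_algo_code_given_not_ahi = 0.000247 jointly reproduce
all three in expectation).  Daily maximum temperatures are drawn per year
from a normal location–scale family with location = the year's published
median and scale = IQR/1.349, the two-parameter family matching a printed
median/IQR summary.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .gold import ChartReview

__all__ = [
    "TABLE_TEMPERATURES",
    "DEFAULT_BACKGROUND_POOL",
    "GeneratorConfig",
    "Encounter",
    "WeatherDay",
    "ConfigError",
    "generate_temperature_series",
    "generate_cohort",
    "reviews_from_encounters",
    "write_encounters_csv",
    "read_encounters_csv",
    "write_weather_csv",
    "read_weather_csv",
]

#: Published per-year (median, IQR) of May–September daily maximum temperature, °C.
TABLE_TEMPERATURES: dict[int, tuple[float, float]] = {
    2014: (24.2, 6.1),
    2015: (24.5, 4.5),
    2016: (26.1, 5.7),
    2017: (24.3, 6.6),
    2018: (25.7, 6.0),
}

#: Filler diagnoses for the code lists — common ED presentations, none of
#: which is captured by the AHI algorithm's include prefixes.
DEFAULT_BACKGROUND_POOL = (
    "J069",  # acute upper respiratory infection
    "A099",  # gastroenteritis
    "K529",  # colitis, unspecified
    "M545",  # low back pain
    "R104",  # abdominal pain
    "S934",  # ankle sprain
    "I10",   # essential hypertension
    "J459",  # asthma, unspecified
    "F329",  # depressive episode
    "R074",  # chest pain
    "Z038",  # observation for suspected condition
    "L039",  # cellulitis
)

# Concrete codes handed to encounters the coder marks as heat-related; all
# match the AHI include prefixes (N179 via the N17 category entry).
_AHI_ASSIGNABLE = (
    "X30", "X32", "T670", "T671", "T672", "T675", "T676", "T677", "T679",
    "E860", "E868", "N179", "R508", "R509", "M628", "E875", "R55",
)

_HEAT_COMPLAINTS = (
    "heat stroke", "syncope", "exhaustion", "muscle cramps", "loss of consciousness", "edema",
)
_GENERIC_COMPLAINTS = ("pain", "fatigue")

# substream tags
_T_TEMP, _T_TRUTH, _T_CODE, _T_DATE, _T_DOC, _T_DEMOG = 11, 12, 13, 14, 15, 16


class ConfigError(ValueError):
    """Generator configuration is inconsistent or incomplete."""


@dataclass(frozen=True)
class WeatherDay:
    date: dt.date
    tmax_c: float


@dataclass(frozen=True)
class Encounter:
    """One ED visit: identifiers, codes, demographics, chart documentation, latent truth."""

    id: str
    date: dt.date
    codes: tuple
    age: int
    sex: str  # "female" | "male"
    ctas: int  # 1 (resuscitation) .. 5 (non-urgent)
    disposition: str  # "discharged" | "admitted" | "left-AMA"
    exposure_documented: bool
    complaints: tuple
    latent_true_ahi: bool


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for the synthetic cohort.

    Probabilities are per-encounter Bernoulli rates; ``p_algo_code_given_ahi``
    is the latent sensitivity of the coding process and
    ``p_algo_code_given_not_ahi`` its latent false-positive rate.  Defaults
    reproduce, in expectation, positivity 0.000637, PPV 0.613 and latent
    sensitivity 0.25.
    """

    n_encounters: int = 10_000
    years: tuple = (2014, 2015, 2016, 2017, 2018)
    p_true_ahi: float = 0.00156
    p_algo_code_given_ahi: float = 0.25
    p_algo_code_given_not_ahi: float = 0.000247
    p_exposure_documented_given_ahi: float = 1.0
    p_complaint_documented_given_ahi: float = 1.0
    p_exposure_documented_given_not_ahi: float = 0.0
    p_complaint_documented_given_not_ahi: float = 0.30
    background_code_pool: tuple = DEFAULT_BACKGROUND_POOL
    temp_params: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE_TEMPERATURES)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_encounters < 1:
            raise ConfigError(f"n_encounters must be >= 1, got {self.n_encounters}")
        if not self.years:
            raise ConfigError("years must be non-empty")
        if not self.background_code_pool:
            raise ConfigError("background_code_pool must be non-empty")
        for name in (
            "p_true_ahi",
            "p_algo_code_given_ahi",
            "p_algo_code_given_not_ahi",
            "p_exposure_documented_given_ahi",
            "p_complaint_documented_given_ahi",
            "p_exposure_documented_given_not_ahi",
            "p_complaint_documented_given_not_ahi",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        missing = [y for y in self.years if y not in self.temp_params]
        if missing:
            raise ConfigError(f"temp_params missing years {missing}")

    @classmethod
    def from_dict(cls, doc: Mapping) -> "GeneratorConfig":
        kwargs = dict(doc)
        if "years" in kwargs:
            kwargs["years"] = tuple(int(y) for y in kwargs["years"])
        if "background_code_pool" in kwargs:
            kwargs["background_code_pool"] = tuple(kwargs["background_code_pool"])
        if "temp_params" in kwargs:
            kwargs["temp_params"] = {
                int(y): (float(m), float(iqr)) for y, (m, iqr) in kwargs["temp_params"].items()
            }
        unknown = set(kwargs) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown generator config keys: {sorted(unknown)}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def _season_dates(year: int) -> list[dt.date]:
    """All calendar days May 1 – September 30 of ``year`` (153 days)."""
    start = dt.date(year, 5, 1)
    end = dt.date(year, 9, 30)
    return [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]


def generate_temperature_series(
    year: int, median_c: float, iqr_c: float, seed: int
) -> list[WeatherDay]:
    """One daily-maximum temperature per May–September day of ``year``.

    Draws i.i.d. normal with location ``median_c`` and scale ``iqr_c``/1.349
    (the normal IQR-to-sigma factor), so the sample median and IQR concentrate
    on the published targets.  Deterministic under (seed, year).
    """
    if iqr_c <= 0:
        raise ConfigError(f"iqr_c must be > 0, got {iqr_c}")
    days = _season_dates(year)
    rng = substream(seed, _T_TEMP, year)
    temps = rng.normal(loc=median_c, scale=iqr_c / 1.349, size=len(days))
    return [WeatherDay(date=d, tmax_c=float(t)) for d, t in zip(days, temps)]


def _sample_complaints(rng: np.random.Generator, pool: Sequence[str], k_max: int) -> tuple:
    k = int(rng.integers(1, k_max + 1))
    idx = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
    return tuple(pool[i] for i in sorted(idx))


def generate_cohort(config: GeneratorConfig) -> tuple[list[Encounter], list[WeatherDay]]:
    """Draw a full synthetic cohort plus its weather series, reproducibly.

    Latent truth ~ Bernoulli(p_true_ahi); the coder assigns an algorithm code
    with p_algo_code_given_ahi (true AHI) or p_algo_code_given_not_ahi
    (everything else); every encounter receives 1–3 background codes so no
    code list is empty; chart documentation follows the configured
    conditional rates.  All randomness derives from ``config.seed``.
    """
    config.validate()
    n = config.n_encounters
    years = tuple(config.years)

    weather: list[WeatherDay] = []
    for y in sorted(set(years)):
        med, iqr = config.temp_params[y]
        weather.extend(generate_temperature_series(y, med, iqr, config.seed))

    truth = substream(config.seed, _T_TRUTH).random(n) < config.p_true_ahi

    rng_code = substream(config.seed, _T_CODE)
    u = rng_code.random(n)
    coded = np.where(truth, u < config.p_algo_code_given_ahi, u < config.p_algo_code_given_not_ahi)
    ahi_pick = rng_code.integers(len(_AHI_ASSIGNABLE), size=n)
    n_bg = rng_code.integers(1, 4, size=n)
    bg_flat = rng_code.integers(len(config.background_code_pool), size=int(n_bg.sum()))
    bg_split = np.cumsum(n_bg)[:-1]
    bg_lists = np.split(bg_flat, bg_split)

    rng_date = substream(config.seed, _T_DATE)
    year_idx = rng_date.integers(len(years), size=n)
    day_off = rng_date.integers(153, size=n)
    season = {y: _season_dates(y) for y in set(years)}

    rng_doc = substream(config.seed, _T_DOC)
    u_exp = rng_doc.random(n)
    exposure = np.where(
        truth,
        u_exp < config.p_exposure_documented_given_ahi,
        u_exp < config.p_exposure_documented_given_not_ahi,
    )
    u_cmp = rng_doc.random(n)
    has_complaint = np.where(
        truth,
        u_cmp < config.p_complaint_documented_given_ahi,
        u_cmp < config.p_complaint_documented_given_not_ahi,
    )

    rng_demog = substream(config.seed, _T_DEMOG)
    age = np.clip(np.rint(rng_demog.normal(41.7, 26.5, size=n)), 0, 102).astype(int)
    sex = np.where(rng_demog.random(n) < 0.511, "female", "male")
    ctas_p = np.array([0.039, 0.250, 0.461, 0.232, 0.011])
    ctas = rng_demog.choice(np.arange(1, 6), size=n, p=ctas_p / ctas_p.sum())
    dispo_p = np.array([0.758, 0.173, 0.066])
    dispo = rng_demog.choice(
        np.array(["discharged", "admitted", "left-AMA"]), size=n, p=dispo_p / dispo_p.sum()
    )

    pool = config.background_code_pool
    width = len(str(max(n - 1, 1)))
    encounters: list[Encounter] = []
    for i in range(n):
        codes = [pool[j] for j in bg_lists[i]]
        if coded[i]:
            codes.append(_AHI_ASSIGNABLE[ahi_pick[i]])
        if has_complaint[i]:
            cmp_pool = _HEAT_COMPLAINTS if truth[i] else _GENERIC_COMPLAINTS
            complaints = _sample_complaints(rng_doc, cmp_pool, 2)
        else:
            complaints = ()
        encounters.append(
            Encounter(
                id=f"E{i:0{width}d}",
                date=season[years[year_idx[i]]][day_off[i]],
                codes=tuple(codes),
                age=int(age[i]),
                sex=str(sex[i]),
                ctas=int(ctas[i]),
                disposition=str(dispo[i]),
                exposure_documented=bool(exposure[i]),
                complaints=complaints,
                latent_true_ahi=bool(truth[i]),
            )
        )
    return encounters, weather


def reviews_from_encounters(
    encounters: Iterable[Encounter], reviewer_id: str = "r1"
) -> list[ChartReview]:
    """Primary-reviewer chart abstractions read off the documented chart fields."""
    return [
        ChartReview(
            encounter_id=e.id,
            reviewer_id=reviewer_id,
            exposure_documented=e.exposure_documented,
            complaints=e.complaints,
        )
        for e in encounters
    ]


def write_encounters_csv(encounters: Iterable[Encounter], path: str | Path) -> None:
    encounters = list(encounters)
    df = pd.DataFrame(
        {
            "id": [e.id for e in encounters],
            "date": [e.date.isoformat() for e in encounters],
            "codes": [";".join(e.codes) for e in encounters],
            "age": [e.age for e in encounters],
            "sex": [e.sex for e in encounters],
            "ctas": [e.ctas for e in encounters],
            "disposition": [e.disposition for e in encounters],
            "exposure_documented": [str(e.exposure_documented).lower() for e in encounters],
            "complaints": [";".join(e.complaints) for e in encounters],
            "latent_true_ahi": [str(e.latent_true_ahi).lower() for e in encounters],
        }
    )
    df.to_csv(path, index=False)


def read_encounters_csv(path: str | Path) -> list[Encounter]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Encounter(
                id=str(row.id),
                date=dt.date.fromisoformat(str(row.date)),
                codes=tuple(c for c in str(row.codes).split(";") if c),
                age=int(row.age),
                sex=str(row.sex),
                ctas=int(row.ctas),
                disposition=str(row.disposition),
                exposure_documented=str(row.exposure_documented).lower() in ("true", "1", "yes"),
                complaints=tuple(c for c in str(row.complaints).split(";") if c),
                latent_true_ahi=str(getattr(row, "latent_true_ahi", "false")).lower()
                in ("true", "1", "yes"),
            )
        )
    return out


def write_weather_csv(weather: Iterable[WeatherDay], path: str | Path) -> None:
    weather = list(weather)
    df = pd.DataFrame(
        {
            "date": [w.date.isoformat() for w in weather],
            "tmax_c": [f"{w.tmax_c:.3f}" for w in weather],
        }
    )
    df.to_csv(path, index=False)


def read_weather_csv(path: str | Path) -> list[WeatherDay]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        WeatherDay(date=dt.date.fromisoformat(str(r.date)), tmax_c=float(r.tmax_c))
        for r in df.itertuples(index=False)
    ]
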