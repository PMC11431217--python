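"""Gold-standard chart labeling and duplicate-abstraction simulation.

The reference ("gold-standard") definition of an acute-heat-illness visit is
a conjunction read off the medical chart: the care provider documented
patient-reported exposure to heat AND documented at least one heat-related
complaint.  Either conjunct missing makes the chart gold-negative, however
suggestive the rest of the record is — the definition is deliberately strict.

Chart abstraction is modelled as done by two independent blinded reviewers
with a fraction of charts reviewed in duplicate; the duplicated subset feeds
the inter-rater kappa, while the first reviewer's label is authoritative for
the 2x2 table downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "DEFAULT_VOCABULARY",
    "ChartReview",
    "DualAbstraction",
    "UnknownComplaintError",
    "label_chart",
    "simulate_dual_abstraction",
    "read_reviews_csv",
    "write_reviews_csv",
    "load_vocabulary",
]

#: Canonical heat-related complaint terms (lowercase).  User-extensible: pass
#: a custom vocabulary to :func:`label_chart` or load one from file.
DEFAULT_VOCABULARY = frozenset(
    {
        "syncope",
        "heat stroke",
        "loss of consciousness",
        "muscle cramps",
        "pain",
        "exhaustion",
        "fatigue",
        "edema",
    }
)


class UnknownComplaintError(ValueError):
    """A review lists complaint terms outside the controlled vocabulary."""


@dataclass(frozen=True)
class ChartReview:
    """One reviewer's abstraction of one encounter's chart."""

    encounter_id: str
    reviewer_id: str
    exposure_documented: bool
    complaints: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "complaints", tuple(str(c).strip().lower() for c in self.complaints)
        )


def label_chart(review: ChartReview, vocabulary: frozenset | None = None) -> bool:
    """Apply the gold-standard definition: documented heat exposure AND >=1 complaint.

    Raises :class:`UnknownComplaintError` listing any complaint terms not in
    the vocabulary.
    """
    vocab = DEFAULT_VOCABULARY if vocabulary is None else vocabulary
    unknown = [c for c in review.complaints if c not in vocab]
    if unknown:
        raise UnknownComplaintError(
            f"chart {review.encounter_id}: unknown complaint terms {unknown}"
        )
    return review.exposure_documented and len(review.complaints) > 0


@dataclass(frozen=True)
class DualAbstraction:
    """Paired labels on the doubly-reviewed subset of a chart sample."""

    indices: tuple  # positions (into the original chart list) reviewed twice
    labels_a: tuple
    labels_b: tuple

    def pairs(self) -> list[tuple[bool, bool]]:
        return list(zip(self.labels_a, self.labels_b))


def simulate_dual_abstraction(
    truth: Sequence[bool],
    flip_prob_per_reviewer: float,
    duplicate_fraction: float,
    seed: int,
) -> DualAbstraction:
    """Simulate blinded duplicate review of round(f·n) randomly chosen charts.

    Each reviewer independently reports the true chart label, mislabelling
    with probability ``flip_prob_per_reviewer``.  With n charts the duplicated
    subset has round(duplicate_fraction·n) members (so 20% of 964 charts gives
    193 pairs).  Deterministic under ``seed``; n = 0 yields an empty result.
    """
    if not 0 <= duplicate_fraction <= 1:
        raise ValueError(f"duplicate_fraction must be in [0, 1], got {duplicate_fraction}")
    if not 0 <= flip_prob_per_reviewer <= 1:
        raise ValueError(f"flip_prob_per_reviewer must be in [0, 1], got {flip_prob_per_reviewer}")
    truth_arr = np.asarray(truth, dtype=bool)
    n = truth_arr.size
    m = round(duplicate_fraction * n)
    if m == 0:
        return DualAbstraction(indices=(), labels_a=(), labels_b=())
    rng = substream(seed, 31)
    idx = np.sort(rng.choice(n, size=m, replace=False))
    flips_a = rng.random(m) < flip_prob_per_reviewer
    flips_b = rng.random(m) < flip_prob_per_reviewer
    sub = truth_arr[idx]
    return DualAbstraction(
        indices=tuple(int(i) for i in idx),
        labels_a=tuple(bool(v) for v in sub ^ flips_a),
        labels_b=tuple(bool(v) for v in sub ^ flips_b),
    )


def read_reviews_csv(path: str | Path) -> list[ChartReview]:
    """Read reviews from CSV: encounter_id,reviewer_id,exposure_documented,complaints."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    reviews = []
    for row in df.itertuples(index=False):
        complaints = tuple(c for c in str(row.complaints).split(";") if c)
        reviews.append(
            ChartReview(
                encounter_id=str(row.encounter_id),
                reviewer_id=str(row.reviewer_id),
                exposure_documented=str(row.exposure_documented).strip().lower()
                in ("true", "1", "yes"),
                complaints=complaints,
            )
        )
    return reviews


def write_reviews_csv(reviews: Iterable[ChartReview], path: str | Path) -> None:
    """Write reviews to CSV (complaints semicolon-delimited)."""
    reviews = list(reviews)
    df = pd.DataFrame(
        {
            "encounter_id": [r.encounter_id for r in reviews],
            "reviewer_id": [r.reviewer_id for r in reviews],
            "exposure_documented": [str(r.exposure_documented).lower() for r in reviews],
            "complaints": [";".join(r.complaints) for r in reviews],
        }
    )
    df.to_csv(path, index=False)


def load_vocabulary(path: str | Path) -> frozenset:
    """Load a complaint vocabulary: one lowercase term per line, blanks ignored."""
    terms = frozenset(
        line.strip().lower() for line in Path(path).read_text().splitlines() if line.strip()
    )
    if not terms:
        raise ValueError(f"vocabulary file {path} contains no terms")
    return terms
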