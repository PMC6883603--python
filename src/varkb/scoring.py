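"""Evidence scoring: star rating times level weight, summed per variant.

An Evidence Item Score is the curator's star rating (one point per star)
multiplied by the weight of its evidence level — by default A=10, B=5, C=3,
D=1, E=0.5. The Variant Evidence Score is the plain sum over the variant's
counted evidence items: it measures the amount of vetted curation, not a
clinical verdict, and deliberately ignores conflicting directions. Arithmetic
is exact (``fractions.Fraction``) so the 0.5 weight never drifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional

from .models import EvidenceItem


class ScoreError(ValueError):
    """Rating outside 1-5 or an evidence level absent from the weight table."""


@dataclass(frozen=True)
class LevelWeights:
    """Positive per-level weights; defaults are the published scheme."""

    weights: Mapping[str, Fraction] = field(
        default_factory=lambda: {
            "A": Fraction(10),
            "B": Fraction(5),
            "C": Fraction(3),
            "D": Fraction(1),
            "E": Fraction(1, 2),
        }
    )

    def __post_init__(self) -> None:
        for level, weight in self.weights.items():
            if weight <= 0:
                raise ScoreError(f"weight for level {level} must be positive")

    def __getitem__(self, level: str) -> Fraction:
        try:
            return self.weights[level]
        except KeyError:
            raise ScoreError(f"unknown evidence level {level!r}") from None

    def __contains__(self, level: str) -> bool:
        return level in self.weights

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "LevelWeights":
        return cls({k: Fraction(str(v)) for k, v in mapping.items()})


DEFAULT_WEIGHTS = LevelWeights()

#: Moderation states whose evidence items count toward the variant score.
#: Rejected evidence never scores; the public number reflects vetted content.
DEFAULT_INCLUDED_STATUSES = frozenset({"accepted"})


@dataclass(frozen=True)
class ScoreReport:
    """Per-item scores and their exact sum for one variant."""

    variant_id: str
    per_eid: tuple[tuple[str, int, str, Fraction], ...]
    variant_score: Fraction
    included_statuses: frozenset[str]

    @property
    def n_items(self) -> int:
        return len(self.per_eid)


def evidence_item_score(
    rating: int,
    level: str,
    weights: LevelWeights = DEFAULT_WEIGHTS,
) -> Fraction:
    """Score one evidence item: ``rating × weights[level]``, exact."""
    if not isinstance(rating, int) or isinstance(rating, bool) or not 1 <= rating <= 5:
        raise ScoreError(f"evidence rating must be an integer 1-5, got {rating!r}")
    return rating * weights[level]


def variant_evidence_score(
    variant_id: str,
    evidence_items: Iterable[EvidenceItem],
    weights: LevelWeights = DEFAULT_WEIGHTS,
    included_statuses: frozenset[str] = DEFAULT_INCLUDED_STATUSES,
) -> ScoreReport:
    """Sum the scores of the variant's counted evidence items.

    Items whose moderation state is outside ``included_statuses`` or whose
    rating/level are unset are skipped; direction and significance are ignored
    by design, so opposing items add rather than cancel.
    """
    rows: list[tuple[str, int, str, Fraction]] = []
    for item in evidence_items:
        if item.variant_id != variant_id:
            raise ScoreError(
                f"evidence item {item.eid} belongs to {item.variant_id}, not {variant_id}"
            )
        if item.moderation.state not in included_statuses:
            continue
        # unscoreable items (missing or out-of-range rating/level) are the
        # validator's business; the aggregate counts only well-formed items
        rating, level = item.evidence_rating, item.evidence_level
        if not isinstance(rating, int) or not 1 <= rating <= 5:
            continue
        if level is None or level not in weights:
            continue
        score = evidence_item_score(item.evidence_rating, item.evidence_level, weights)
        rows.append((item.eid, item.evidence_rating, item.evidence_level, score))
    total = sum((row[3] for row in rows), Fraction(0))
    return ScoreReport(
        variant_id=variant_id,
        per_eid=tuple(rows),
        variant_score=total,
        included_statuses=frozenset(included_statuses),
    )


def format_score(score: Fraction) -> str:
    """Render an exact score: integers bare, halves with one decimal."""
    if score.denominator == 1:
        return str(score.numerator)
    return str(float(score))
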