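"""Classification engines for assertions.

Germline (Predisposing) assertions combine ACMG-AMP 2015 evidence codes into
the 5-tier classification (Pathogenic … Benign) via the published combining
table, encoded as an editable YAML data table. Somatic assertion types
(Predictive, Prognostic, Diagnostic) receive an AMP-ASCO-CAP 2017 Tier (I-IV)
and, for Tiers I-II, a Level (A-D) derived from regulatory flags and the
strength of the accepted supporting evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence, Union

import yaml

from .models import AcmgCode, Assertion
from .vocab import BENIGN_SIDE_SIGNIFICANCE


class AcmgError(ValueError):
    """Unknown or duplicated ACMG token, or an invalid strength override."""


class AmpTypeError(TypeError):
    """AMP tier assignment requested for a non-somatic assertion type."""


#: The 28 ACMG-AMP 2015 evidence codes.
ACMG_TOKENS: tuple[str, ...] = (
    ("PVS1",)
    + tuple(f"PS{i}" for i in range(1, 5))
    + tuple(f"PM{i}" for i in range(1, 7))
    + tuple(f"PP{i}" for i in range(1, 6))
    + ("BA1",)
    + tuple(f"BS{i}" for i in range(1, 5))
    + tuple(f"BP{i}" for i in range(1, 8))
)

#: Default strength by token prefix.
_PREFIX_STRENGTH = {
    "PVS": "very_strong",
    "PS": "strong",
    "PM": "moderate",
    "PP": "supporting",
    "BA": "standalone",
    "BS": "strong_benign",
    "BP": "supporting_benign",
}

PATHOGENIC_STRENGTHS = ("very_strong", "strong", "moderate", "supporting")
BENIGN_STRENGTHS = ("standalone", "strong_benign", "supporting_benign")

#: Override vocabulary -> internal strength, per side of the code.
_PATHOGENIC_OVERRIDES = {
    "very_strong": "very_strong",
    "strong": "strong",
    "moderate": "moderate",
    "supporting": "supporting",
}
_BENIGN_OVERRIDES = {
    "standalone": "standalone",
    "strong": "strong_benign",
    "supporting": "supporting_benign",
}


def token_prefix(token: str) -> str:
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if token.startswith(prefix) and token[len(prefix):].isdigit():
            return prefix
    raise AcmgError(f"unknown ACMG token {token!r}")


def is_benign_token(token: str) -> bool:
    return token_prefix(token) in ("BA", "BS", "BP")


def code_strength(code: AcmgCode) -> str:
    """Effective strength of a code after any override."""
    prefix = token_prefix(code.token)
    if code.token not in ACMG_TOKENS:
        raise AcmgError(f"unknown ACMG token {code.token!r}")
    if code.strength_override is None:
        return _PREFIX_STRENGTH[prefix]
    table = _BENIGN_OVERRIDES if prefix in ("BA", "BS", "BP") else _PATHOGENIC_OVERRIDES
    try:
        return table[code.strength_override]
    except KeyError:
        raise AcmgError(
            f"override {code.strength_override!r} invalid for {code.token}"
        ) from None


@dataclass(frozen=True)
class CombiningRow:
    """One combining-table row: fires when counts meet min (and any max)."""

    row_id: str
    result: str
    minimum: dict[str, int]
    maximum: dict[str, int] = field(default_factory=dict)

    def fires(self, counts: dict[str, int]) -> bool:
        for strength, needed in self.minimum.items():
            if counts.get(strength, 0) < needed:
                return False
        for strength, cap in self.maximum.items():
            if counts.get(strength, 0) > cap:
                return False
        return True


def _load_rows(doc: dict) -> tuple[list[CombiningRow], list[CombiningRow]]:
    def parse(rows):
        return [
            CombiningRow(
                row_id=r["id"],
                result=r["result"],
                minimum=dict(r.get("min", {})),
                maximum=dict(r.get("max", {})),
            )
            for r in rows
        ]

    return parse(doc["pathogenic_rows"]), parse(doc["benign_rows"])


def load_combining_table(path: Optional[str] = None):
    """Load combining rows from YAML; default is the bundled 2015 table."""
    if path is None:
        text = resources.files("varkb.data").joinpath("acmg_combining.yaml").read_text(
            encoding="utf-8"
        )
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    return _load_rows(yaml.safe_load(text))


_DEFAULT_ROWS = load_combining_table()

_RESULT_RANK = {"Likely Pathogenic": 1, "Pathogenic": 2, "Likely Benign": 1, "Benign": 2}


@dataclass(frozen=True)
class AcmgClassification:
    value: str
    fired_rules: tuple[str, ...] = ()
    conflict: bool = False


def combine_acmg(
    codes: Iterable[Union[AcmgCode, str]],
    table: Optional[tuple[Sequence[CombiningRow], Sequence[CombiningRow]]] = None,
) -> AcmgClassification:
    """Combine ACMG evidence codes into a 5-tier germline classification.

    Strength overrides are applied before counting. A rule firing on one side
    while codes from the opposite side are present is contradictory evidence
    and yields VUS with ``conflict=True``; no rule firing yields plain VUS.
    """
    pathogenic_rows, benign_rows = table if table is not None else _DEFAULT_ROWS
    normalized = [AcmgCode(c) if isinstance(c, str) else c for c in codes]
    seen: set[str] = set()
    for code in normalized:
        if code.token not in ACMG_TOKENS:
            raise AcmgError(f"unknown ACMG token {code.token!r}")
        if code.token in seen:
            raise AcmgError(f"duplicate ACMG token {code.token}")
        seen.add(code.token)

    counts: dict[str, int] = {}
    for code in normalized:
        strength = code_strength(code)
        counts[strength] = counts.get(strength, 0) + 1

    has_pathogenic_codes = any(not is_benign_token(c.token) for c in normalized)
    has_benign_codes = any(is_benign_token(c.token) for c in normalized)

    fired_path = [row for row in pathogenic_rows if row.fires(counts)]
    fired_benign = [row for row in benign_rows if row.fires(counts)]
    fired_ids = tuple(r.row_id for r in fired_path + fired_benign)

    conflict = (bool(fired_path) and has_benign_codes) or (
        bool(fired_benign) and has_pathogenic_codes
    )
    if conflict:
        return AcmgClassification("VUS", fired_ids, conflict=True)
    if fired_path:
        best = max(fired_path, key=lambda r: _RESULT_RANK[r.result])
        return AcmgClassification(best.result, fired_ids)
    if fired_benign:
        best = max(fired_benign, key=lambda r: _RESULT_RANK[r.result])
        return AcmgClassification(best.result, fired_ids)
    return AcmgClassification("VUS", ())


# ---------------------------------------------------------------------------
# AMP-ASCO-CAP tier/level assignment (somatic assertion types)
# ---------------------------------------------------------------------------

_LEVEL_ORDER = {"A": 0, "B": 1, "C": 2, "D": 3, "E": 4}

SOMATIC_ASSERTION_TYPES = ("Predictive", "Prognostic", "Diagnostic")


@dataclass(frozen=True)
class AmpAssignment:
    tier: str
    level: Optional[str] = None
    rationale: tuple[str, ...] = ()


def assign_amp(assertion: Assertion, corpus) -> AmpAssignment:
    """Assign an AMP-ASCO-CAP Tier (and Level for Tiers I-II) to an assertion.

    Level table (a documented stand-in for guideline evidence minima):
    Level A needs a regulatory anchor (FDA approval/companion test or an NCCN
    guideline) corroborated by an accepted Level-A evidence item; Level B an
    accepted Level A/B item with Supports direction; Level C/D follow the best
    accepted supporting item. Tier I covers Levels A/B, Tier II Levels C/D;
    Tier III marks missing significance consensus (no supporting accepted
    evidence on the asserted significance, or contradiction); Tier IV marks
    benign-side asserted significance. Only Supports-direction items count
    toward the level; Does-not-support items count toward contradiction.
    """
    if assertion.assertion_type not in SOMATIC_ASSERTION_TYPES:
        raise AmpTypeError(
            f"assertion type {assertion.assertion_type!r} uses the ACMG germline "
            "pathway (combine_acmg), not AMP tier assignment"
        )

    rationale: list[str] = []
    accepted = []
    for eid in assertion.supporting_eids:
        item = corpus.evidence_items.get(eid)
        if item is not None and item.moderation.state == "accepted":
            accepted.append(item)

    if assertion.clinical_significance in BENIGN_SIDE_SIGNIFICANCE:
        rationale.append(
            f"asserted significance {assertion.clinical_significance!r} is benign-side"
        )
        return AmpAssignment("IV", None, tuple(rationale))

    supports = [
        i
        for i in accepted
        if i.evidence_direction == "Supports"
        and i.clinical_significance == assertion.clinical_significance
        and i.clinical_significance not in (None, "N/A")
    ]
    refutes = [
        i
        for i in accepted
        if i.evidence_direction == "Does not support"
        and i.clinical_significance == assertion.clinical_significance
    ]

    if not supports:
        rationale.append("no accepted Supports-direction evidence on the asserted significance")
        return AmpAssignment("III", None, tuple(rationale))
    if refutes and len(refutes) >= len(supports):
        rationale.append(
            f"contradictory directions: {len(refutes)} refuting vs {len(supports)} supporting"
        )
        return AmpAssignment("III", None, tuple(rationale))

    levels = sorted({i.evidence_level for i in supports if i.evidence_level in _LEVEL_ORDER},
                    key=_LEVEL_ORDER.get)
    best = levels[0] if levels else "E"
    regulatory = (
        assertion.fda_regulatory_approval
        or assertion.fda_companion_test
        or bool(assertion.nccn_guideline)
    )

    if regulatory and "A" in levels:
        level = "A"
        rationale.append("regulatory/guideline anchor with accepted Level A evidence")
    elif best in ("A", "B"):
        level = "B"
        rationale.append(f"accepted Level {best} supporting evidence")
    elif best == "C":
        level = "C"
        rationale.append("best accepted evidence is Level C (case studies)")
    else:
        level = "D"
        rationale.append(f"best accepted evidence is Level {best} (preclinical/inferential)")

    tier = "I" if level in ("A", "B") else "II"
    rationale.append(f"{len(supports)} supporting accepted evidence item(s)")
    return AmpAssignment(tier, level, tuple(rationale))
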