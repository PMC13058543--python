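"""Additive chest trauma score calculators.

Two published additive severity scores over structured chest X-ray findings:

* the conventional chest trauma score (C-CTS): age band + rib-fracture band +
  bilaterality + pulmonary-contusion grade, range 2-12;
* the South African chest trauma score (SA-CTS): an X-ray-only variant that
  drops age, assigns zero points to the absence of rib fractures, and adds
  one point each for pneumothorax and haemothorax, range 0-11;
* the modified SA-CTS: SA-CTS with the age component re-added, range 1-14.

The published C-CTS component table assigns the "< 3 fractures" category one
point, which read literally includes zero fractures; worked examples in the
source material are split between that literal reading and one where an
uninjured chest scores zero.  Both conventions are available via
:class:`ZeroRibRule`; the literal table is the default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from .cohort import ContusionGrade, PatientRecord, RadiographicFindings, ValidationError


class Scheme(str, enum.Enum):
    CCTS = "ccts"
    SACTS = "sacts"
    MODIFIED_SACTS = "modified_sacts"


class ZeroRibRule(str, enum.Enum):
    """How the C-CTS scores a patient with no visible rib fractures.

    ``TABLE2_LITERAL``: the "< 3" category applies, scoring 1 (score floor 2).
    ``ZERO_SCORES_ZERO``: absence of fractures scores 0, as in the SA-CTS.
    """

    TABLE2_LITERAL = "table2_literal"
    ZERO_SCORES_ZERO = "zero_scores_zero"


DEFAULT_ZERO_RIB_RULE = ZeroRibRule.TABLE2_LITERAL

#: theoretical total ranges per scheme (C-CTS under the literal convention)
SCHEME_RANGES: dict[Scheme, tuple[int, int]] = {
    Scheme.CCTS: (2, 12),
    Scheme.SACTS: (0, 11),
    Scheme.MODIFIED_SACTS: (1, 14),
}

_CONTUSION_POINTS = {
    ContusionGrade.NONE: 0,
    ContusionGrade.UNILATERAL_MINOR: 1,
    ContusionGrade.BILATERAL_MINOR: 2,
    ContusionGrade.UNILATERAL_MAJOR: 3,
    ContusionGrade.BILATERAL_MAJOR: 4,
}


@dataclass(frozen=True)
class ScoreResult:
    """A score total with its per-variable breakdown (absent parts zero)."""

    total: int
    scheme: Scheme
    age: int = 0
    rib: int = 0
    bilateral: int = 0
    contusion: int = 0
    pneumothorax: int = 0
    haemothorax: int = 0

    def __post_init__(self) -> None:
        parts = (
            self.age + self.rib + self.bilateral + self.contusion
            + self.pneumothorax + self.haemothorax
        )
        if parts != self.total:
            raise ValueError(f"components sum to {parts}, not total {self.total}")


def age_component(age_years: int) -> int:
    """Age points: <45 -> 1, 45-65 (inclusive) -> 2, >65 -> 3."""
    if age_years < 18:
        raise ValidationError(f"age_years must be >= 18 (adult score), got {age_years}")
    if age_years < 45:
        return 1
    if age_years <= 65:
        return 2
    return 3


def _rib_component(count: int, zero_scores_zero: bool) -> int:
    if count == 0:
        return 0 if zero_scores_zero else 1
    if count < 3:
        return 1
    if count <= 5:
        return 2
    return 3


def ccts_score(
    age_years: int,
    findings: RadiographicFindings,
    zero_rib_rule: ZeroRibRule = DEFAULT_ZERO_RIB_RULE,
) -> ScoreResult:
    """Conventional chest trauma score.

    Age + rib-fracture band (<3 -> 1, 3-5 -> 2, >5 -> 3) + bilateral fractures
    (2) + contusion grade (0-4).  Pleural findings are not scored.  Under the
    literal published component table the total lies in 2-12.
    """
    rule = ZeroRibRule(zero_rib_rule)
    age = age_component(age_years)
    rib = _rib_component(
        findings.rib_fracture_count, rule is ZeroRibRule.ZERO_SCORES_ZERO
    )
    bilateral = 2 if findings.bilateral_rib_fractures else 0
    contusion = _CONTUSION_POINTS[findings.contusion_grade]
    return ScoreResult(
        total=age + rib + bilateral + contusion,
        scheme=Scheme.CCTS,
        age=age,
        rib=rib,
        bilateral=bilateral,
        contusion=contusion,
    )


def sacts_score(findings: RadiographicFindings) -> ScoreResult:
    """South African chest trauma score (X-ray only, no age).

    Rib band (0 -> 0, 1-2 -> 1, 3-5 -> 2, >5 -> 3) + bilateral fractures (2)
    + contusion grade (0-4) + pneumothorax (1) + haemothorax (1); total 0-11.
    """
    rib = _rib_component(findings.rib_fracture_count, zero_scores_zero=True)
    bilateral = 2 if findings.bilateral_rib_fractures else 0
    contusion = _CONTUSION_POINTS[findings.contusion_grade]
    pneumo = 1 if findings.pneumothorax else 0
    haemo = 1 if findings.haemothorax else 0
    return ScoreResult(
        total=rib + bilateral + contusion + pneumo + haemo,
        scheme=Scheme.SACTS,
        rib=rib,
        bilateral=bilateral,
        contusion=contusion,
        pneumothorax=pneumo,
        haemothorax=haemo,
    )


def modified_sacts_score(age_years: int, findings: RadiographicFindings) -> ScoreResult:
    """SA-CTS with the age component re-added (sensitivity-analysis variant)."""
    base = sacts_score(findings)
    age = age_component(age_years)
    return ScoreResult(
        total=base.total + age,
        scheme=Scheme.MODIFIED_SACTS,
        age=age,
        rib=base.rib,
        bilateral=base.bilateral,
        contusion=base.contusion,
        pneumothorax=base.pneumothorax,
        haemothorax=base.haemothorax,
    )


def score_patient(
    record: PatientRecord,
    scheme: Scheme,
    zero_rib_rule: ZeroRibRule = DEFAULT_ZERO_RIB_RULE,
) -> ScoreResult:
    scheme = Scheme(scheme)
    if scheme is Scheme.CCTS:
        return ccts_score(record.age_years, record.findings, zero_rib_rule)
    if scheme is Scheme.SACTS:
        return sacts_score(record.findings)
    return modified_sacts_score(record.age_years, record.findings)


def score_cohort(
    records: Sequence[PatientRecord],
    scheme: Scheme,
    zero_rib_rule: ZeroRibRule = DEFAULT_ZERO_RIB_RULE,
) -> list[ScoreResult]:
    """Score every record under one scheme, preserving input order."""
    if not records:
        raise ValidationError("cannot score an empty cohort")
    return [score_patient(r, scheme, zero_rib_rule) for r in records]
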