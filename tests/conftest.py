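"""Shared fixtures: worked-example patients, printed contingency tables, and a
programmatically reconstructed cohort whose per-variable margins match the
reference study tables exactly."""

from __future__ import annotations

import itertools

import pytest

from sacts_kit.cohort import (
    ContusionGrade,
    Disposition,
    Mechanism,
    PatientRecord,
    RadiographicFindings,
    Sex,
)


def findings(
    ribs: int = 0,
    bilateral: bool = False,
    contusion: ContusionGrade = ContusionGrade.NONE,
    pneumo: bool = False,
    haemo: bool = False,
) -> RadiographicFindings:
    return RadiographicFindings(
        rib_fracture_count=ribs,
        bilateral_rib_fractures=bilateral,
        contusion_grade=contusion,
        pneumothorax=pneumo,
        haemothorax=haemo,
    )


@pytest.fixture(scope="session")
def worked_examples():
    """The four published worked examples: (age, findings, C-CTS, SA-CTS, zero-rib rule).

    The quoted C-CTS totals for (b) and (c) require the zero-scores-zero rib
    convention; (a)'s total of 2 requires the literal component table.
    """
    return [
        # (a) 27 y, clear chest
        dict(age=27, f=findings(), ccts=2, sacts=0, rule="table2_literal"),
        # (b) 53 y, unilateral minor contusion only
        dict(age=53, f=findings(contusion=ContusionGrade.UNILATERAL_MINOR),
             ccts=3, sacts=1, rule="zero_scores_zero"),
        # (c) 31 y, bilateral major contusions + haemothorax
        dict(age=31, f=findings(contusion=ContusionGrade.BILATERAL_MAJOR, haemo=True),
             ccts=5, sacts=5, rule="zero_scores_zero"),
        # (d) 56 y, >5 bilateral fractures, bilateral major contusions, pneumothorax
        dict(age=56, f=findings(ribs=6, bilateral=True,
                                contusion=ContusionGrade.BILATERAL_MAJOR, pneumo=True),
             ccts=11, sacts=10, rule="table2_literal"),
    ]


@pytest.fixture(scope="session")
def printed_tables():
    """2x2 tables as printed in the reference association tables.

    Rows are exposure levels in listed order, columns (non_critical, critical).
    Expected values are the conditional-MLE OR and exact CI at 2 dp; values
    cross-checked against R fisher.test and scipy.
    """
    return {
        "sex": dict(rows=[[140, 73], [62, 26]], odds_ratio=0.80, ci=(0.45, 1.42), p3=0.500),
        "ventilation": dict(rows=[[199, 70], [3, 29]], odds_ratio=27.16,
                            ci=(8.04, 143.61), p3=None),
        "bilateral": dict(rows=[[197, 90], [5, 9]], odds_ratio=3.92, ci=(1.14, 15.33),
                          p3=0.017),
        "pneumothorax": dict(rows=[[194, 81], [8, 18]], odds_ratio=5.35, ci=(2.11, 14.84),
                             p3=None),
        "haemothorax": dict(rows=[[138, 50], [64, 49]], odds_ratio=2.11, ci=(1.25, 3.56),
                            p3=0.004),
        "ccts_high": dict(rows=[[157, 44], [45, 55]], odds_ratio=4.34, ci=(2.52, 7.55),
                          p3=None),
        "sacts_high": dict(rows=[[165, 51], [37, 48]], odds_ratio=4.17, ci=(2.38, 7.39),
                           p3=None),
    }


def _spread(pairs):
    """[(value, count), ...] -> flat list with exact multiplicities."""
    return list(itertools.chain.from_iterable([v] * c for v, c in pairs))


@pytest.fixture(scope="session")
def reconstructed_cohort():
    """A 301-patient cohort whose margins reproduce the reference summary
    table and whose per-variable outcome cross-tabulations reproduce the
    reference association table, built deterministically.

    Within each outcome class every variable's level counts are exact;
    bilateral fractures are aligned with the 3-5 fracture band so every
    record satisfies the bilaterality invariant.
    """
    C = ContusionGrade
    per_class = {
        # critical: 99 patients
        "critical": dict(
            n=99,
            sex=_spread([(Sex.MALE, 73), (Sex.FEMALE, 26)]),
            age=_spread([(30, 81), (50, 11), (70, 7)]),
            # rib counts: 1 of >5, 23 of 3-5, then 14 singles and 61 zeros
            ribs=_spread([(6, 1), (3, 23), (1, 14), (0, 61)]),
            bilateral=_spread([(True, 9), (False, 90)]),
            contusion=_spread([(C.NONE, 20), (C.UNILATERAL_MINOR, 20),
                               (C.BILATERAL_MINOR, 12), (C.UNILATERAL_MAJOR, 30),
                               (C.BILATERAL_MAJOR, 17)]),
            pneumo=_spread([(True, 18), (False, 81)]),
            haemo=_spread([(True, 49), (False, 50)]),
            vent=_spread([(True, 29), (False, 70)]),
            dispo=_spread([(Disposition.ICU, 86), (Disposition.DEATH, 11),
                           (Disposition.POOR_OUTCOME, 2)]),
        ),
        # non-critical: 202 patients
        "non_critical": dict(
            n=202,
            sex=_spread([(Sex.MALE, 140), (Sex.FEMALE, 62)]),
            age=_spread([(30, 148), (50, 44), (70, 10)]),
            ribs=_spread([(3, 18), (1, 55), (0, 129)]),
            bilateral=_spread([(True, 5), (False, 197)]),
            contusion=_spread([(C.NONE, 88), (C.UNILATERAL_MINOR, 57),
                               (C.BILATERAL_MINOR, 25), (C.UNILATERAL_MAJOR, 23),
                               (C.BILATERAL_MAJOR, 9)]),
            pneumo=_spread([(True, 8), (False, 194)]),
            haemo=_spread([(True, 64), (False, 138)]),
            vent=_spread([(True, 3), (False, 199)]),
            dispo=_spread([(Disposition.WARD, 200), (Disposition.DISCHARGED, 2)]),
        ),
    }
    mechanisms = _spread(
        [(Mechanism.MOTOR_VEHICLE_ACCIDENT, 181), (Mechanism.PEDESTRIAN_VEHICLE_ACCIDENT, 90),
         (Mechanism.FALL_FROM_HEIGHT, 21), (Mechanism.ASSAULT, 6), (Mechanism.UNKNOWN, 3)]
    )
    records = []
    idx = 0
    for label, cls in per_class.items():
        for i in range(cls["n"]):
            records.append(
                PatientRecord(
                    patient_id=f"{label}-{i:03d}",
                    age_years=cls["age"][i],
                    sex=cls["sex"][i],
                    mechanism=mechanisms[idx],
                    ventilated=cls["vent"][i],
                    disposition=cls["dispo"][i],
                    findings=RadiographicFindings(
                        rib_fracture_count=cls["ribs"][i],
                        bilateral_rib_fractures=cls["bilateral"][i],
                        contusion_grade=cls["contusion"][i],
                        pneumothorax=cls["pneumo"][i],
                        haemothorax=cls["haemo"][i],
                    ),
                )
            )
            idx += 1
    assert len(records) == 301
    return records
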