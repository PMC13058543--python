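"""Score-versus-outcome curves, dichotomization and cutpoint selection.

A risk score is clinically actionable once dichotomized: patients at or above
a threshold are flagged high risk.  This module tabulates the per-score
critical-outcome fractions (the curves clinicians eyeball for a "sharp
increase"), builds the low/high 2x2 table at any candidate threshold, and
selects a threshold by a reproducible surrogate for the visual criterion:
the feasible candidate minimizing the two-sided exact p-value, with ties
broken toward the smallest cutoff.  The full sweep (per-candidate table,
exact inference, sensitivity, specificity) is always reported so users can
apply their own judgement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .cohort import OutcomeLabel
from .exact import ExactTestResult, Table2x2, exact_test_2x2


@dataclass(frozen=True)
class ScoreOutcomeCurve:
    """Per score value: critical / non-critical counts and critical fraction.

    ``points`` maps score value -> (n_critical, n_non_critical); values in
    ``score_range`` that no patient attained appear with zero counts.
    """

    points: dict[int, tuple[int, int]]

    @property
    def n(self) -> int:
        return sum(c + nc for c, nc in self.points.values())

    def fraction_critical(self, score: int) -> float:
        c, nc = self.points[score]
        return c / (c + nc) if c + nc else math.nan


def _check_outcomes(scores: Sequence[int], outcomes: Sequence[OutcomeLabel]) -> list[bool]:
    if len(scores) != len(outcomes):
        raise ValueError(
            f"scores ({len(scores)}) and outcomes ({len(outcomes)}) differ in length"
        )
    if not scores:
        raise ValueError("need at least one patient")
    return [OutcomeLabel(o) is OutcomeLabel.CRITICAL for o in outcomes]


def score_outcome_curve(
    scores: Sequence[int],
    outcomes: Sequence[OutcomeLabel],
    score_range: tuple[int, int] | None = None,
) -> ScoreOutcomeCurve:
    """Tabulate critical/non-critical counts at each score value.

    ``score_range`` (inclusive) pads unattained values with zero counts so a
    scheme's full theoretical range appears on the curve.
    """
    critical = _check_outcomes(scores, outcomes)
    lo = min(scores) if score_range is None else min(score_range[0], min(scores))
    hi = max(scores) if score_range is None else max(score_range[1], max(scores))
    points = {v: [0, 0] for v in range(lo, hi + 1)}
    for s, crit in zip(scores, critical):
        points[s][0 if crit else 1] += 1
    return ScoreOutcomeCurve(points={v: (c, nc) for v, (c, nc) in points.items()})


def dichotomize(
    scores: Sequence[int], cutoff: int, outcomes: Sequence[OutcomeLabel]
) -> Table2x2:
    """Split at ``cutoff`` into low (score < cutoff) and high (score >= cutoff).

    Rows (low, high), columns (non_critical, critical) — the layout the
    exact-inference engine expects, with psi > 1 meaning high scores carry
    higher odds of a critical outcome.
    """
    critical = _check_outcomes(scores, outcomes)
    a = b = c = d = 0
    for s, crit in zip(scores, critical):
        if s < cutoff:
            b, a = (b + 1, a) if crit else (b, a + 1)
        else:
            d, c = (d + 1, c) if crit else (d, c + 1)
    return Table2x2(a, b, c, d)


@dataclass(frozen=True)
class CutpointCandidate:
    cutoff: int
    table: Table2x2
    feasible: bool
    result: ExactTestResult | None
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class CutpointSweep:
    candidates: list[CutpointCandidate]
    selected_cutoff: int
    selection_rule: str = "min_exact_p_smallest_cutoff"

    def candidate(self, cutoff: int) -> CutpointCandidate:
        for cand in self.candidates:
            if cand.cutoff == cutoff:
                return cand
        raise KeyError(cutoff)


def cutpoint_sweep(
    scores: Sequence[int],
    outcomes: Sequence[OutcomeLabel],
    candidate_cutoffs: Sequence[int],
    conf_level: float = 0.95,
) -> CutpointSweep:
    """Evaluate every candidate threshold and select the minimum-p one.

    A candidate is feasible when both the low and high groups are non-empty;
    infeasible candidates are reported (with their degenerate table) but
    never selected.  Sensitivity is the fraction of critical patients at or
    above the cutoff; specificity the fraction of non-critical patients
    below it.
    """
    if len(candidate_cutoffs) < 2:
        raise ValueError("need at least two candidate cutoffs")
    critical = _check_outcomes(scores, outcomes)
    n_crit = sum(critical)
    n_noncrit = len(critical) - n_crit

    candidates: list[CutpointCandidate] = []
    for cutoff in sorted(set(int(c) for c in candidate_cutoffs)):
        table = dichotomize(scores, cutoff, outcomes)
        low_n = table.a + table.b
        high_n = table.c + table.d
        feasible = low_n > 0 and high_n > 0
        sens = table.d / n_crit if n_crit else math.nan
        spec = table.a / n_noncrit if n_noncrit else math.nan
        result = exact_test_2x2(table, conf_level) if feasible else None
        candidates.append(
            CutpointCandidate(
                cutoff=cutoff, table=table, feasible=feasible,
                result=result, sensitivity=sens, specificity=spec,
            )
        )

    feasible_cands = [c for c in candidates if c.feasible]
    if not feasible_cands:
        raise ValueError("no feasible candidate cutoff (one group always empty)")
    # min p; ties (within nothing — exact equality) go to the smallest cutoff,
    # which sorted order already guarantees
    selected = min(feasible_cands, key=lambda c: (c.result.p_two_sided, c.cutoff))
    return CutpointSweep(candidates=candidates, selected_cutoff=selected.cutoff)
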