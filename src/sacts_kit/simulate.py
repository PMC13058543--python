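"""Seeded synthetic blunt-chest-trauma cohort generator.

Emulates a single-centre adult cohort of 301 emergency-department patients:
demographics and CXR findings are drawn independently from the observed
marginal distributions, a patient's SA-CTS is computed from the sampled
findings, and the critical/non-critical outcome is drawn from a logistic
link on that score.  Disposition within each outcome class and the
ventilation flag are then sampled conditionally, so a generated cohort
round-trips through the full analysis pipeline.

The logistic link's intercept and slope are calibrated so the population
critical fraction and the population odds ratio of a high score (SA-CTS >= 4)
match the study-level targets (0.328 and ~4.17).  Because the SA-CTS score
distribution implied by the findings marginals is computable in closed form,
calibration is exact root-finding, not simulation.

Findings components are independent by default (only marginals are known);
an optional multiplier raises pleural-injury probabilities for patients with
three or more rib fractures, off (1.0) unless requested.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import (
    ContusionGrade,
    Disposition,
    Mechanism,
    PatientRecord,
    RadiographicFindings,
    Sex,
)
from .scores import sacts_score

_CONTUSION_LEVELS = list(ContusionGrade)
_MECHANISM_LEVELS = list(Mechanism)

# disposition splits within each outcome class (ICU : death : poor outcome,
# ward : discharged), matching the observed cohort composition
_CRITICAL_DISPO = ([Disposition.ICU, Disposition.DEATH, Disposition.POOR_OUTCOME],
                   [86 / 99, 11 / 99, 2 / 99])
_NONCRITICAL_DISPO = ([Disposition.WARD, Disposition.DISCHARGED],
                      [200 / 202, 2 / 202])


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic link from the SA-CTS to the probability of a critical outcome.

    ``link = "step"`` (default): P(critical) = expit(intercept + slope * 1[score >= threshold]),
    i.e. a genuine jump in risk at the threshold — the coupling that makes
    threshold recovery well-posed and mirrors a dichotomized risk table.
    ``link = "linear"``: P(critical) = expit(intercept + slope * score), a
    smooth dose-response alternative.
    """

    intercept: float
    slope: float
    link: str = "step"
    threshold: int = 4

    def __post_init__(self) -> None:
        if self.link not in ("step", "linear"):
            raise ValueError(f"link must be 'step' or 'linear', got {self.link!r}")

    def p_critical(self, score) -> np.ndarray:
        """Vectorized P(critical | SA-CTS = score)."""
        s = np.asarray(score)
        x = (s >= self.threshold).astype(float) if self.link == "step" else s
        return expit(self.intercept + self.slope * x)


@dataclass(frozen=True)
class CohortSimParams:
    """Generator parameters; defaults reproduce the reference cohort marginals.

    Probability vectors are ordered as their level lists: age bands
    (<45, 45-65, >65); mechanisms (MVA, PVA, fall, assault, unknown); rib
    bands (0, 1-2, 3-5, >5); contusion (none, uni-minor, bi-minor, uni-major,
    bi-major).  ``p_bilateral_given_multi`` applies to patients with >= 2
    fractures and its default makes the marginal bilateral rate ~4.7%.
    ``pleural_rib_dependence`` multiplies pneumo/haemothorax probabilities
    when the rib count is >= 3 (1.0 = independent, the default).
    """

    n: int = 301
    seed: int = 0
    p_male: float = 0.708
    age_band_probs: tuple[float, ...] = (0.761, 0.183, 0.056)
    mechanism_probs: tuple[float, ...] = (0.601, 0.299, 0.070, 0.020, 0.010)
    rib_band_probs: tuple[float, ...] = (0.631, 0.230, 0.136, 0.003)
    p_bilateral_given_multi: float = 0.183
    contusion_probs: tuple[float, ...] = (0.359, 0.256, 0.123, 0.176, 0.086)
    p_pneumothorax: float = 0.086
    p_haemothorax: float = 0.375
    outcome_model: OutcomeModel = field(default=OutcomeModel(0.0, 0.0))
    p_ventilated_given_critical: float = 29 / 99
    p_ventilated_given_noncritical: float = 3 / 202
    pleural_rib_dependence: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        for name, vec, k in (
            ("age_band_probs", self.age_band_probs, 3),
            ("mechanism_probs", self.mechanism_probs, 5),
            ("rib_band_probs", self.rib_band_probs, 4),
            ("contusion_probs", self.contusion_probs, 5),
        ):
            if len(vec) != k:
                raise ValueError(f"{name} must have {k} entries")
            if any(p < 0 for p in vec):
                raise ValueError(f"{name} has a negative entry")
            if abs(sum(vec) - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1, got {sum(vec)}")
        for name in (
            "p_male", "p_bilateral_given_multi", "p_pneumothorax", "p_haemothorax",
            "p_ventilated_given_critical", "p_ventilated_given_noncritical",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pleural_rib_dependence < 0:
            raise ValueError("pleural_rib_dependence must be >= 0")

    def to_json(self, path: str | Path) -> None:
        d = {k: v for k, v in self.__dict__.items() if k != "outcome_model"}
        d["outcome_intercept"] = self.outcome_model.intercept
        d["outcome_slope"] = self.outcome_model.slope
        d["outcome_link"] = self.outcome_model.link
        d["outcome_threshold"] = self.outcome_model.threshold
        Path(path).write_text(json.dumps(d, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSimParams":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        model = OutcomeModel(
            d.pop("outcome_intercept"),
            d.pop("outcome_slope"),
            d.pop("outcome_link", "step"),
            d.pop("outcome_threshold", 4),
        )
        for key in ("age_band_probs", "mechanism_probs", "rib_band_probs", "contusion_probs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(outcome_model=model, **d)


# ---------------------------------------------------------------------------
# exact SA-CTS distribution under the findings marginals
# ---------------------------------------------------------------------------

def sacts_distribution(params: CohortSimParams) -> np.ndarray:
    """Exact pmf of the SA-CTS (length 12, scores 0..11) implied by ``params``.

    Enumerates the rib-band / bilaterality cases, then convolves in the
    contusion and pleural components.  When ``pleural_rib_dependence`` != 1
    the pleural probabilities differ between the <3 and >=3 fracture strata,
    so the convolution is done per stratum.
    """
    pb = params.p_bilateral_given_multi
    p0, p12, p35, p6 = params.rib_band_probs

    # (rib+bilateral points, probability, has >= 3 fractures)
    rib_cases = [
        (0, p0, False),
        (1, p12 * 0.5, False),              # one fracture: never bilateral
        (1, p12 * 0.5 * (1 - pb), False),   # two fractures, unilateral
        (3, p12 * 0.5 * pb, False),         # two fractures, bilateral (+2)
        (2, p35 * (1 - pb), True),
        (4, p35 * pb, True),
        (3, p6 * (1 - pb), True),
        (5, p6 * pb, True),
    ]

    pmf = np.zeros(12)
    for stratum_multi in (False, True):
        boost = params.pleural_rib_dependence if stratum_multi else 1.0
        p_pneu = min(1.0, params.p_pneumothorax * boost)
        p_haem = min(1.0, params.p_haemothorax * boost)
        base = np.zeros(12)
        for pts, prob, multi in rib_cases:
            if multi == stratum_multi:
                base[pts] += prob
        if base.sum() == 0:
            continue
        conv = np.convolve(base, np.asarray(params.contusion_probs))
        conv = np.convolve(conv, [1 - p_pneu, p_pneu])
        conv = np.convolve(conv, [1 - p_haem, p_haem])
        pmf[: len(conv[:12])] += conv[:12]
    return pmf


# ---------------------------------------------------------------------------
# outcome-model calibration
# ---------------------------------------------------------------------------

class CalibrationError(ValueError):
    """The requested calibration targets are not attainable."""


def _critical_fraction(pmf: np.ndarray, model: OutcomeModel) -> float:
    return float(pmf @ model.p_critical(np.arange(len(pmf))))


def _population_or(pmf: np.ndarray, model: OutcomeModel, cutoff: int) -> float:
    s = np.arange(len(pmf))
    p_crit = model.p_critical(s)
    hi = s >= cutoff
    w_hi, w_lo = pmf[hi].sum(), pmf[~hi].sum()
    c_hi = float(pmf[hi] @ p_crit[hi]) / w_hi
    c_lo = float(pmf[~hi] @ p_crit[~hi]) / w_lo
    return (c_hi / (1 - c_hi)) / (c_lo / (1 - c_lo))


def _intercept_for_fraction(
    pmf: np.ndarray, slope: float, target: float, link: str, threshold: int
) -> float:
    if slope == 0.0:
        return math.log(target / (1 - target))
    return brentq(
        lambda a: _critical_fraction(pmf, OutcomeModel(a, slope, link, threshold)) - target,
        -50.0, 50.0, xtol=1e-12, maxiter=200,
    )


def calibrate_outcome_model(
    params: CohortSimParams,
    target_critical_fraction: float = 0.328,
    target_high_or: float | None = 4.17,
    cutoff: int = 4,
    slope: float | None = None,
    link: str = "step",
) -> OutcomeModel:
    """Solve the logistic link's parameters against population targets.

    With ``slope`` given (``target_high_or`` ignored), only the intercept is
    solved so the expected critical fraction matches
    ``target_critical_fraction``.  Otherwise both parameters are found by
    nested root-finding: for each trial slope the intercept is solved for the
    critical fraction, and the outer root matches the population odds ratio
    of score >= ``cutoff`` to ``target_high_or``.  At fixed critical fraction
    the population OR is increasing in the slope, so the outer root is unique.
    """
    if not 0.0 < target_critical_fraction < 1.0:
        raise CalibrationError(
            f"target critical fraction must be in (0, 1), got {target_critical_fraction}"
        )
    pmf = sacts_distribution(params)
    if slope is not None:
        a = _intercept_for_fraction(pmf, slope, target_critical_fraction, link, cutoff)
        return OutcomeModel(a, slope, link, cutoff)
    if target_high_or is None or target_high_or <= 0:
        raise CalibrationError("target_high_or must be positive when slope is free")

    def or_gap(b: float) -> float:
        a = _intercept_for_fraction(pmf, b, target_critical_fraction, link, cutoff)
        return _population_or(pmf, OutcomeModel(a, b, link, cutoff), cutoff) - target_high_or

    b_lo, b_hi = 0.0, 8.0
    if or_gap(b_hi) < 0:
        attained = or_gap(b_hi) + target_high_or
        raise CalibrationError(
            f"target OR {target_high_or} not attainable; max attained ~{attained:.2f}"
        )
    b = brentq(or_gap, b_lo, b_hi, xtol=1e-10, maxiter=200)
    a = _intercept_for_fraction(pmf, b, target_critical_fraction, link, cutoff)
    return OutcomeModel(a, b, link, cutoff)


def default_params_from_table4(n: int = 301, seed: int = 0) -> CohortSimParams:
    """Default parameters: reference-cohort marginals plus a calibrated link."""
    base = CohortSimParams(n=n, seed=seed)
    model = calibrate_outcome_model(base)
    return replace(base, outcome_model=model)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_AGE_RANGES = ((18, 44), (45, 65), (66, 90))  # inclusive, per age band


def generate_cohort(params: CohortSimParams) -> list[PatientRecord]:
    """Draw a cohort of ``params.n`` patients, deterministically in the seed.

    Fields are drawn vectorized in a fixed documented order (sex, age band,
    age, mechanism, rib band, rib count, bilaterality, contusion,
    pneumothorax, haemothorax, outcome, disposition, ventilation), so equal
    seeds give byte-identical cohorts across runs and platforms.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n

    male = rng.random(n) < params.p_male
    band_idx = rng.choice(3, size=n, p=np.asarray(params.age_band_probs))
    age_u = rng.random(n)
    ages = np.array(
        [lo + int(u * (hi - lo + 1)) for (lo, hi), u in
         zip((_AGE_RANGES[i] for i in band_idx), age_u)]
    )
    mech_idx = rng.choice(5, size=n, p=np.asarray(params.mechanism_probs))

    rib_band_idx = rng.choice(4, size=n, p=np.asarray(params.rib_band_probs))
    count_u = rng.random(n)
    _COUNT_RANGES = ((0, 0), (1, 2), (3, 5), (6, 8))  # ">5" realized as 6-8
    rib_counts = np.array(
        [lo + int(u * (hi - lo + 1)) for (lo, hi), u in
         zip((_COUNT_RANGES[i] for i in rib_band_idx), count_u)]
    )
    bilateral = (rib_counts >= 2) & (rng.random(n) < params.p_bilateral_given_multi)

    contusion_idx = rng.choice(5, size=n, p=np.asarray(params.contusion_probs))
    boost = np.where(rib_counts >= 3, params.pleural_rib_dependence, 1.0)
    pneumo = rng.random(n) < np.minimum(1.0, params.p_pneumothorax * boost)
    haemo = rng.random(n) < np.minimum(1.0, params.p_haemothorax * boost)

    findings = [
        RadiographicFindings(
            rib_fracture_count=int(rib_counts[i]),
            bilateral_rib_fractures=bool(bilateral[i]),
            contusion_grade=_CONTUSION_LEVELS[contusion_idx[i]],
            pneumothorax=bool(pneumo[i]),
            haemothorax=bool(haemo[i]),
        )
        for i in range(n)
    ]
    sacts = np.array([sacts_score(f).total for f in findings])
    critical = rng.random(n) < params.outcome_model.p_critical(sacts)

    dispo_u = rng.random(n)
    vent_u = rng.random(n)

    def _pick(levels, probs, u):
        edges = np.cumsum(probs)
        return levels[int(np.searchsorted(edges, u, side="right"))]

    records = []
    for i in range(n):
        if critical[i]:
            dispo = _pick(*_CRITICAL_DISPO, dispo_u[i])
            p_vent = params.p_ventilated_given_critical
        else:
            dispo = _pick(*_NONCRITICAL_DISPO, dispo_u[i])
            p_vent = params.p_ventilated_given_noncritical
        records.append(
            PatientRecord(
                patient_id=f"sim-{i:05d}",
                age_years=int(ages[i]),
                sex=Sex.MALE if male[i] else Sex.FEMALE,
                mechanism=_MECHANISM_LEVELS[mech_idx[i]],
                ventilated=bool(vent_u[i] < p_vent),
                disposition=dispo,
                findings=findings[i],
            )
        )
    return records
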