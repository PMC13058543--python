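"""End-to-end orchestration: cohort in, reproduction report out.

``run_full_analysis`` ingests (or simulates) a cohort and produces every
analysis stage in one pass: the cohort summary table, the per-variable
exact association battery, the per-score outcome curves, the cutpoint
sweeps, and the dichotomized low/high score analysis.  ``render_report``
writes each stage as a CSV plus a plain-text summary and a checksum
manifest.  The rendering layer only formats numbers already computed by the
analysis modules; it never recomputes a statistic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    CohortSummary,
    PatientRecord,
    ValidationError,
    age_band,
    parse_cohort_csv,
    summarize_cohort,
)
from .cutpoints import CutpointSweep, cutpoint_sweep, dichotomize, score_outcome_curve, ScoreOutcomeCurve
from .exact import ExactTestResult, Table2x2, TableRxC, exact_test_2x2, fisher_rxc
from .scores import SCHEME_RANGES, Scheme, ZeroRibRule, score_cohort
from .simulate import CohortSimParams, generate_cohort

logger = logging.getLogger(__name__)

#: association battery: variable name -> ordered level extractor
_ASSOC_VARIABLES = (
    "sex",
    "ventilated",
    "age_band",
    "rib_band_coarse",
    "bilateral_rib_fractures",
    "contusion_grade",
    "pneumothorax",
    "haemothorax",
)

_ASSOC_LEVELS: dict[str, list[str]] = {
    "sex": ["male", "female"],
    "ventilated": ["no", "yes"],
    "age_band": ["<45", "45-65", ">65"],
    # the conventional "< 3 / 3-5 / > 5" banding used for association testing
    "rib_band_coarse": ["<3", "3-5", ">5"],
    "bilateral_rib_fractures": ["no", "yes"],
    "contusion_grade": [
        "none", "unilateral_minor", "bilateral_minor", "unilateral_major", "bilateral_major",
    ],
    "pneumothorax": ["no", "yes"],
    "haemothorax": ["no", "yes"],
}


def _assoc_level(record: PatientRecord, variable: str) -> str:
    f = record.findings
    match variable:
        case "sex":
            return record.sex.value
        case "ventilated":
            return "yes" if record.ventilated else "no"
        case "age_band":
            return age_band(record.age_years)
        case "rib_band_coarse":
            c = f.rib_fracture_count
            return "<3" if c < 3 else ("3-5" if c <= 5 else ">5")
        case "bilateral_rib_fractures":
            return "yes" if f.bilateral_rib_fractures else "no"
        case "contusion_grade":
            return f.contusion_grade.value
        case "pneumothorax":
            return "yes" if f.pneumothorax else "no"
        case "haemothorax":
            return "yes" if f.haemothorax else "no"
    raise KeyError(variable)


@dataclass(frozen=True)
class AssociationRow:
    """One variable's exact-test result against the binary outcome.

    2-level variables carry the full 2x2 result (p, conditional-MLE OR,
    exact CI); variables with three or more levels carry the r x 2 exact p
    only, matching how multi-level association tables are conventionally
    reported.
    """

    variable: str
    levels: list[str]
    counts: list[tuple[int, int]]  # per level: (n_non_critical, n_critical)
    p_two_sided: float
    result_2x2: ExactTestResult | None  # None for r > 2


@dataclass(frozen=True)
class AnalysisConfig:
    input_path: str | Path | None = None
    sim_params: CohortSimParams | None = None
    schemes: tuple[Scheme, ...] = (Scheme.CCTS, Scheme.SACTS)
    zero_rib_rule: ZeroRibRule = ZeroRibRule.TABLE2_LITERAL
    conf_level: float = 0.95
    candidate_cutoffs: dict[Scheme, list[int]] | None = None  # None = full range
    strict: bool = False

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.sim_params is None):
            raise ValidationError(
                "exactly one of input_path / sim_params must be provided"
            )
        if not 0.0 < self.conf_level < 1.0:
            raise ValidationError(f"conf_level must be in (0, 1), got {self.conf_level}")


@dataclass(frozen=True)
class SchemeAnalysis:
    scheme: Scheme
    scores: list[int]
    curve: ScoreOutcomeCurve
    sweep: CutpointSweep
    dichotomized_table: Table2x2
    dichotomized_result: ExactTestResult


@dataclass(frozen=True)
class ReproductionReport:
    n: int
    n_rejected: int
    summary: CohortSummary
    associations: list[AssociationRow]
    schemes: dict[Scheme, SchemeAnalysis]
    provenance: dict = field(default_factory=dict)


def association_battery(
    records: list[PatientRecord], conf_level: float = 0.95
) -> list[AssociationRow]:
    """Exact association test of each cohort variable against the outcome."""
    rows: list[AssociationRow] = []
    for variable in _ASSOC_VARIABLES:
        levels = _ASSOC_LEVELS[variable]
        counts = []
        for level in levels:
            in_level = [r for r in records if _assoc_level(r, variable) == level]
            n_crit = sum(r.outcome.value == "critical" for r in in_level)
            counts.append((len(in_level) - n_crit, n_crit))
        if len(levels) == 2:
            table = Table2x2.from_rows(counts)
            res = exact_test_2x2(table, conf_level)
            rows.append(AssociationRow(variable, levels, counts, res.p_two_sided, res))
        else:
            p = fisher_rxc(TableRxC.from_rows(counts))
            rows.append(AssociationRow(variable, levels, counts, p, None))
    return rows


def run_full_analysis(config: AnalysisConfig) -> ReproductionReport:
    """Ingest or simulate a cohort and run every analysis stage."""
    if config.input_path is not None:
        records, rejected = parse_cohort_csv(config.input_path, strict=config.strict)
        n_rejected = len(rejected)
        provenance = {"input": str(config.input_path), "rejected_rows": n_rejected}
        if n_rejected:
            logger.info("excluded %d row(s) failing validation", n_rejected)
    else:
        records = generate_cohort(config.sim_params)
        n_rejected = 0
        provenance = {
            "input": "simulated",
            "seed": config.sim_params.seed,
            "n": config.sim_params.n,
        }
    if not records:
        raise ValidationError("no valid records to analyse")
    provenance.update(
        {
            "version": __version__,
            "zero_rib_rule": ZeroRibRule(config.zero_rib_rule).value,
            "conf_level": config.conf_level,
        }
    )
    logger.info(
        "analysing %d records (conf_level=%s, zero_rib_rule=%s)",
        len(records), config.conf_level, ZeroRibRule(config.zero_rib_rule).value,
    )

    summary = summarize_cohort(records)
    associations = association_battery(records, config.conf_level)
    outcomes = [r.outcome for r in records]

    schemes: dict[Scheme, SchemeAnalysis] = {}
    for scheme in config.schemes:
        scheme = Scheme(scheme)
        totals = [s.total for s in score_cohort(records, scheme, config.zero_rib_rule)]
        lo, hi = SCHEME_RANGES[scheme]
        curve = score_outcome_curve(totals, outcomes, score_range=(lo, hi))
        if config.candidate_cutoffs and scheme in config.candidate_cutoffs:
            cands = config.candidate_cutoffs[scheme]
        else:
            cands = list(range(lo + 1, hi + 1))
        sweep = cutpoint_sweep(totals, outcomes, cands, config.conf_level)
        table = dichotomize(totals, sweep.selected_cutoff, outcomes)
        schemes[scheme] = SchemeAnalysis(
            scheme=scheme,
            scores=totals,
            curve=curve,
            sweep=sweep,
            dichotomized_table=table,
            dichotomized_result=exact_test_2x2(table, config.conf_level),
        )
    return ReproductionReport(
        n=len(records),
        n_rejected=n_rejected,
        summary=summary,
        associations=associations,
        schemes=schemes,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def format_p(p: float) -> str:
    """3 dp, switching to 3-significant-digit scientific notation below 0.001."""
    if p < 0.001:
        return f"{p:.2e}"
    return f"{p:.3f}"


def _fmt_or(v: float) -> str:
    return "inf" if math.isinf(v) else f"{v:.2f}"


def _summary_frame(summary: CohortSummary) -> pd.DataFrame:
    rows = []
    for variable, entries in summary.tables.items():
        for level, count, pct in entries:
            rows.append({"variable": variable, "level": level, "n": count, "percent": pct})
    return pd.DataFrame(rows)


def _association_frame(associations: list[AssociationRow]) -> pd.DataFrame:
    rows = []
    for assoc in associations:
        for i, (level, (n_noncrit, n_crit)) in enumerate(zip(assoc.levels, assoc.counts)):
            row = {
                "variable": assoc.variable,
                "level": level,
                "n_critical": n_crit,
                "n_non_critical": n_noncrit,
                "p": format_p(assoc.p_two_sided) if i == 0 else "",
                "significant": ("yes" if assoc.p_two_sided < 0.05 else "no") if i == 0 else "",
            }
            if i == 0 and assoc.result_2x2 is not None:
                row["odds_ratio"] = _fmt_or(assoc.result_2x2.or_cmle)
                row["ci_low"] = _fmt_or(assoc.result_2x2.ci_low)
                row["ci_high"] = _fmt_or(assoc.result_2x2.ci_high)
            else:
                row["odds_ratio"] = row["ci_low"] = row["ci_high"] = ""
            rows.append(row)
    return pd.DataFrame(rows)


def _curve_frame(curve: ScoreOutcomeCurve) -> pd.DataFrame:
    rows = []
    for score, (n_crit, n_noncrit) in sorted(curve.points.items()):
        total = n_crit + n_noncrit
        rows.append(
            {
                "score": score,
                "n_critical": n_crit,
                "n_non_critical": n_noncrit,
                "fraction_critical": round(n_crit / total, 4) if total else "",
            }
        )
    return pd.DataFrame(rows)


def _sweep_frame(sweep: CutpointSweep) -> pd.DataFrame:
    rows = []
    for cand in sweep.candidates:
        t = cand.table
        row = {
            "cutoff": cand.cutoff,
            "feasible": "yes" if cand.feasible else "no",
            "low_non_critical": t.a,
            "low_critical": t.b,
            "high_non_critical": t.c,
            "high_critical": t.d,
            "sensitivity": round(cand.sensitivity, 4),
            "specificity": round(cand.specificity, 4),
            "selected": "yes" if cand.cutoff == sweep.selected_cutoff else "no",
        }
        if cand.result is not None:
            row.update(
                p=format_p(cand.result.p_two_sided),
                odds_ratio=_fmt_or(cand.result.or_cmle),
                ci_low=_fmt_or(cand.result.ci_low),
                ci_high=_fmt_or(cand.result.ci_high),
            )
        else:
            row.update(p="", odds_ratio="", ci_low="", ci_high="")
        rows.append(row)
    return pd.DataFrame(rows)


def _dichotomized_frame(report: ReproductionReport) -> pd.DataFrame:
    rows = []
    for scheme, ana in report.schemes.items():
        t, res = ana.dichotomized_table, ana.dichotomized_result
        cut = ana.sweep.selected_cutoff
        rows.append(
            {
                "scheme": scheme.value,
                "category": f"low (<= {cut - 1})",
                "total": t.a + t.b,
                "n_critical": t.b,
                "n_non_critical": t.a,
                "p": format_p(res.p_two_sided),
                "ci_low": _fmt_or(res.ci_low),
                "ci_high": _fmt_or(res.ci_high),
                "odds_ratio": _fmt_or(res.or_cmle),
            }
        )
        rows.append(
            {
                "scheme": scheme.value,
                "category": f"high (>= {cut})",
                "total": t.c + t.d,
                "n_critical": t.d,
                "n_non_critical": t.c,
                "p": "", "ci_low": "", "ci_high": "", "odds_ratio": "",
            }
        )
    return pd.DataFrame(rows)


def render_report(report: ReproductionReport, outdir: str | Path) -> dict[str, str]:
    """Write the report as CSVs + summary text; return {filename: sha256}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    files: dict[str, pd.DataFrame] = {
        "cohort_summary.csv": _summary_frame(report.summary),
        "associations.csv": _association_frame(report.associations),
        "dichotomized.csv": _dichotomized_frame(report),
    }
    for scheme, ana in report.schemes.items():
        files[f"curve_{scheme.value}.csv"] = _curve_frame(ana.curve)
        files[f"cutpoint_sweep_{scheme.value}.csv"] = _sweep_frame(ana.sweep)

    manifest: dict[str, str] = {}
    for name, frame in files.items():
        path = outdir / name
        frame.to_csv(path, index=False)
        manifest[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    lines = [
        f"sacts-kit {report.provenance.get('version', '')} reproduction report",
        f"cohort: n = {report.n} ({report.n_rejected} rejected rows)",
        f"provenance: {json.dumps(report.provenance, sort_keys=True)}",
        "",
        "associations (p < 0.05 flagged *):",
    ]
    for assoc in report.associations:
        flag = "*" if assoc.p_two_sided < 0.05 else " "
        or_txt = (
            f"  OR {_fmt_or(assoc.result_2x2.or_cmle)}"
            f" [{_fmt_or(assoc.result_2x2.ci_low)}, {_fmt_or(assoc.result_2x2.ci_high)}]"
            if assoc.result_2x2 is not None else ""
        )
        lines.append(f"  {flag} {assoc.variable}: p = {format_p(assoc.p_two_sided)}{or_txt}")
    lines.append("")
    for scheme, ana in report.schemes.items():
        res = ana.dichotomized_result
        lines.append(
            f"{scheme.value}: selected cutoff >= {ana.sweep.selected_cutoff}; "
            f"OR {_fmt_or(res.or_cmle)} [{_fmt_or(res.ci_low)}, {_fmt_or(res.ci_high)}], "
            f"p = {format_p(res.p_two_sided)}"
        )
    summary_path = outdir / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    manifest["summary.txt"] = hashlib.sha256(summary_path.read_bytes()).hexdigest()

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
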