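"""End-to-end evaluation pipeline and report rendering.

``run_audit`` ties the modules together: load or generate a cohort,
apply the exclusion filter, compute the Sepsis-3 reference labels, run
every screen, and emit the performance tables (one column per screen),
the paired McNemar comparisons, the triage audit summary and the
missingness accounting, as CSV plus a Markdown summary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import audit as audit_mod
from .audit import ReviewSelection, TriageAuditSummary
from .cohort_io import (
    EncounterRecord,
    ExclusionReport,
    apply_exclusions,
    read_cohort,
    write_cohort,
)
from .diagnostics import (
    Estimate,
    McNemarResult,
    PerformanceReport,
    Stratum,
    TwoByTwo,
    confusion_table,
    correctly_triaged,
    mcnemar_paired,
    performance,
    round_half_up,
)
from .reference_labels import SepsisLabel, sepsis3_label
from .screening_rules import (
    DEFAULT_THRESHOLDS,
    MissingPolicy,
    MtsPositivity,
    RecordScreens,
    RuleThresholds,
    screen_record,
)
from .synthetic_data import (
    ReplayMargins,
    SimulationParams,
    replay_cohort,
    simulate_cohort,
    study_margins,
)

__all__ = ["RunConfig", "EvaluationResult", "evaluate_cohort", "run_audit"]

SCREEN_NAMES = ("mts", "sirs", "combined")


@dataclass(frozen=True)
class RunConfig:
    """One audit run: exactly one input source plus analysis options."""

    input_path: Optional[str] = None
    mode: str = "replay"                      # replay | simulate | load
    seed: int = 0
    params: Optional[SimulationParams] = None
    margins: Optional[ReplayMargins] = None
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS
    policy: MissingPolicy = MissingPolicy.MISSING_NORMAL
    positivity: MtsPositivity = MtsPositivity.ALERT_ONLY
    ci_level: float = 0.95
    shock_lactate_mmol_l: float = 2.0
    out_dir: Optional[str] = None
    include_excluded: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.mode not in ("replay", "simulate", "load"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "load" and not self.input_path:
            raise ValueError("mode 'load' requires input_path")
        if self.mode != "load" and self.input_path:
            raise ValueError("exactly one input source: either a file or a generator")


@dataclass(frozen=True)
class EvaluationResult:
    exclusions: ExclusionReport
    tables: Mapping[str, TwoByTwo]
    reports: Mapping[str, PerformanceReport]
    mcnemar: Mapping[str, McNemarResult]
    correct_triage: Estimate
    audit_summary: TriageAuditSummary
    review: ReviewSelection
    missingness: Mapping[str, int]
    n_alerts: int
    labels: Sequence[SepsisLabel] = field(repr=False)
    screens: Sequence[RecordScreens] = field(repr=False)


def evaluate_cohort(
    records: Sequence[EncounterRecord],
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
    policy: MissingPolicy = MissingPolicy.MISSING_NORMAL,
    positivity: MtsPositivity = MtsPositivity.ALERT_ONLY,
    ci_level: float = 0.95,
    shock_lactate_mmol_l: float = 2.0,
) -> EvaluationResult:
    """Run the full audit on an already-loaded cohort.

    Applies the exclusion filter first; indeterminate screen results are
    resolved to negative (the production behaviour) before the
    contingency tables are formed.
    """
    retained, exclusions = apply_exclusions(records)
    if not retained:
        raise ValueError("cohort is empty after exclusions")
    labels = [sepsis3_label(r, shock_lactate_mmol_l) for r in retained]
    screens = [screen_record(r, thresholds, policy, positivity) for r in retained]

    truth = [lab.sepsis for lab in labels]
    flags = {
        "mts": [s.mts_alert for s in screens],
        "sirs": [s.sirs_alert_fired for s in screens],
        "combined": [s.combined for s in screens],
    }
    tables = {name: confusion_table(flags[name], truth) for name in SCREEN_NAMES}
    reports = {name: performance(tables[name], ci_level) for name in SCREEN_NAMES}
    mcnemar = {
        "combined_vs_mts_sensitivity": mcnemar_paired(
            flags["combined"], flags["mts"], truth, Stratum.DISEASED
        ),
        "combined_vs_mts_specificity": mcnemar_paired(
            flags["combined"], flags["mts"], truth, Stratum.NON_DISEASED
        ),
        "sirs_vs_mts_sensitivity": mcnemar_paired(
            flags["sirs"], flags["mts"], truth, Stratum.DISEASED
        ),
        "sirs_vs_mts_specificity": mcnemar_paired(
            flags["sirs"], flags["mts"], truth, Stratum.NON_DISEASED
        ),
    }
    return EvaluationResult(
        exclusions=exclusions,
        tables=tables,
        reports=reports,
        mcnemar=mcnemar,
        correct_triage=correctly_triaged(retained, labels, ci_level),
        audit_summary=audit_mod.triage_audit_summary(retained, thresholds, policy),
        review=audit_mod.select_for_review(retained, labels, screens),
        missingness=audit_mod.missingness_report(retained, thresholds),
        n_alerts=tables["combined"].positives,
        labels=labels,
        screens=screens,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _fmt_pct(est: Estimate) -> str:
    if not est.defined:
        return "undefined"
    return f"{round_half_up(100 * est.value, 1)}%"


def _fmt_pct_ci(est: Estimate) -> str:
    if est.ci is None:
        return ""
    return (
        f"{round_half_up(100 * est.ci.lower, 1)} to "
        f"{round_half_up(100 * est.ci.upper, 1)}%"
    )


def _fmt_num(est: Estimate, ndigits: int) -> str:
    if not est.defined:
        return "undefined"
    return f"{round_half_up(est.value, ndigits):.{ndigits}f}"


def _fmt_num_ci(est: Estimate, ndigits: int) -> str:
    if est.ci is None:
        return ""
    return (
        f"{round_half_up(est.ci.lower, ndigits):.{ndigits}f} to "
        f"{round_half_up(est.ci.upper, ndigits):.{ndigits}f}"
    )


_MEASURE_ROWS = (
    ("Sensitivity", "sensitivity", "pct"),
    ("Specificity", "specificity", "pct"),
    ("AUC", "auc", 2),
    ("Positive likelihood ratio", "lr_pos", 1),
    ("Negative likelihood ratio", "lr_neg", 2),
    ("Positive predictive value", "ppv", "pct"),
    ("Negative predictive value", "npv", "pct"),
    ("Accuracy", "accuracy", "pct"),
)

_SCREEN_TITLES = {
    "mts": "MTS possible sepsis",
    "sirs": "SIRS-based system",
    "combined": "MTS plus SIRS-based system",
}


def performance_table_rows(result: EvaluationResult) -> list[dict[str, str]]:
    """Rows of the performance table: one measure per row, one screen per
    column pair (estimate, 95% CI), mirroring the conventional layout."""
    rows = []
    for title, attr, kind in _MEASURE_ROWS:
        row = {"measure": title}
        for name in SCREEN_NAMES:
            est: Estimate = getattr(result.reports[name], attr)
            if kind == "pct":
                row[name] = _fmt_pct(est)
                row[f"{name}_ci"] = _fmt_pct_ci(est)
            else:
                row[name] = _fmt_num(est, kind)
                row[f"{name}_ci"] = _fmt_num_ci(est, kind)
        rows.append(row)
    return rows


def counts_table_rows(result: EvaluationResult) -> list[dict[str, object]]:
    rows = []
    for name in SCREEN_NAMES:
        t = result.tables[name]
        rows.append(
            {
                "screen": _SCREEN_TITLES[name],
                "tp": t.tp,
                "fp": t.fp,
                "fn": t.fn,
                "tn": t.tn,
                "positives": t.positives,
                "total": t.total,
            }
        )
    return rows


def _csv_text(rows: list[dict]) -> str:
    import csv as _csv

    buf = io.StringIO()
    writer = _csv.DictWriter(buf, fieldnames=list(rows[0]), lineterminator="\n")
    writer.writeheader()
    writer.writerows(rows)
    return buf.getvalue()


def render_markdown(result: EvaluationResult) -> str:
    """Human-readable Markdown report of the whole audit."""
    out = io.StringIO()
    ex = result.exclusions
    prev = result.reports["mts"].prevalence
    out.write("# Sepsis screening audit\n\n")
    out.write(
        f"Cohort: {ex.n_input} encounters, {ex.n_blue_excluded} blue and "
        f"{ex.n_palliative_excluded} palliative excluded, {ex.n_retained} analysed.\n"
    )
    n_sepsis = result.tables["mts"].diseased
    out.write(
        f"Sepsis-3 reference: {n_sepsis} cases "
        f"({_fmt_pct(prev)} prevalence); {result.n_alerts} digital sepsis alerts.\n\n"
    )

    out.write("## Performance\n\n")
    headers = ["Measure"]
    for name in SCREEN_NAMES:
        headers += [_SCREEN_TITLES[name], "95% CI"]
    out.write("| " + " | ".join(headers) + " |\n")
    out.write("|" + "---|" * len(headers) + "\n")
    for row in performance_table_rows(result):
        cells = [row["measure"]]
        for name in SCREEN_NAMES:
            cells += [row[name], row[f"{name}_ci"]]
        out.write("| " + " | ".join(cells) + " |\n")

    out.write("\n## Contingency tables\n\n")
    out.write("| Screen | TP | FP | FN | TN | Alerts |\n|---|---|---|---|---|---|\n")
    for row in counts_table_rows(result):
        out.write(
            f"| {row['screen']} | {row['tp']} | {row['fp']} | {row['fn']} | "
            f"{row['tn']} | {row['positives']} |\n"
        )

    out.write("\n## Paired comparisons (exact McNemar)\n\n")
    for name, res in result.mcnemar.items():
        out.write(
            f"- {name}: b={res.b}, c={res.c}, "
            f"p={'<0.0001' if res.p_value < 1e-4 else format(res.p_value, '.4g')}\n"
        )

    a = result.audit_summary
    out.write("\n## Triage audit\n\n")
    out.write(
        f"- Correctly triaged sepsis (red/orange/possible sepsis): "
        f"{_fmt_pct(result.correct_triage)} ({_fmt_pct_ci(result.correct_triage)})\n"
    )
    out.write(
        f"- Possible-sepsis assignments: {a.n_possible_sepsis_assigned}; "
        f"without any qSOFA criterion (overtriage): {a.n_overtriaged}"
    )
    if a.overtriage_proportion is not None:
        out.write(f" ({round_half_up(100 * a.overtriage_proportion, 1)}%)")
    out.write("\n")
    out.write(
        f"- Suspected new infection: {a.n_suspected_infection}; with criteria but "
        f"not assigned (undertriage): {a.n_undertriaged}\n"
    )
    out.write(f"- Charts flagged for review: {len(result.review.selected_ids)}\n")

    out.write("\n## Missingness\n\n")
    for fname, count in sorted(result.missingness.items()):
        out.write(f"- {fname}: {count}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def load_or_generate(config: RunConfig) -> list[EncounterRecord]:
    if config.mode == "load":
        return read_cohort(config.input_path)
    if config.mode == "replay":
        margins = config.margins if config.margins is not None else study_margins()
        return replay_cohort(margins, config.seed, config.include_excluded)
    params = config.params if config.params is not None else SimulationParams()
    return simulate_cohort(params, config.seed)


def run_audit(config: RunConfig) -> EvaluationResult:
    """Run the whole pipeline per ``config``; write the report bundle when
    ``config.out_dir`` is set.  Deterministic given the seed."""
    records = load_or_generate(config)
    result = evaluate_cohort(
        records,
        thresholds=config.thresholds,
        policy=config.policy,
        positivity=config.positivity,
        ci_level=config.ci_level,
        shock_lactate_mmol_l=config.shock_lactate_mmol_l,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "performance.csv").write_text(_csv_text(performance_table_rows(result)))
        (out / "counts.csv").write_text(_csv_text(counts_table_rows(result)))
        review_rows = [
            {"criterion": name, "count": count}
            for name, count in result.review.per_criterion_counts.items()
        ]
        (out / "review_selection.csv").write_text(_csv_text(review_rows))
        ex = result.exclusions
        (out / "exclusions.csv").write_text(
            _csv_text(
                [
                    {
                        "n_input": ex.n_input,
                        "n_blue_excluded": ex.n_blue_excluded,
                        "n_palliative_excluded": ex.n_palliative_excluded,
                        "n_retained": ex.n_retained,
                    }
                ]
            )
        )
        (out / "report.md").write_text(render_markdown(result))
        write_cohort(records, out / "cohort.csv")
    return result
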