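"""Triage-audit procedures: chart-review selection, over/undertriage,
inter-rater weighted kappa, and missingness accounting.

Overtriage means the nurse assigned the possible-sepsis category although
no qSOFA criterion was met; undertriage means a patient with nurse-
documented suspicion of infection met one or more qSOFA criteria yet was
not assigned to possible sepsis.  Both are judged against the recorded
vitals under the configured missing-data policy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort_io import EncounterRecord, TriageCategory
from .reference_labels import SepsisLabel
from .screening_rules import (
    DEFAULT_THRESHOLDS,
    MissingPolicy,
    RecordScreens,
    RuleThresholds,
    qsofa_score,
)

__all__ = [
    "ReviewSelection",
    "TriageAuditSummary",
    "REVIEW_CRITERIA",
    "select_for_review",
    "triage_audit_summary",
    "overtriage_summary",
    "undertriage_summary",
    "weighted_kappa",
    "missingness_report",
]

#: Names of the nine chart-review selection criteria, in reporting order.
REVIEW_CRITERIA: tuple[str, ...] = (
    "mts_possible_sepsis",
    "news_gt_5",
    "suspicion_documented",
    "qsofa_ge_1",
    "sirs_screen_positive",
    "mts_red",
    "blood_cultures",
    "icu_within_72h",
    "died_in_hospital",
)


@dataclass(frozen=True)
class ReviewSelection:
    """Records flagged for manual chart review (union of nine criteria)."""

    selected_ids: frozenset[str]
    per_criterion_counts: Mapping[str, int]


@dataclass(frozen=True)
class TriageAuditSummary:
    n_possible_sepsis_assigned: int
    n_overtriaged: int            # assigned, zero qSOFA criteria
    n_suspected_infection: int
    n_undertriaged: int           # suspected, >=1 criterion, not assigned

    def __post_init__(self) -> None:
        if self.n_overtriaged > self.n_possible_sepsis_assigned:
            raise ValueError("overtriaged count exceeds assignments")
        if self.n_undertriaged > self.n_suspected_infection:
            raise ValueError("undertriaged count exceeds suspected-infection count")

    @property
    def overtriage_proportion(self) -> Optional[float]:
        if self.n_possible_sepsis_assigned == 0:
            return None
        return self.n_overtriaged / self.n_possible_sepsis_assigned


def select_for_review(
    records: Sequence[EncounterRecord],
    labels: Sequence[SepsisLabel],
    screens: Sequence[RecordScreens],
) -> ReviewSelection:
    """Flag every record meeting at least one of the nine review criteria.

    A record is selected once however many criteria it meets; the
    per-criterion tallies overlap by design.
    """
    if not (len(records) == len(labels) == len(screens)):
        raise ValueError("records, labels and screens must align")
    counts: Counter[str] = Counter({name: 0 for name in REVIEW_CRITERIA})
    selected: set[str] = set()
    for rec, scr in zip(records, screens):
        met = {
            "mts_possible_sepsis": rec.triage_category is TriageCategory.POSSIBLE_SEPSIS,
            "news_gt_5": scr.news2.value > 5,
            "suspicion_documented": rec.suspicion_new_infection is True,
            "qsofa_ge_1": scr.qsofa.value >= 1,
            "sirs_screen_positive": scr.sirs_alert_fired,
            "mts_red": rec.triage_category is TriageCategory.RED,
            "blood_cultures": rec.blood_cultures_ordered,
            "icu_within_72h": rec.icu_within_72h,
            "died_in_hospital": rec.died_in_hospital,
        }
        if any(met.values()):
            selected.add(rec.encounter_id)
        for name, hit in met.items():
            if hit:
                counts[name] += 1
    return ReviewSelection(
        selected_ids=frozenset(selected), per_criterion_counts=dict(counts)
    )


def triage_audit_summary(
    records: Sequence[EncounterRecord],
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
    policy: MissingPolicy = MissingPolicy.MISSING_NORMAL,
) -> TriageAuditSummary:
    """Quantify over- and undertriage of the possible-sepsis discriminator."""
    n_assigned = n_over = n_suspected = n_under = 0
    for rec in records:
        q = qsofa_score(rec.vitals, policy, thresholds)
        assigned = rec.triage_category is TriageCategory.POSSIBLE_SEPSIS
        if assigned:
            n_assigned += 1
            if q.value == 0:
                n_over += 1
        if rec.suspicion_new_infection is True:
            n_suspected += 1
            if q.value >= 1 and not assigned:
                n_under += 1
    return TriageAuditSummary(
        n_possible_sepsis_assigned=n_assigned,
        n_overtriaged=n_over,
        n_suspected_infection=n_suspected,
        n_undertriaged=n_under,
    )


def overtriage_summary(
    records: Sequence[EncounterRecord],
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
    policy: MissingPolicy = MissingPolicy.MISSING_NORMAL,
) -> TriageAuditSummary:
    """Assignments to possible sepsis with zero qSOFA criteria."""
    return triage_audit_summary(records, thresholds, policy)


def undertriage_summary(
    records: Sequence[EncounterRecord],
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
    policy: MissingPolicy = MissingPolicy.MISSING_NORMAL,
) -> TriageAuditSummary:
    """Suspected-infection patients with criteria but no assignment."""
    return triage_audit_summary(records, thresholds, policy)


def weighted_kappa(
    ratings_a: Sequence,
    ratings_b: Sequence,
    weights: str = "linear",
    categories: Optional[Sequence] = None,
) -> float:
    """Chance-corrected ordinal agreement between two raters.

    kappa = 1 - sum(w * O) / sum(w * E) with disagreement weights
    ``w[i, j] = |i - j|`` (linear) or ``(i - j)**2`` (quadratic) over the
    shared ordered category set; O is the observed contingency table and
    E its independence expectation.  Perfect agreement gives 1; with two
    categories the quadratic and unweighted statistics coincide.
    """
    if len(ratings_a) != len(ratings_b):
        raise ValueError("rating vectors must have equal length")
    if len(ratings_a) == 0:
        raise ValueError("rating vectors are empty")
    if categories is None:
        categories = sorted(set(ratings_a) | set(ratings_b))
    index = {cat: i for i, cat in enumerate(categories)}
    k = len(categories)
    observed = np.zeros((k, k))
    for a, b in zip(ratings_a, ratings_b):
        observed[index[a], index[b]] += 1
    n = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / n
    distance = np.abs(np.subtract.outer(np.arange(k), np.arange(k))).astype(float)
    if weights == "quadratic":
        w = distance**2
    elif weights == "linear":
        w = distance
    else:
        raise ValueError("weights must be 'linear' or 'quadratic'")
    denom = float((w * expected).sum())
    if denom == 0.0:
        return 1.0  # a single category in use: agreement is trivially perfect
    return 1.0 - float((w * observed).sum()) / denom


def missingness_report(
    records: Sequence[EncounterRecord],
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> dict[str, int]:
    """Per-field absent counts plus the strict-policy qSOFA accounting.

    ``mental_status`` counts records with neither a GCS nor an answered
    altered-mental checkbox; ``qsofa_indeterminate_strict`` counts records
    whose qSOFA score cannot be computed when missing data are not
    assumed normal.
    """
    counts = Counter(
        {
            "temp_c": 0,
            "heart_rate": 0,
            "resp_rate": 0,
            "sbp": 0,
            "gcs": 0,
            "spo2": 0,
            "mental_status": 0,
            "suspicion_new_infection": 0,
            "qsofa_indeterminate_strict": 0,
        }
    )
    for rec in records:
        v = rec.vitals
        for name in ("temp_c", "heart_rate", "resp_rate", "sbp", "gcs", "spo2"):
            if getattr(v, name) is None:
                counts[name] += 1
        if v.gcs is None and v.altered_mental_checkbox is None:
            counts["mental_status"] += 1
        if rec.suspicion_new_infection is None:
            counts["suspicion_new_infection"] += 1
        if qsofa_score(v, MissingPolicy.STRICT, thresholds).indeterminate:
            counts["qsofa_indeterminate_strict"] += 1
    return dict(counts)
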