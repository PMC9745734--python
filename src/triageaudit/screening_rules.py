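"""Deterministic triage screening rules.

Implements the scorers and alert rules audited in this package:

* ``qsofa_score`` — quick SOFA (RR >= 22 /min, SBP < 100 mmHg, GCS < 15);
* ``sirs_count`` — the local 3-item SIRS variant used by the digital
  screening form (temperature < 36 or > 38 degrees C, HR > 90 bpm,
  RR > 20 /min; strict inequalities, no white-cell criterion);
* ``news2_score`` — National Early Warning Score 2, scale-1 bands;
* ``mts_possible_sepsis_rule`` — the MTS possible-sepsis discriminator
  (>= 1 qSOFA criterion);
* ``sirs_alert`` — the EHR digital alert: nurse-suspected new infection
  AND (altered mental state checkbox OR >= 2 SIRS criteria);
* ``combined_alert`` — the union of the MTS and SIRS alert sources.

All scorers are pure functions of the vitals and return a
:class:`ScreenResult` carrying the score, which criteria were met, which
inputs were absent, and whether the result is indeterminate under the
strict missing-data policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Union

from .cohort_io import Avpu, EncounterRecord, TriageCategory, Vitals

__all__ = [
    "RuleThresholds",
    "DEFAULT_THRESHOLDS",
    "MissingPolicy",
    "MtsPositivity",
    "ScreenResult",
    "RecordScreens",
    "qsofa_score",
    "sirs_count",
    "news2_score",
    "mts_possible_sepsis_rule",
    "sirs_alert",
    "combined_alert",
    "mts_category_positive",
    "screen_record",
]


@dataclass(frozen=True)
class RuleThresholds:
    """Cut-offs of the screening rules.

    qSOFA comparisons are RR inclusive (>=) and SBP/GCS strict (<); the
    SIRS comparisons are all strict ("less than 36 / more than 38 / more
    than 90 / more than 20"), so 36.0, 38.0, 90 and 20 do *not* meet
    their criterion.
    """

    qsofa_rr_min: float = 22.0                # breaths/min, inclusive
    qsofa_sbp_max_exclusive: float = 100.0    # mmHg
    qsofa_gcs_max_exclusive: int = 15
    sirs_temp_low_exclusive: float = 36.0     # degrees C
    sirs_temp_high_exclusive: float = 38.0    # degrees C
    sirs_hr_exclusive: float = 90.0           # beats/min
    sirs_rr_exclusive: float = 20.0           # breaths/min

    def __post_init__(self) -> None:
        for name in (
            "qsofa_rr_min",
            "qsofa_sbp_max_exclusive",
            "qsofa_gcs_max_exclusive",
            "sirs_temp_low_exclusive",
            "sirs_temp_high_exclusive",
            "sirs_hr_exclusive",
            "sirs_rr_exclusive",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sirs_temp_low_exclusive >= self.sirs_temp_high_exclusive:
            raise ValueError("SIRS temperature bounds must satisfy low < high")


DEFAULT_THRESHOLDS = RuleThresholds()


class MissingPolicy(str, Enum):
    """How an absent vital affects a rule.

    ``missing_normal`` (the production system's behaviour and the default)
    treats an absent input as *criterion not met*.  ``strict`` marks a
    result indeterminate whenever a deciding input is absent, which is the
    accounting used to report how many encounters render qSOFA
    incomputable.
    """

    MISSING_NORMAL = "missing_normal"
    STRICT = "strict"


class MtsPositivity(str, Enum):
    """What counts as an MTS screen positive when evaluating the cohort.

    ``alert_only``: the nurse assigned the dedicated possible-sepsis
    category (the assignment that actually fires the digital alert).
    ``possible_sepsis_or_red``: possible-sepsis or red.
    """

    ALERT_ONLY = "alert_only"
    POSSIBLE_SEPSIS_OR_RED = "possible_sepsis_or_red"


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of one screening rule on one encounter."""

    value: Union[int, bool]
    criteria_met: frozenset[str]
    indeterminate: bool = False
    missing_inputs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.indeterminate and not self.missing_inputs:
            raise ValueError("indeterminate result must name its missing inputs")


def _mental_status(v: Vitals, gcs_bound: int):
    """qSOFA altered-mentation criterion: GCS preferred, checkbox fallback.

    Returns (met, missing): ``met`` is None when undecidable.
    """
    if v.gcs is not None:
        return v.gcs < gcs_bound, False
    if v.altered_mental_checkbox is not None:
        return bool(v.altered_mental_checkbox), False
    return None, True


def qsofa_score(
    v: Vitals,
    policy: MissingPolicy = MissingPolicy.MISSING_NORMAL,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> ScreenResult:
    """Count met qSOFA criteria (0-3).

    ``value`` is the number of *definitely* met criteria; under
    ``policy="strict"`` any absent deciding input marks the result
    indeterminate, under ``missing_normal`` absent inputs simply do not
    meet their criterion.
    """
    met: set[str] = set()
    missing: set[str] = set()

    if v.resp_rate is None:
        missing.add("resp_rate")
    elif v.resp_rate >= thresholds.qsofa_rr_min:
        met.add("resp_rate")

    if v.sbp is None:
        missing.add("sbp")
    elif v.sbp < thresholds.qsofa_sbp_max_exclusive:
        met.add("sbp")

    mental_met, mental_missing = _mental_status(v, thresholds.qsofa_gcs_max_exclusive)
    if mental_missing:
        missing.add("mental_status")
    elif mental_met:
        met.add("mental_status")

    indeterminate = policy is MissingPolicy.STRICT and bool(missing)
    return ScreenResult(
        value=len(met),
        criteria_met=frozenset(met),
        indeterminate=indeterminate,
        missing_inputs=frozenset(missing),
    )


def sirs_count(
    v: Vitals,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> ScreenResult:
    """Count met SIRS criteria (0-3) of the local 3-item variant.

    All comparisons strict; a missing vital never meets its criterion
    (the production alert fires on entered values only) but is listed in
    ``missing_inputs``.
    """
    met: set[str] = set()
    missing: set[str] = set()

    if v.temp_c is None:
        missing.add("temp_c")
    elif (
        v.temp_c < thresholds.sirs_temp_low_exclusive
        or v.temp_c > thresholds.sirs_temp_high_exclusive
    ):
        met.add("temperature")

    if v.heart_rate is None:
        missing.add("heart_rate")
    elif v.heart_rate > thresholds.sirs_hr_exclusive:
        met.add("heart_rate")

    if v.resp_rate is None:
        missing.add("resp_rate")
    elif v.resp_rate > thresholds.sirs_rr_exclusive:
        met.add("resp_rate")

    return ScreenResult(
        value=len(met),
        criteria_met=frozenset(met),
        indeterminate=False,
        missing_inputs=frozenset(missing),
    )


# NEWS2 scale-1 bands (Royal College of Physicians chart); each entry is
# (upper_bound_inclusive, points) scanned in order, last entry catches all.
_NEWS2_BANDS = {
    "resp_rate": ((8, 3), (11, 1), (20, 0), (24, 2), (float("inf"), 3)),
    "spo2": ((91, 3), (93, 2), (95, 1), (float("inf"), 0)),
    "temp_c": ((35.0, 3), (36.0, 1), (38.0, 0), (39.0, 1), (float("inf"), 2)),
    "sbp": ((90, 3), (100, 2), (110, 1), (219, 0), (float("inf"), 3)),
    "heart_rate": ((40, 3), (50, 1), (90, 0), (110, 1), (130, 2), (float("inf"), 3)),
}


def _news2_band_points(component: str, value: float) -> int:
    for bound, points in _NEWS2_BANDS[component]:
        if value <= bound:
            return points
    raise AssertionError("unreachable")


def news2_score(v: Vitals) -> ScreenResult:
    """NEWS2 aggregate score, scale-1 oxygen-saturation bands.

    Components: respiratory rate, SpO2, supplemental oxygen (2 points when
    in use), temperature, systolic blood pressure, heart rate, and
    consciousness (anything other than Alert on the AVPU scale, or the
    altered-mental checkbox when AVPU is unrecorded, scores 3).  Missing
    components contribute 0 points and are listed in ``missing_inputs``.
    """
    total = 0
    met: set[str] = set()
    missing: set[str] = set()

    for component in ("resp_rate", "spo2", "temp_c", "sbp", "heart_rate"):
        value = getattr(v, component)
        if value is None:
            missing.add(component)
            continue
        points = _news2_band_points(component, value)
        total += points
        if points > 0:
            met.add(component)

    if v.supplemental_o2 is None:
        missing.add("supplemental_o2")
    elif v.supplemental_o2:
        total += 2
        met.add("supplemental_o2")

    if v.avpu is not None:
        conscious_points = 0 if v.avpu is Avpu.ALERT else 3
    elif v.altered_mental_checkbox is not None:
        conscious_points = 3 if v.altered_mental_checkbox else 0
    else:
        conscious_points = 0
        missing.add("consciousness")
    total += conscious_points
    if conscious_points:
        met.add("consciousness")

    return ScreenResult(
        value=total,
        criteria_met=frozenset(met),
        indeterminate=False,
        missing_inputs=frozenset(missing),
    )


def mts_possible_sepsis_rule(
    v: Vitals,
    policy: MissingPolicy = MissingPolicy.MISSING_NORMAL,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> ScreenResult:
    """The MTS possible-sepsis discriminator: >= 1 qSOFA criterion.

    If at least one criterion is definitely met the rule is positive
    regardless of missing inputs.  With zero definite criteria and absent
    deciding inputs the result is indeterminate under the strict policy
    (the count could cross 1 only via the missing data); under
    ``missing_normal`` it is negative.
    """
    q = qsofa_score(v, policy=MissingPolicy.MISSING_NORMAL, thresholds=thresholds)
    positive = q.value >= 1
    indeterminate = (
        not positive and policy is MissingPolicy.STRICT and bool(q.missing_inputs)
    )
    return ScreenResult(
        value=positive,
        criteria_met=q.criteria_met,
        indeterminate=indeterminate,
        missing_inputs=q.missing_inputs,
    )


def sirs_alert(
    suspicion: Optional[bool],
    altered_mental: Optional[bool],
    sirs: ScreenResult,
) -> bool:
    """The EHR digital sepsis alert of the SIRS-based form.

    Fires only when the nurse recorded suspicion of a *new* infection, in
    combination with an altered mental state (separate checkbox) or two or
    more SIRS criteria.  Absent checkboxes count as unchecked.
    """
    return bool(suspicion) and (bool(altered_mental) or sirs.value >= 2)


def combined_alert(mts_positive: bool, sirs_positive: bool) -> bool:
    """Union of the two alert sources (the digital patient-overview alert)."""
    return bool(mts_positive) or bool(sirs_positive)


def mts_category_positive(
    category: TriageCategory,
    positivity: MtsPositivity = MtsPositivity.ALERT_ONLY,
) -> bool:
    """Whether the nurse-assigned category counts as an MTS screen positive."""
    if positivity is MtsPositivity.ALERT_ONLY:
        return category is TriageCategory.POSSIBLE_SEPSIS
    return category in (TriageCategory.POSSIBLE_SEPSIS, TriageCategory.RED)


@dataclass(frozen=True)
class RecordScreens:
    """All screen outcomes for one encounter."""

    qsofa: ScreenResult
    sirs: ScreenResult
    news2: ScreenResult
    mts_rule: ScreenResult        # what the discriminator *should* say
    mts_alert: bool               # what the nurse actually assigned
    sirs_alert_fired: bool
    combined: bool


def screen_record(
    rec: EncounterRecord,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
    policy: MissingPolicy = MissingPolicy.MISSING_NORMAL,
    positivity: MtsPositivity = MtsPositivity.ALERT_ONLY,
) -> RecordScreens:
    """Run every screen on one encounter.

    The MTS *alert* is the nurse-assigned category (vitals were not
    cross-checked by the audited software), while ``mts_rule`` is what the
    qSOFA-based discriminator itself would say for the recorded vitals.
    """
    v = rec.vitals
    sirs = sirs_count(v, thresholds)
    fired = sirs_alert(rec.suspicion_new_infection, v.altered_mental_checkbox, sirs)
    mts = mts_category_positive(rec.triage_category, positivity)
    return RecordScreens(
        qsofa=qsofa_score(v, policy, thresholds),
        sirs=sirs,
        news2=news2_score(v),
        mts_rule=mts_possible_sepsis_rule(v, policy, thresholds),
        mts_alert=mts,
        sirs_alert_fired=fired,
        combined=combined_alert(mts, fired),
    )
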