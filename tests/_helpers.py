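"""Shared builders for test cohorts."""

from __future__ import annotations

from triageaudit.cohort_io import EncounterRecord, TriageCategory, Vitals
from triageaudit.synthetic_data import ReplayMargins, StratumCells


def make_vitals(**kw) -> Vitals:
    """Fully normal, fully present vitals unless overridden."""
    base = dict(
        temp_c=37.0,
        heart_rate=70.0,
        resp_rate=14.0,
        sbp=120.0,
        gcs=15,
        avpu="A",
        spo2=98.0,
        supplemental_o2=False,
        altered_mental_checkbox=False,
    )
    base.update(kw)
    if isinstance(base.get("avpu"), str):
        from triageaudit.cohort_io import Avpu

        base["avpu"] = Avpu(base["avpu"])
    return Vitals(**base)


_COUNTER = [0]


def make_record(
    category: TriageCategory | str = TriageCategory.GREEN,
    vitals: Vitals | None = None,
    **kw,
) -> EncounterRecord:
    _COUNTER[0] += 1
    return EncounterRecord(
        encounter_id=kw.pop("encounter_id", f"T{_COUNTER[0]:05d}"),
        triage_category=TriageCategory(category),
        vitals=vitals if vitals is not None else make_vitals(),
        **kw,
    )


def small_margins() -> ReplayMargins:
    """A compact, fully consistent set of replay margins for fast tests."""
    return ReplayMargins(
        sepsis=StratumCells(both=2, mts_only=1, sirs_only=1, neither=3),
        non_sepsis=StratumCells(both=3, mts_only=2, sirs_only=4, neither=30),
        n_septic_shock=1,
        n_suspicion_total=12,
        n_altered_mental_checked=2,
        n_overtriaged=4,
        n_undertriaged=1,
        missing_sbp=1,
        missing_mental_status=1,
        missing_temp=1,
        sepsis_category_counts={"green": 1, "yellow": 2, "orange": 1, "red": 0},
        non_sepsis_category_counts={"green": 20, "yellow": 10, "orange": 3, "red": 1},
        n_blue_excluded=3,
        n_palliative_excluded=1,
        n_sepsis_icu_24h=1,
        n_sepsis_icu_72h=2,
        n_sepsis_died=1,
        n_non_sepsis_icu_72h=2,
        n_non_sepsis_died=1,
    )
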