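"""Synthetic ED cohort generation.

Two modes:

* **Exact replay** — reconstruct an encounter-level cohort whose screening
  and labelling margins reproduce, cell for cell, a specified joint
  contingency structure: the (MTS x SIRS x sepsis) joint cells, triage
  category margins, nurse-checkbox totals, over/undertriage counts and
  the per-field missingness.  :func:`study_margins` ships the margins of
  the audited tertiary-care ED cohort (28,213 analysed encounters at
  0.67% sepsis prevalence) so the whole published audit can be re-run end
  to end on synthetic records.
* **Stochastic simulation** — draw cohorts from configurable per-stratum
  vital-sign distributions with nurse triage-error rates and per-field
  missingness, for power studies and property tests.

Replay places each record in its joint cell by construction: vitals are
drawn from just-past-threshold (or clearly normal) bands so the rule
outcome is guaranteed, the nurse-entered possible-sepsis category is set
from the MTS-alert cell regardless of vitals (modelling nurse error), and
missingness is applied only to records whose cell outcome cannot depend
on the missing field, which preserves every margin exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional

import numpy as np
import yaml

from .cohort_io import Avpu, EncounterRecord, TriageCategory, Vitals
from .diagnostics import TwoByTwo

__all__ = [
    "MarginsError",
    "StratumCells",
    "ReplayMargins",
    "derive_replay_margins",
    "study_margins",
    "replay_cohort",
    "BandProbabilities",
    "StratumParams",
    "SimulationParams",
    "simulate_cohort",
    "STUDY_MTS_TABLE",
    "STUDY_SIRS_TABLE",
    "STUDY_COMBINED_TABLE",
    "STUDY_BOTH_ALERTS",
]

# 2x2 tables of the audited ED cohort (screen vs Sepsis-3 reference).
STUDY_MTS_TABLE = TwoByTwo(tp=90, fp=179, fn=99, tn=27845)
STUDY_SIRS_TABLE = TwoByTwo(tp=98, fp=831, fn=91, tn=27193)
STUDY_COMBINED_TABLE = TwoByTwo(tp=121, fp=895, fn=68, tn=27129)
#: Encounters that alerted through both sources simultaneously.
STUDY_BOTH_ALERTS = 182


class MarginsError(ValueError):
    """Raised when requested replay margins are mutually inconsistent."""


@dataclass(frozen=True)
class StratumCells:
    """Joint (MTS x SIRS) cell counts within one sepsis stratum."""

    both: int
    mts_only: int
    sirs_only: int
    neither: int

    def __post_init__(self) -> None:
        for name in ("both", "mts_only", "sirs_only", "neither"):
            if getattr(self, name) < 0:
                raise MarginsError(f"negative joint cell {name!r}: inconsistent inputs")

    @property
    def total(self) -> int:
        return self.both + self.mts_only + self.sirs_only + self.neither

    @property
    def mts_positive(self) -> int:
        return self.both + self.mts_only

    @property
    def sirs_positive(self) -> int:
        return self.both + self.sirs_only

    @property
    def any_alert(self) -> int:
        return self.both + self.mts_only + self.sirs_only


# Non-MTS-positive triage category allocation for the study cohort.  The
# category-margin table of the source cohort is internally inconsistent
# with its alert counts by a handful of patients, so the red category
# absorbs the difference and these margins are documented as approximate.
_SEPSIS_CATEGORY_COUNTS = {"green": 10, "yellow": 51, "orange": 38, "red": 0}
_NON_SEPSIS_CATEGORY_COUNTS = {
    "green": 13240,
    "yellow": 10989,
    "orange": 3325,
    "red": 291,
}
_SHOCK_CATEGORY_QUOTA = {"possible_sepsis": 27, "orange": 13, "yellow": 6, "green": 1}


@dataclass(frozen=True)
class ReplayMargins:
    """Every margin the replay generator reproduces exactly.

    The joint cells come from the three screen-level 2x2 tables (via
    :func:`derive_replay_margins`); the remaining fields default to the
    audited study cohort and control the nurse-checkbox totals, the
    audit's over/undertriage counts, the per-field missingness and the
    pre-exclusion accounting.
    """

    sepsis: StratumCells
    non_sepsis: StratumCells
    n_septic_shock: int = 47
    n_suspicion_total: int = 4538       # nurse scored "new infection"
    n_altered_mental_checked: int = 251
    n_overtriaged: int = 172            # possible-sepsis assignments w/o criteria
    n_undertriaged: int = 425           # suspected + criteria, not assigned
    missing_sbp: int = 33
    missing_mental_status: int = 369
    missing_temp: int = 975
    sepsis_category_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(_SEPSIS_CATEGORY_COUNTS)
    )
    non_sepsis_category_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(_NON_SEPSIS_CATEGORY_COUNTS)
    )
    n_blue_excluded: int = 1537
    n_palliative_excluded: int = 16
    n_sepsis_icu_24h: int = 41
    n_sepsis_icu_72h: int = 50
    n_sepsis_died: int = 31
    n_non_sepsis_icu_72h: int = 484
    n_non_sepsis_died: int = 150

    # -- derived quantities ------------------------------------------------
    @property
    def n_assigned(self) -> int:
        return self.sepsis.mts_positive + self.non_sepsis.mts_positive

    @property
    def n_assigned_with_criteria(self) -> int:
        return self.n_assigned - self.n_overtriaged

    @property
    def n_sirs_positive(self) -> int:
        return self.sepsis.sirs_positive + self.non_sepsis.sirs_positive

    @property
    def n_suspicion_extension(self) -> int:
        """Suspicion checkboxes beyond the SIRS-alert-positive records."""
        return self.n_suspicion_total - self.n_sirs_positive

    def validate(self) -> None:
        s, ns = self.sepsis, self.non_sepsis
        if self.n_septic_shock > s.total:
            raise MarginsError("more septic-shock cases than sepsis cases")
        if self.n_suspicion_extension < 0:
            raise MarginsError("suspicion total below SIRS-positive count")
        if self.n_undertriaged > self.n_suspicion_extension:
            raise MarginsError(
                "undertriaged count cannot exceed the suspicion extension: "
                "SIRS-positive records carry alert-consistent normal qSOFA vitals"
            )
        if self.n_altered_mental_checked > self.n_sirs_positive:
            raise MarginsError("altered-mental checkboxes exceed SIRS-positive records")
        if self.n_overtriaged > self.n_assigned:
            raise MarginsError("overtriaged count exceeds possible-sepsis assignments")
        if self.n_assigned_with_criteria < s.mts_positive:
            raise MarginsError(
                "assignments-with-criteria below the sepsis MTS-positive count"
            )
        if self.n_assigned_with_criteria - s.mts_positive > ns.mts_only:
            raise MarginsError(
                "non-sepsis assignments with criteria exceed the MTS-only cell"
            )
        if sum(self.sepsis_category_counts.values()) != s.sirs_only + s.neither:
            raise MarginsError("sepsis category margins do not sum to MTS-negatives")
        if sum(self.non_sepsis_category_counts.values()) != ns.sirs_only + ns.neither:
            raise MarginsError("non-sepsis category margins do not sum to MTS-negatives")
        n_plain = ns.neither - self.n_suspicion_extension
        needed = self.missing_mental_status + self.missing_sbp + self.missing_temp
        if needed > n_plain:
            raise MarginsError("not enough alert-neutral records to carry missingness")
        if self.n_non_sepsis_icu_72h + self.n_non_sepsis_died > n_plain - needed:
            raise MarginsError("not enough plain records for outcome flags")
        for name in ("n_sepsis_icu_24h", "n_sepsis_icu_72h", "n_sepsis_died"):
            if getattr(self, name) > s.total:
                raise MarginsError(f"{name} exceeds the sepsis count")


def derive_replay_margins(
    mts: TwoByTwo,
    sirs: TwoByTwo,
    combined: TwoByTwo,
    both_alerts_total: Optional[int] = None,
    **overrides,
) -> ReplayMargins:
    """Recover the joint (MTS x SIRS x sepsis) cells by inclusion-exclusion.

    Within each stratum ``|A and B| = |A| + |B| - |A or B|``; the three
    tables must share totals and diseased margins, and when
    ``both_alerts_total`` is given it must equal the derived overlap.
    Any derived negative cell raises :class:`MarginsError`.
    """
    if not (mts.total == sirs.total == combined.total):
        raise MarginsError("tables do not share a cohort total")
    if not (mts.diseased == sirs.diseased == combined.diseased):
        raise MarginsError("tables do not share the diseased margin")

    def cells(a_pos: int, b_pos: int, union_pos: int, total: int) -> StratumCells:
        both = a_pos + b_pos - union_pos
        return StratumCells(
            both=both,
            mts_only=a_pos - both,
            sirs_only=b_pos - both,
            neither=total - union_pos,
        )

    sepsis = cells(mts.tp, sirs.tp, combined.tp, mts.diseased)
    non_sepsis = cells(mts.fp, sirs.fp, combined.fp, mts.non_diseased)
    if both_alerts_total is not None and sepsis.both + non_sepsis.both != both_alerts_total:
        raise MarginsError(
            f"stated both-alert overlap {both_alerts_total} disagrees with the "
            f"derived {sepsis.both + non_sepsis.both}"
        )
    margins = ReplayMargins(sepsis=sepsis, non_sepsis=non_sepsis, **overrides)
    margins.validate()
    return margins


def study_margins() -> ReplayMargins:
    """The full replay margins of the audited ED cohort."""
    return derive_replay_margins(
        STUDY_MTS_TABLE,
        STUDY_SIRS_TABLE,
        STUDY_COMBINED_TABLE,
        both_alerts_total=STUDY_BOTH_ALERTS,
    )


# ---------------------------------------------------------------------------
# Replay generator
# ---------------------------------------------------------------------------

_CATEGORY_AGE_RANGE = {
    TriageCategory.BLUE: (19, 60),
    TriageCategory.GREEN: (30, 62),
    TriageCategory.YELLOW: (33, 67),
    TriageCategory.ORANGE: (41, 73),
    TriageCategory.POSSIBLE_SEPSIS: (49, 74),
    TriageCategory.RED: (50, 75),
}


def _sofa_components(total: int, rng: np.random.Generator) -> tuple:
    """Distribute a SOFA total over six organ systems (each capped at 4)."""
    scores = [0] * 6
    order = rng.permutation(6)
    remaining = total
    for idx in order:
        if remaining == 0:
            break
        take = int(min(4, remaining))
        if take > 1:
            take = int(rng.integers(1, take + 1))
        scores[idx] = take
        remaining -= take
    return tuple(s if s > 0 else None for s in scores)


def replay_cohort(
    margins: ReplayMargins,
    seed: int = 0,
    include_excluded: bool = True,
) -> list[EncounterRecord]:
    """Materialise an encounter cohort hitting every replay margin exactly.

    With ``include_excluded`` the blue-category and palliative encounters
    removed by the cohort filter are emitted as well, so the full
    exclusion accounting is reproducible; the analysed margins always
    refer to the post-exclusion cohort.  Identical seeds produce
    identical cohorts.
    """
    margins.validate()
    rng = np.random.default_rng(seed)
    s, ns = margins.sepsis, margins.non_sepsis

    POSS = TriageCategory.POSSIBLE_SEPSIS

    # Category pools for MTS-negative records, consumed in build order.
    sepsis_pool = [
        TriageCategory(cat)
        for cat, count in margins.sepsis_category_counts.items()
        for _ in range(count)
    ]
    ns_pool = [
        TriageCategory(cat)
        for cat, count in margins.non_sepsis_category_counts.items()
        for _ in range(count)
    ]
    rng.shuffle(sepsis_pool)
    rng.shuffle(ns_pool)
    sepsis_pool_iter = iter(sepsis_pool)
    ns_pool_iter = iter(ns_pool)

    # Altered-mental checkboxes go to SIRS-positive records (the checkbox
    # is one arm of the alert, so it can only sit where an alert fired).
    altered_budget = margins.n_altered_mental_checked
    n_ns_assigned_with_crit = margins.n_assigned_with_criteria - s.mts_positive
    n_ext = margins.n_suspicion_extension
    n_plain = ns.neither - n_ext - (
        margins.missing_mental_status + margins.missing_sbp + margins.missing_temp
    )

    plans: list[dict] = []

    def add(n: int, **kw) -> None:
        for _ in range(n):
            plans.append(dict(kw))

    def take_altered(n: int) -> tuple[int, int]:
        nonlocal altered_budget
        hit = min(n, altered_budget)
        altered_budget -= hit
        return hit, n - hit

    # --- sepsis stratum ---------------------------------------------------
    hit, rest = take_altered(s.both)
    add(hit, sepsis=True, cat=POSS, susp=True, febrile=True, rr_q=True, altered=True)
    add(rest, sepsis=True, cat=POSS, susp=True, febrile=True, rr_q=True, altered=False)
    add(s.mts_only, sepsis=True, cat=POSS, susp=False, febrile=False, rr_q=True,
        altered=False)
    hit, rest = take_altered(s.sirs_only)
    add(hit, sepsis=True, cat="pool_s", susp=True, febrile=True, rr_q=False,
        altered=True)
    add(rest, sepsis=True, cat="pool_s", susp=True, febrile=True, rr_q=False,
        altered=False)
    add(s.neither, sepsis=True, cat="pool_s", susp=False, febrile=False, rr_q=False,
        altered=False)

    # --- non-sepsis stratum -----------------------------------------------
    hit, rest = take_altered(ns.both)
    add(hit, sepsis=False, cat=POSS, susp=True, febrile=True, rr_q=False, altered=True)
    add(rest, sepsis=False, cat=POSS, susp=True, febrile=True, rr_q=False,
        altered=False)
    add(n_ns_assigned_with_crit, sepsis=False, cat=POSS, susp=False, febrile=False,
        rr_q=True, altered=False)
    add(ns.mts_only - n_ns_assigned_with_crit, sepsis=False, cat=POSS, susp=False,
        febrile=False, rr_q=False, altered=False)
    hit, rest = take_altered(ns.sirs_only)
    add(hit, sepsis=False, cat="pool_ns", susp=True, febrile=True, rr_q=False,
        altered=True)
    add(rest, sepsis=False, cat="pool_ns", susp=True, febrile=True, rr_q=False,
        altered=False)
    # neither cell: suspicion extension (with the undertriaged subset),
    # missingness carriers, then plain records with the outcome flags.
    add(margins.n_undertriaged, sepsis=False, cat="pool_ns", susp=True, febrile=False,
        rr_q=False, altered=False, sbp_low=True)
    add(n_ext - margins.n_undertriaged, sepsis=False, cat="pool_ns", susp=True,
        febrile=False, rr_q=False, altered=False)
    add(margins.missing_mental_status, sepsis=False, cat="pool_ns", susp=False,
        febrile=False, rr_q=False, altered=None, missing="mental")
    add(margins.missing_sbp, sepsis=False, cat="pool_ns", susp=False, febrile=False,
        rr_q=False, altered=False, missing="sbp")
    add(margins.missing_temp, sepsis=False, cat="pool_ns", susp=False, febrile=False,
        rr_q=False, altered=False, missing="temp")
    add(margins.n_non_sepsis_icu_72h, sepsis=False, cat="pool_ns", susp=False,
        febrile=False, rr_q=False, altered=False, icu72=True)
    add(margins.n_non_sepsis_died, sepsis=False, cat="pool_ns", susp=False,
        febrile=False, rr_q=False, altered=False, died=True)
    add(n_plain - margins.n_non_sepsis_icu_72h - margins.n_non_sepsis_died,
        sepsis=False, cat="pool_ns", susp=False, febrile=False, rr_q=False,
        altered=False)

    # --- excluded records (pre-filter cohort) -----------------------------
    if include_excluded:
        add(margins.n_blue_excluded, sepsis=False, cat=TriageCategory.BLUE,
            susp=False, febrile=False, rr_q=False, altered=False, excluded=True)
        add(margins.n_palliative_excluded, sepsis=True, cat=POSS, susp=True,
            febrile=True, rr_q=False, altered=False, palliative=True, excluded=True)

    # Septic-shock quota and sepsis outcome flags are assigned across the
    # sepsis plans before shuffling (deterministic given the margins).
    shock_quota = dict(_SHOCK_CATEGORY_QUOTA)
    shock_left = margins.n_septic_shock
    sepsis_plans = [p for p in plans if p["sepsis"] and not p.get("excluded")]
    for plan in sepsis_plans:
        cat = plan["cat"]
        key = cat.value if isinstance(cat, TriageCategory) else None
        if shock_left > 0 and key is not None and shock_quota.get(key, 0) > 0:
            plan["shock"] = True
            shock_quota[key] -= 1
            shock_left -= 1
    for plan in sepsis_plans:
        if shock_left == 0:
            break
        if not plan.get("shock"):
            plan["shock"] = True
            shock_left -= 1
    for i, plan in enumerate(sepsis_plans):
        plan["icu24"] = i < margins.n_sepsis_icu_24h
        plan["icu72"] = i < margins.n_sepsis_icu_72h
        plan["died"] = i < margins.n_sepsis_died

    rng.shuffle(plans)

    records: list[EncounterRecord] = []
    for i, plan in enumerate(plans):
        cat = plan["cat"]
        if cat == "pool_s":
            cat = next(sepsis_pool_iter)
        elif cat == "pool_ns":
            cat = next(ns_pool_iter)
        missing = plan.get("missing")
        sepsis = plan["sepsis"]
        altered = plan["altered"]

        if plan["febrile"]:
            temp = round(float(rng.uniform(38.3, 40.0)), 1)
            hr = int(rng.integers(95, 136))
        else:
            temp = round(float(rng.uniform(36.4, 37.5)), 1)
            hr = int(rng.integers(62, 89))
        rr = int(rng.integers(22, 33)) if plan["rr_q"] else int(rng.integers(12, 19))
        if plan.get("sbp_low"):
            sbp: Optional[float] = float(rng.integers(84, 97))
        else:
            sbp = float(rng.integers(105, 151))
        gcs: Optional[int] = 15
        avpu: Optional[Avpu] = Avpu.VOICE if altered else Avpu.ALERT
        if missing == "mental":
            gcs, avpu = None, None
        elif missing == "sbp":
            sbp = None
        elif missing == "temp":
            temp = None
        spo2 = float(rng.integers(94, 98) if sepsis else rng.integers(96, 100))

        if sepsis:
            sofa = _sofa_components(int(rng.integers(2, 13)), rng)
            shock = bool(plan.get("shock"))
            lactate = round(
                float(rng.uniform(2.5, 6.0) if shock else rng.uniform(0.6, 1.9)), 1
            )
            vasopressors: Optional[bool] = shock
            abx, cultures = True, True
        else:
            sofa = (None,) * 6
            lactate, vasopressors = None, None
            abx = cultures = False

        lo, hi = _CATEGORY_AGE_RANGE[cat]
        records.append(
            EncounterRecord(
                encounter_id=f"E{i + 1:06d}",
                age_years=float(rng.integers(lo, hi + 1)),
                triage_category=cat,
                vitals=Vitals(
                    temp_c=temp,
                    heart_rate=float(hr),
                    resp_rate=float(rr),
                    sbp=sbp,
                    gcs=gcs,
                    avpu=avpu,
                    spo2=spo2,
                    supplemental_o2=False,
                    altered_mental_checkbox=altered,
                ),
                suspicion_new_infection=plan["susp"],
                antibiotics_ordered=abx,
                blood_cultures_ordered=cultures,
                sofa_components=sofa,
                lactate_mmol_l=lactate,
                vasopressors=vasopressors,
                palliative_pathway=bool(plan.get("palliative")),
                icu_within_24h=bool(plan.get("icu24")),
                icu_within_72h=bool(plan.get("icu72")),
                died_in_hospital=bool(plan.get("died")),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Stochastic simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandProbabilities:
    """Per-vital probabilities of landing in the rule-relevant band."""

    p_rr_ge_22: float
    p_rr_20_22: float      # tachypnoeic for SIRS but below the qSOFA cut
    p_sbp_lt_100: float
    p_gcs_lt_15: float
    p_temp_abnormal: float
    p_hr_gt_90: float
    p_altered_checkbox: float
    p_suspicion: float

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_rr_ge_22 + self.p_rr_20_22 > 1:
            raise ValueError("respiratory-rate band probabilities exceed 1")


@dataclass(frozen=True)
class StratumParams:
    """Two-class severity mixture within one sepsis stratum.

    A latent "severe" class (overt physiological derangement for sepsis
    cases, clinically evident infection for non-sepsis cases) carries
    most of the abnormal vitals; the mixture induces the positive
    correlation between the two screens seen in real triage data.
    """

    share_severe: float
    severe: BandProbabilities
    mild: BandProbabilities

    def __post_init__(self) -> None:
        if not 0 <= self.share_severe <= 1:
            raise ValueError("share_severe must be in [0, 1]")


def _default_sepsis_stratum() -> StratumParams:
    return StratumParams(
        share_severe=0.5,
        severe=BandProbabilities(0.65, 0.05, 0.40, 0.30, 0.70, 0.75, 0.25, 0.95),
        mild=BandProbabilities(0.10, 0.05, 0.08, 0.04, 0.25, 0.30, 0.03, 0.75),
    )


def _default_non_sepsis_stratum() -> StratumParams:
    return StratumParams(
        share_severe=0.16,
        severe=BandProbabilities(0.03, 0.12, 0.02, 0.01, 0.45, 0.40, 0.01, 0.90),
        mild=BandProbabilities(0.005, 0.035, 0.005, 0.002, 0.03, 0.10, 0.002, 0.02),
    )


@dataclass(frozen=True)
class SimulationParams:
    """Configuration of the stochastic cohort generator.

    Defaults emulate the audited study conditions: 28,213 analysed
    encounters, 0.67% sepsis prevalence, small nurse overtriage and
    moderate undertriage of the possible-sepsis discriminator, and the
    study's per-field missingness rates.
    """

    n: int = 28213
    prevalence: float = 0.0067
    overtriage_rate: float = 0.003   # P(assign possible sepsis | rule negative)
    undertriage_rate: float = 0.12   # P(not assign | rule positive)
    missingness: Mapping[str, float] = field(
        default_factory=lambda: {"sbp": 0.0012, "mental_status": 0.013, "temp_c": 0.035}
    )
    sepsis: StratumParams = field(default_factory=_default_sepsis_stratum)
    non_sepsis: StratumParams = field(default_factory=_default_non_sepsis_stratum)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")
        for name in ("overtriage_rate", "undertriage_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for fname, rate in self.missingness.items():
            if fname not in ("sbp", "mental_status", "temp_c"):
                raise ValueError(f"unknown missingness field {fname!r}")
            if not 0 <= rate <= 1:
                raise ValueError("missingness rates must be in [0, 1]")

    # -- YAML round-trip ---------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationParams":
        raw = yaml.safe_load(text) or {}
        for key in ("sepsis", "non_sepsis"):
            if key in raw:
                raw[key] = StratumParams(
                    share_severe=raw[key]["share_severe"],
                    severe=BandProbabilities(**raw[key]["severe"]),
                    mild=BandProbabilities(**raw[key]["mild"]),
                )
        return cls(**raw)


_NS_CATEGORY_WEIGHTS = np.array([0.47, 0.39, 0.12, 0.02])
_SEPSIS_CATEGORY_WEIGHTS = np.array([0.10, 0.50, 0.33, 0.07])
_NON_POSS_CATEGORIES = (
    TriageCategory.GREEN,
    TriageCategory.YELLOW,
    TriageCategory.ORANGE,
    TriageCategory.RED,
)


def simulate_cohort(
    params: SimulationParams,
    seed: Optional[int] = None,
) -> list[EncounterRecord]:
    """Draw a seeded stochastic cohort.

    Sepsis status is Bernoulli(prevalence); vitals are drawn per latent
    severity class within the stratum; the nurse category follows the
    possible-sepsis discriminator applied to the drawn vitals, flipped
    with the configured triage-error rates; missingness masks are applied
    last (after the nurse decision — the nurse saw the patient, the
    extract did not).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n

    sepsis = rng.random(n) < params.prevalence
    share = np.where(
        sepsis, params.sepsis.share_severe, params.non_sepsis.share_severe
    )
    severe = rng.random(n) < share

    def prob(attr: str) -> np.ndarray:
        return np.select(
            [sepsis & severe, sepsis & ~severe, ~sepsis & severe],
            [
                getattr(params.sepsis.severe, attr),
                getattr(params.sepsis.mild, attr),
                getattr(params.non_sepsis.severe, attr),
            ],
            default=getattr(params.non_sepsis.mild, attr),
        )

    u_rr = rng.random(n)
    p22 = prob("p_rr_ge_22")
    rr = np.where(
        u_rr < p22,
        rng.integers(22, 33, n),
        np.where(u_rr < p22 + prob("p_rr_20_22"), 21, rng.integers(12, 19, n)),
    ).astype(float)
    sbp_low = rng.random(n) < prob("p_sbp_lt_100")
    sbp = np.where(sbp_low, rng.integers(78, 99, n), rng.integers(102, 160, n)).astype(
        float
    )
    gcs_low = rng.random(n) < prob("p_gcs_lt_15")
    gcs = np.where(gcs_low, rng.integers(10, 15, n), 15)
    temp_abn = rng.random(n) < prob("p_temp_abnormal")
    febrile = rng.random(n) < 0.85
    temp = np.where(
        temp_abn,
        np.where(febrile, rng.uniform(38.3, 40.2, n), rng.uniform(34.8, 35.9, n)),
        rng.uniform(36.2, 37.8, n),
    ).round(1)
    hr_high = rng.random(n) < prob("p_hr_gt_90")
    hr = np.where(hr_high, rng.integers(92, 136, n), rng.integers(55, 89, n)).astype(
        float
    )
    altered = rng.random(n) < prob("p_altered_checkbox")
    suspicion = rng.random(n) < prob("p_suspicion")
    spo2 = np.where(
        sepsis & severe, rng.integers(90, 97, n), rng.integers(95, 100, n)
    ).astype(float)
    supp_o2 = sepsis & severe & (rng.random(n) < 0.3)

    # Nurse category: rule on the true (pre-masking) vitals, then error flips.
    rule_pos = (rr >= 22) | (sbp < 100) | (gcs < 15)
    flip = rng.random(n)
    assigned = np.where(
        rule_pos, flip >= params.undertriage_rate, flip < params.overtriage_rate
    )
    cat_weights = np.where(
        sepsis[:, None], _SEPSIS_CATEGORY_WEIGHTS, _NS_CATEGORY_WEIGHTS
    )
    cat_idx = (rng.random(n)[:, None] > np.cumsum(cat_weights, axis=1)).sum(axis=1)
    cat_idx = np.minimum(cat_idx, 3)

    cultures = sepsis | (~sepsis & severe & (rng.random(n) < 0.3))
    sofa_totals = np.where(sepsis, rng.integers(2, 15, n), 0)
    shock = sepsis & (rng.random(n) < 0.25)
    lactate = np.where(shock, rng.uniform(2.5, 7.0, n), rng.uniform(0.5, 2.4, n)).round(
        1
    )
    icu24 = sepsis & (rng.random(n) < 0.22)
    icu72 = icu24 | (sepsis & (rng.random(n) < 0.05)) | (
        ~sepsis & (rng.random(n) < 0.017)
    )
    died = (sepsis & (rng.random(n) < 0.16)) | (~sepsis & (rng.random(n) < 0.005))
    age = rng.integers(19, 93, n).astype(float)

    miss = {
        fname: rng.random(n) < rate for fname, rate in params.missingness.items()
    }
    miss_sbp = miss.get("sbp", np.zeros(n, dtype=bool))
    miss_mental = miss.get("mental_status", np.zeros(n, dtype=bool))
    miss_temp = miss.get("temp_c", np.zeros(n, dtype=bool))

    records: list[EncounterRecord] = []
    for i in range(n):
        is_sepsis = bool(sepsis[i])
        category = (
            TriageCategory.POSSIBLE_SEPSIS
            if assigned[i]
            else _NON_POSS_CATEGORIES[cat_idx[i]]
        )
        mental_missing = bool(miss_mental[i])
        gcs_i: Optional[int] = None if mental_missing else int(gcs[i])
        altered_i: Optional[bool] = None if mental_missing else bool(altered[i])
        if mental_missing:
            avpu = None
        else:
            avpu = Avpu.VOICE if (gcs[i] < 15 or altered[i]) else Avpu.ALERT
        records.append(
            EncounterRecord(
                encounter_id=f"S{i + 1:06d}",
                age_years=float(age[i]),
                triage_category=category,
                vitals=Vitals(
                    temp_c=None if miss_temp[i] else float(temp[i]),
                    heart_rate=float(hr[i]),
                    resp_rate=float(rr[i]),
                    sbp=None if miss_sbp[i] else float(sbp[i]),
                    gcs=gcs_i,
                    avpu=avpu,
                    spo2=float(spo2[i]),
                    supplemental_o2=bool(supp_o2[i]),
                    altered_mental_checkbox=altered_i,
                ),
                suspicion_new_infection=bool(suspicion[i]),
                antibiotics_ordered=is_sepsis,
                blood_cultures_ordered=bool(cultures[i]),
                sofa_components=(
                    _sofa_components(int(sofa_totals[i]), rng)
                    if is_sepsis
                    else (None,) * 6
                ),
                lactate_mmol_l=float(lactate[i]) if is_sepsis else None,
                vasopressors=bool(shock[i]) if is_sepsis else None,
                palliative_pathway=False,
                icu_within_24h=bool(icu24[i]),
                icu_within_72h=bool(icu72[i]),
                died_in_hospital=bool(died[i]),
            )
        )
    return records
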