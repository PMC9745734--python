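"""Diagnostic-accuracy engine for binary screens against a binary reference.

Everything derives from a 2x2 contingency table.  Point estimates use the
standard definitions (Se = TP/(TP+FN), LR+ = Se/(1-Sp), binary-test
AUC = (Se+Sp)/2, ...).  Interval methods follow the conventions of
diagnostic-accuracy software:

* sensitivity, specificity, accuracy, prevalence, correctly-triaged
  proportion — Clopper-Pearson exact binomial intervals (beta-quantile
  inversion);
* likelihood ratios — Simel log method;
* predictive values — Mercaldo standard-logit intervals;
* AUC — delta method on (Se+Sp)/2.

Measures with a zero denominator (or a likelihood ratio at a boundary
proportion) are reported as explicitly undefined estimates with a note,
never as silently propagated NaNs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Optional, Sequence

from scipy import stats

from .cohort_io import EncounterRecord, TriageCategory
from .reference_labels import SepsisLabel

__all__ = [
    "TwoByTwo",
    "Interval",
    "Estimate",
    "PerformanceReport",
    "McNemarResult",
    "Stratum",
    "confusion_table",
    "performance",
    "exact_binomial_ci",
    "lr_ci",
    "predictive_value_ci",
    "mcnemar_paired",
    "correctly_triaged",
    "round_half_up",
]

CORRECT_TRIAGE_CATEGORIES = (
    TriageCategory.RED,
    TriageCategory.ORANGE,
    TriageCategory.POSSIBLE_SEPSIS,
)


@dataclass(frozen=True)
class TwoByTwo:
    """Confusion counts of one screen against the sepsis reference."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def diseased(self) -> int:
        return self.tp + self.fn

    @property
    def non_diseased(self) -> int:
        return self.fp + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fp

    @property
    def negatives(self) -> int:
        return self.fn + self.tn


@dataclass(frozen=True)
class Interval:
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("confidence level must be in (0, 1)")
        if self.lower > self.upper + 1e-12:
            raise ValueError("interval lower bound exceeds upper bound")

    def __contains__(self, x: float) -> bool:
        return self.lower <= x <= self.upper


@dataclass(frozen=True)
class Estimate:
    """A point estimate with its interval, or an explicit 'undefined'."""

    value: Optional[float]
    ci: Optional[Interval] = None
    note: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class PerformanceReport:
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    accuracy: Estimate
    prevalence: Estimate
    lr_pos: Estimate
    lr_neg: Estimate
    auc: Estimate
    table: TwoByTwo


class Stratum(str, Enum):
    DISEASED = "diseased"
    NON_DISEASED = "non_diseased"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at the last digit always rounds away)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def confusion_table(
    test: Sequence[bool], truth: Sequence[bool]
) -> TwoByTwo:
    """Cross-tabulate a resolved (no indeterminate) screen against truth."""
    if len(test) != len(truth):
        raise ValueError("test and truth must have equal length")
    tp = fp = fn = tn = 0
    for t, d in zip(test, truth):
        if t:
            if d:
                tp += 1
            else:
                fp += 1
        else:
            if d:
                fn += 1
            else:
                tn += 1
    return TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn)


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> Interval:
    """Clopper-Pearson exact interval for a binomial proportion.

    Lower bound is 0 when ``k == 0`` and upper bound is 1 when ``k == n``;
    otherwise the bounds invert the exact binomial tail conditions via
    beta quantiles.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return Interval(lower, upper, level)


def _z(level: float) -> float:
    return float(stats.norm.ppf(0.5 + level / 2))


def lr_ci(t: TwoByTwo, which: str, level: float = 0.95) -> Estimate:
    """Simel log-method interval for a likelihood ratio.

    Requires both proportions in the ratio strictly inside (0, 1); at a
    boundary the ratio is degenerate and the estimate is flagged
    undefined instead.
    """
    se = t.tp / t.diseased if t.diseased else None
    sp = t.tn / t.non_diseased if t.non_diseased else None
    if se is None or sp is None or not (0 < se < 1 and 0 < sp < 1):
        return Estimate(None, note="likelihood ratio undefined at boundary proportions")
    if which == "pos":
        lr = se / (1 - sp)
        var_log = (1 - se) / (se * t.diseased) + sp / ((1 - sp) * t.non_diseased)
    elif which == "neg":
        lr = (1 - se) / sp
        var_log = se / ((1 - se) * t.diseased) + (1 - sp) / (sp * t.non_diseased)
    else:
        raise ValueError("which must be 'pos' or 'neg'")
    half = _z(level) * math.sqrt(var_log)
    return Estimate(lr, Interval(lr * math.exp(-half), lr * math.exp(half), level))


def _inv_logit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def predictive_value_ci(t: TwoByTwo, which: str, level: float = 0.95) -> Estimate:
    """Mercaldo standard-logit interval for PPV or NPV.

    The logit-scale variance is expressed through Se/Sp and the stratum
    sizes; when the predictive value sits at 0 or 1 a continuity
    correction (0.5 added to each cell) keeps the interval computable.
    """
    if which == "ppv":
        num, den = t.tp, t.positives
    elif which == "npv":
        num, den = t.tn, t.negatives
    else:
        raise ValueError("which must be 'ppv' or 'npv'")
    if den == 0:
        return Estimate(None, note=f"{which} undefined: no test-{'positives' if which == 'ppv' else 'negatives'}")
    pv = num / den

    tp, fp, fn, tn = t.tp, t.fp, t.fn, t.tn
    degenerate = pv in (0.0, 1.0) or 0 in (tp, fp, fn, tn)
    if degenerate:  # continuity fallback
        tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    n1 = tp + fn
    n0 = tn + fp
    if which == "ppv":
        var_logit = (1 - se) / (se * n1) + sp / ((1 - sp) * n0)
        logit = math.log(tp / fp)  # logit(PPV) at the observed prevalence
    else:
        var_logit = se / ((1 - se) * n1) + (1 - sp) / (sp * n0)
        logit = math.log(tn / fn)
    half = _z(level) * math.sqrt(var_logit)
    ci = Interval(_inv_logit(logit - half), _inv_logit(logit + half), level)
    note = "continuity-corrected interval (boundary proportion)" if degenerate else None
    return Estimate(pv, ci, note=note)


def _proportion_estimate(k: int, n: int, level: float, what: str) -> Estimate:
    if n == 0:
        return Estimate(None, note=f"{what} undefined: empty denominator")
    return Estimate(k / n, exact_binomial_ci(k, n, level))


def performance(t: TwoByTwo, level: float = 0.95) -> PerformanceReport:
    """All performance measures of one screen, each with its interval."""
    se = _proportion_estimate(t.tp, t.diseased, level, "sensitivity")
    sp = _proportion_estimate(t.tn, t.non_diseased, level, "specificity")
    acc = _proportion_estimate(t.tp + t.tn, t.total, level, "accuracy")
    prev = _proportion_estimate(t.diseased, t.total, level, "prevalence")
    ppv = predictive_value_ci(t, "ppv", level)
    npv = predictive_value_ci(t, "npv", level)

    if se.defined and sp.defined:
        se_v, sp_v = se.value, sp.value
        auc_v = (se_v + sp_v) / 2
        var_auc = (
            se_v * (1 - se_v) / t.diseased + sp_v * (1 - sp_v) / t.non_diseased
        ) / 4
        half = _z(level) * math.sqrt(var_auc)
        auc = Estimate(
            auc_v,
            Interval(max(0.0, auc_v - half), min(1.0, auc_v + half), level),
        )
        lr_pos = (
            lr_ci(t, "pos", level)
            if 0 < sp_v < 1
            else (
                Estimate(None, note="LR+ undefined: specificity at boundary")
                if sp_v == 1
                else Estimate(0.0, note="LR+ degenerate: specificity 0")
            )
        )
        if 0 < se_v < 1 and 0 < sp_v < 1:
            lr_neg = lr_ci(t, "neg", level)
        elif sp_v > 0:
            lr_neg = Estimate((1 - se_v) / sp_v, note="boundary proportion: no interval")
        else:
            lr_neg = Estimate(None, note="LR- undefined: specificity 0")
    else:
        auc = Estimate(None, note="AUC undefined: one stratum empty")
        lr_pos = Estimate(None, note="LR undefined: one stratum empty")
        lr_neg = Estimate(None, note="LR undefined: one stratum empty")

    return PerformanceReport(
        sensitivity=se,
        specificity=sp,
        ppv=ppv,
        npv=npv,
        accuracy=acc,
        prevalence=prev,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        auc=auc,
        table=t,
    )


@dataclass(frozen=True)
class McNemarResult:
    """Exact paired comparison of two screens within one truth stratum."""

    b: int  # first screen positive, second negative
    c: int  # first screen negative, second positive
    p_value: float
    stratum: Stratum


def mcnemar_paired(
    test_a: Sequence[bool],
    test_b: Sequence[bool],
    truth: Sequence[bool],
    stratum: Stratum | str = Stratum.DISEASED,
) -> McNemarResult:
    """Exact McNemar test on the discordant pairs within a truth stratum.

    Comparing sensitivities uses the diseased stratum, specificities the
    non-diseased one.  The exact two-sided p-value is
    ``min(1, 2 * P(Binomial(b+c, 1/2) <= min(b, c)))``; with no
    discordant pairs the tests are identical and p = 1.
    """
    if not (len(test_a) == len(test_b) == len(truth)):
        raise ValueError("test_a, test_b and truth must have equal length")
    stratum = Stratum(stratum)
    want = stratum is Stratum.DISEASED
    b = c = 0
    for a, bb, d in zip(test_a, test_b, truth):
        if bool(d) is not want:
            continue
        if a and not bb:
            b += 1
        elif bb and not a:
            c += 1
    n_disc = b + c
    if n_disc == 0:
        p = 1.0
    else:
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n_disc, 0.5)))
    return McNemarResult(b=b, c=c, p_value=p, stratum=stratum)


def correctly_triaged(
    records: Sequence[EncounterRecord],
    labels: Sequence[SepsisLabel],
    level: float = 0.95,
) -> Estimate:
    """Proportion of sepsis cases triaged red, orange or possible-sepsis."""
    if len(records) != len(labels):
        raise ValueError("records and labels must have equal length")
    n_sepsis = sum(1 for lab in labels if lab.sepsis)
    if n_sepsis == 0:
        return Estimate(None, note="no sepsis cases: proportion undefined")
    k = sum(
        1
        for rec, lab in zip(records, labels)
        if lab.sepsis and rec.triage_category in CORRECT_TRIAGE_CATEGORIES
    )
    return Estimate(k / n_sepsis, exact_binomial_ci(k, n_sepsis, level))
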