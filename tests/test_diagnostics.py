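"""Diagnostic-accuracy engine: estimates, exact intervals, paired tests."""

import math

import numpy as np
import pytest
from scipy import stats

from _helpers import make_record
from triageaudit.diagnostics import (
    Interval,
    Stratum,
    TwoByTwo,
    confusion_table,
    correctly_triaged,
    exact_binomial_ci,
    lr_ci,
    mcnemar_paired,
    performance,
    predictive_value_ci,
    round_half_up,
)
from triageaudit.reference_labels import SepsisLabel


def test_confusion_table_partitions_cohort():
    test = [True, True, False, False, True]
    truth = [True, False, True, False, False]
    t = confusion_table(test, truth)
    assert (t.tp, t.fp, t.fn, t.tn) == (1, 2, 1, 1)
    assert t.total == 5


def test_confusion_table_all_negative():
    t = confusion_table([False] * 4, [False] * 4)
    assert (t.tp, t.fp, t.fn, t.tn) == (0, 0, 0, 4)


def test_empty_table_rejected():
    with pytest.raises(ValueError):
        TwoByTwo(0, 0, 0, 0)
    with pytest.raises(ValueError):
        TwoByTwo(-1, 1, 1, 1)


def test_perfect_test_measures():
    r = performance(TwoByTwo(tp=7, fp=0, fn=0, tn=13))
    assert r.sensitivity.value == 1.0
    assert r.specificity.value == 1.0
    assert r.lr_neg.value == 0.0
    assert not r.lr_pos.defined  # Se/(1-Sp) diverges at Sp = 1
    assert r.auc.value == 1.0


def test_ppv_matches_bayes_from_prevalence_se_sp():
    rng = np.random.default_rng(5)
    for _ in range(50):
        t = TwoByTwo(*(int(x) for x in rng.integers(1, 200, size=4)))
        r = performance(t)
        se, sp, prev = r.sensitivity.value, r.specificity.value, r.prevalence.value
        bayes = prev * se / (prev * se + (1 - prev) * (1 - sp))
        assert math.isclose(r.ppv.value, bayes, rel_tol=1e-12)


# --- Clopper-Pearson -------------------------------------------------------

def _cp_oracle(k, n, level=0.95):
    """Invert the exact binomial tail conditions by bisection on p."""
    alpha = 1 - level

    def solve(f, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid):
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lower = 0.0 if k == 0 else solve(
        lambda p: stats.binom.sf(k - 1, n, p) < alpha / 2, 0.0, k / n
    )
    upper = 1.0 if k == n else solve(
        lambda p: stats.binom.cdf(k, n, p) > alpha / 2, k / n, 1.0
    )
    return lower, upper


@pytest.mark.parametrize("k,n", [(7, 19), (0, 10), (10, 10), (1, 50), (25, 50)])
def test_exact_binomial_ci_matches_tail_inversion(k, n):
    ci = exact_binomial_ci(k, n)
    lo, hi = _cp_oracle(k, n)
    assert ci.lower == pytest.approx(lo, abs=1e-6)
    assert ci.upper == pytest.approx(hi, abs=1e-6)


def test_exact_binomial_ci_boundaries():
    assert exact_binomial_ci(0, 10).lower == 0.0
    assert exact_binomial_ci(10, 10).upper == 1.0


def test_exact_binomial_ci_coverage_at_nominal_point():
    """Clopper-Pearson is conservative: empirical coverage >= 0.95."""
    rng = np.random.default_rng(42)
    p, n, reps = 0.3, 50, 2000
    ks = rng.binomial(n, p, size=reps)
    alpha = 0.05
    lower = np.where(ks == 0, 0.0, stats.beta.ppf(alpha / 2, ks, n - ks + 1))
    upper = np.where(ks == n, 1.0, stats.beta.ppf(1 - alpha / 2, ks + 1, n - ks))
    coverage = np.mean((lower <= p) & (p <= upper))
    assert coverage >= 0.95


def test_invalid_binomial_inputs():
    with pytest.raises(ValueError):
        exact_binomial_ci(5, 0)
    with pytest.raises(ValueError):
        exact_binomial_ci(11, 10)


# --- likelihood-ratio intervals -------------------------------------------

def test_lr_flip_reciprocity():
    """Flipping the test labels maps LR+ onto LR- of the flipped table."""
    t = TwoByTwo(tp=30, fp=40, fn=20, tn=110)
    flipped = TwoByTwo(tp=t.fn, fp=t.tn, fn=t.tp, tn=t.fp)
    assert lr_ci(t, "pos").value == pytest.approx(lr_ci(flipped, "neg").value)


def test_lr_ci_matches_bootstrap_percentiles():
    """Log-method endpoints agree with a 1e5-replicate bootstrap."""
    t = TwoByTwo(tp=20, fp=30, fn=10, tn=40)
    est = lr_ci(t, "pos")
    rng = np.random.default_rng(11)
    reps = 100_000
    se_star = rng.binomial(t.diseased, t.tp / t.diseased, reps) / t.diseased
    sp_star = rng.binomial(t.non_diseased, t.tn / t.non_diseased, reps) / t.non_diseased
    ok = (se_star > 0) & (sp_star < 1)
    lr_star = se_star[ok] / (1 - sp_star[ok])
    lo, hi = np.percentile(lr_star, [2.5, 97.5])
    assert est.ci.lower == pytest.approx(lo, rel=0.12)
    assert est.ci.upper == pytest.approx(hi, rel=0.12)


def test_lr_undefined_at_boundary():
    assert not lr_ci(TwoByTwo(tp=5, fp=0, fn=0, tn=5), "pos").defined


# --- predictive-value intervals -------------------------------------------

def test_ppv_ci_contains_point_estimate():
    rng = np.random.default_rng(3)
    for _ in range(30):
        t = TwoByTwo(*(int(x) for x in rng.integers(1, 100, size=4)))
        for which in ("ppv", "npv"):
            est = predictive_value_ci(t, which)
            assert est.value in est.ci


def test_ppv_degenerate_uses_continuity_fallback():
    est = predictive_value_ci(TwoByTwo(tp=0, fp=10, fn=5, tn=50), "ppv")
    assert est.value == 0.0
    assert est.ci is not None and est.note is not None


def test_ppv_undefined_without_positives():
    assert not predictive_value_ci(TwoByTwo(tp=0, fp=0, fn=5, tn=5), "ppv").defined


# --- McNemar ---------------------------------------------------------------

def _mcnemar_oracle(b, c):
    n = b + c
    if n == 0:
        return 1.0
    tail = sum(math.comb(n, i) for i in range(min(b, c) + 1)) / 2**n
    return min(1.0, 2 * tail)


def test_mcnemar_balanced_discordance_p_one():
    a = [True] * 3 + [False] * 3
    b = [False] * 3 + [True] * 3
    res = mcnemar_paired(a, b, [True] * 6, Stratum.DISEASED)
    assert (res.b, res.c) == (3, 3)
    assert res.p_value == 1.0


def test_mcnemar_one_sided_discordance():
    a = [True] * 5 + [False] * 10
    b = [False] * 5 + [False] * 10
    res = mcnemar_paired(a, b, [True] * 15, Stratum.DISEASED)
    assert (res.b, res.c) == (5, 0)
    assert res.p_value == pytest.approx(2 * 0.5**5)


@pytest.mark.parametrize("b,c", [(0, 0), (1, 0), (3, 3), (7, 2), (12, 8), (0, 20)])
def test_mcnemar_matches_binomial_enumeration(b, c):
    a_flags = [True] * b + [False] * c + [True] * 4
    b_flags = [False] * b + [True] * c + [True] * 4
    truth = [True] * (b + c + 4)
    res = mcnemar_paired(a_flags, b_flags, truth, "diseased")
    assert res.p_value == pytest.approx(_mcnemar_oracle(b, c), abs=1e-12)


def test_mcnemar_agrees_with_statsmodels_exact():
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

    b, c = 9, 3
    table = [[10, b], [c, 20]]
    expected = sm_mcnemar(table, exact=True).pvalue
    a_flags = [True] * b + [False] * c
    b_flags = [False] * b + [True] * c
    res = mcnemar_paired(a_flags, b_flags, [True] * (b + c), "diseased")
    assert res.p_value == pytest.approx(float(expected), abs=1e-12)


def test_mcnemar_stratum_restricts_pairs():
    a = [True, True, False, False]
    b = [False, False, True, True]
    truth = [True, False, True, False]
    diseased = mcnemar_paired(a, b, truth, "diseased")
    assert (diseased.b, diseased.c) == (1, 1)
    non = mcnemar_paired(a, b, truth, "non_diseased")
    assert (non.b, non.c) == (1, 1)


# --- correctly triaged -----------------------------------------------------

def _sepsis_label():
    return SepsisLabel(suspected_infection=True, sofa_total=4, sepsis=True,
                       septic_shock=False)


def _negative_label():
    return SepsisLabel(suspected_infection=False, sofa_total=0, sepsis=False,
                       septic_shock=False)


def test_correctly_triaged_category_margins():
    """Sepsis per category green 10 / yellow 51 / orange 38 /
    possible-sepsis 59 / red 31 gives 128 of 189 correctly triaged."""
    counts = {"green": 10, "yellow": 51, "orange": 38, "possible_sepsis": 59,
              "red": 31}
    records, labels = [], []
    for cat, n in counts.items():
        for _ in range(n):
            records.append(make_record(cat))
            labels.append(_sepsis_label())
    est = correctly_triaged(records, labels)
    assert est.value == pytest.approx(128 / 189)


def test_correctly_triaged_undefined_without_sepsis():
    records = [make_record("red")]
    assert not correctly_triaged(records, [_negative_label()]).defined


def test_correctly_triaged_all_red_is_one():
    records = [make_record("red") for _ in range(5)]
    labels = [_sepsis_label() for _ in range(5)]
    assert correctly_triaged(records, labels).value == 1.0


# --- formatting ------------------------------------------------------------

@pytest.mark.parametrize(
    "x,nd,expected",
    [(47.6190, 1, 47.6), (0.7349, 2, 0.73), (74.55, 1, 74.6), (2.5, 0, 3.0),
     (99.045, 1, 99.0), (88.09, 1, 88.1)],
)
def test_round_half_up(x, nd, expected):
    assert round_half_up(x, nd) == expected


def test_interval_ordering_enforced():
    with pytest.raises(ValueError):
        Interval(0.6, 0.4)
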