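"""Sample-size calculation for diagnostic-accuracy studies (Buderer).

The number of cases needed to estimate a sensitivity Se within an
absolute error d at confidence level 1-alpha is

    n_cases = ceil(z^2 * Se * (1 - Se) / d^2)

with z the standard-normal quantile at 1 - alpha/2; dividing by the
expected prevalence (and taking the ceiling) gives the total screening
cohort required.  The specificity side is analogous with 1 - prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats

__all__ = ["SampleSizeSpec", "SampleSizeResult", "buderer_sample_size"]


@dataclass(frozen=True)
class SampleSizeSpec:
    expected_sensitivity: float
    max_error_d: float            # CI half-width, absolute proportion
    prevalence: float
    expected_specificity: Optional[float] = None
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.expected_sensitivity < 1:
            raise ValueError("expected_sensitivity must be in (0, 1)")
        if self.expected_specificity is not None and not 0 < self.expected_specificity < 1:
            raise ValueError("expected_specificity must be in (0, 1)")
        if self.max_error_d <= 0:
            raise ValueError("max_error_d must be > 0")
        if not 0 < self.prevalence <= 1:
            raise ValueError("prevalence must be in (0, 1]")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")


@dataclass(frozen=True)
class SampleSizeResult:
    n_cases: int
    n_total_for_sensitivity: int
    n_controls: Optional[int]
    n_total_for_specificity: Optional[int]
    n_minimum: int


def _side(p: float, d: float, z: float) -> int:
    return math.ceil(z * z * p * (1 - p) / (d * d))


def buderer_sample_size(spec: SampleSizeSpec) -> SampleSizeResult:
    """Minimum case, control and total cohort sizes for target precision.

    ``n_minimum`` is the larger of the two required totals.  At
    prevalence 1 there are no controls and the specificity side is
    reported as ``None``.
    """
    z = float(stats.norm.ppf(0.5 + spec.level / 2))
    n_cases = _side(spec.expected_sensitivity, spec.max_error_d, z)
    n_total_sens = math.ceil(n_cases / spec.prevalence)

    if spec.expected_specificity is None or spec.prevalence == 1.0:
        n_controls = None
        n_total_spec = None
        n_minimum = n_total_sens
    else:
        n_controls = _side(spec.expected_specificity, spec.max_error_d, z)
        n_total_spec = math.ceil(n_controls / (1 - spec.prevalence))
        n_minimum = max(n_total_sens, n_total_spec)

    return SampleSizeResult(
        n_cases=n_cases,
        n_total_for_sensitivity=n_total_sens,
        n_controls=n_controls,
        n_total_for_specificity=n_total_spec,
        n_minimum=n_minimum,
    )
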