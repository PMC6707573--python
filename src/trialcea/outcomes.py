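"""Clinical and utility outcomes: symptom-free status, QALYs, descriptives.

Symptom-free status is a remission indicator on the 10-item Perceived
Stress Scale (PSS-10, integer 0-40, higher = more stress): a follow-up
score more than two baseline standard deviations below the baseline sample
mean. QALYs are the trapezoidal area under the health-utility curve across
the three assessment weeks, converted to years with a 52-week year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trial_data import Timepoints


@dataclass(frozen=True)
class OutcomeConfig:
    baseline_mean: float = 25.52
    baseline_sd: float = 3.91
    sd_multiplier: float = 2.0
    timepoints: Timepoints = field(default_factory=Timepoints)
    qaly_instrument: str = "SF6D"  # or "EQ5D"

    @property
    def symptom_free_threshold(self) -> float:
        """PSS score strictly below this counts as symptom-free
        (25.52 - 2 x 3.91 = 17.70 at the defaults)."""
        return self.baseline_mean - self.sd_multiplier * self.baseline_sd


def symptom_free(pss_t3: float, config: OutcomeConfig = OutcomeConfig()) -> bool:
    """Remission at follow-up: PSS strictly below mean - k*SD.

    The boundary is non-integer at the defaults (17.70), so strict vs
    non-strict inequality is immaterial for integer PSS scores.
    """
    if pss_t3 is None or (isinstance(pss_t3, float) and math.isnan(pss_t3)):
        raise ValueError("follow-up PSS missing; impute before classification")
    return pss_t3 < config.symptom_free_threshold


def qaly_auc(
    utilities: tuple[float, float, float],
    timepoints: Timepoints = Timepoints(),
) -> float:
    """Trapezoidal QALY over the trial horizon.

    Utility 1.0 at all three assessments over the 6-month (26-week) horizon
    accrues exactly 0.5 QALY.
    """
    u = np.asarray(utilities, dtype=float)
    if np.isnan(u).any():
        raise ValueError("all three utilities required; impute first")
    weeks = np.array([timepoints.t1_week, timepoints.t2_week, timepoints.t3_week])
    return float(np.trapezoid(u, weeks) / timepoints.weeks_per_year)


def nnt(p_treat: float, p_control: float) -> float:
    """Number needed to treat: reciprocal of the risk difference."""
    for p in (p_treat, p_control):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion out of [0,1]: {p}")
    diff = p_treat - p_control
    if diff == 0:
        raise ZeroDivisionError("risk difference is zero; NNT undefined")
    return 1.0 / diff


def chisq_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table
    [[a, b], [c, d]]; returns (statistic, p-value)."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("cell counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin; chi-square undefined")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def mean_change(
    records,
    arm: str,
    timepair: tuple[str, str] = ("T1", "T3"),
) -> tuple[float, float]:
    """Mean and SD of the PSS improvement (pre - post) within one arm.

    Expects post-imputation records (every score present).
    """
    pre_t, post_t = timepair
    changes = [
        r.pss[pre_t] - r.pss[post_t] for r in records if r.arm == arm
    ]
    if not changes:
        raise ValueError(f"no participants in arm {arm!r}")
    arr = np.asarray(changes, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def format_percent(numerator: float, denominator: float, ndigits: int = 1) -> str:
    """Render a proportion the way trial reports print it, e.g. '59.8%'."""
    return f"{100.0 * numerator / denominator:.{ndigits}f}%"
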