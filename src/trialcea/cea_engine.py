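"""Bootstrapped incremental cost-effectiveness analysis.

Incremental costs and effects come from a seemingly-unrelated-regression
(SUR) model of the cost and effect equations on an intercept plus arm
indicator. With identical regressor sets SUR coincides with
equation-by-equation least squares, so the point estimates equal the
arm-mean differences; the cross-equation residual correlation is reported.

Sampling uncertainty is handled by nonparametric bootstrapping: draws
resample participants with replacement *within arm* (preserving the 1:1
design), refit the SUR, and are stacked equally across the m
multiply-imputed datasets. The resulting (delta cost, delta effect) cloud
yields the cost-effectiveness plane quadrant distribution, percentile
confidence intervals, the ICER with dominance semantics, and the
cost-effectiveness acceptability curve (CEAC) by net-monetary-benefit
counting: at willingness-to-pay ceiling lambda, the probability of
cost-effectiveness is the fraction of draws with lambda*dE - dC > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costing import RECURRING_CATEGORIES
from .outcomes import OutcomeConfig
from .trial_data import Timepoints, UnitCostTable

SCENARIOS = (
    "main",
    "no_inpatient",
    "intervention_plus_100",
    "intervention_minus_100",
    "eq5d",
)

#: default willingness-to-pay grids (EUR per effect unit)
WTP_GRID_SYMPTOM_FREE = tuple(range(0, 5001, 100))
WTP_GRID_QALY = tuple(range(0, 50001, 500))


@dataclass
class SurFit:
    delta_cost: float
    delta_effect: float
    residual_correlation: float


@dataclass
class IncrementalCloud:
    """B paired bootstrap draws of (delta cost, delta effect) plus the
    pooled point estimates."""

    delta_costs: np.ndarray
    delta_effects: np.ndarray
    delta_cost_hat: float
    delta_effect_hat: float
    effect_kind: str
    seed: int

    @property
    def B(self) -> int:
        return self.delta_costs.size

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("cloud needs at least one draw")
        if not (np.isfinite(self.delta_costs).all() and np.isfinite(self.delta_effects).all()):
            raise ValueError("cloud draws must be finite")


@dataclass
class CeacCurve:
    wtp: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.wtp) <= 0):
            raise ValueError("WTP grid must be strictly increasing")


@dataclass
class PlaneDistribution:
    """Percentage of bootstrap draws per cost-effectiveness-plane quadrant."""

    ne: float
    se: float
    sw: float
    nw: float

    def as_dict(self) -> dict[str, float]:
        return {"NE": self.ne, "SE": self.se, "SW": self.sw, "NW": self.nw}


# --------------------------------------------------------------------------
# effect and cost columns on a completed analysis frame
# --------------------------------------------------------------------------


def effect_column(
    df: pd.DataFrame,
    effect_kind: str,
    outcome_config: OutcomeConfig = OutcomeConfig(),
) -> np.ndarray:
    """Per-participant effect values on a completed (post-imputation) frame."""
    tp = outcome_config.timepoints
    if effect_kind == "pss":
        return (df["pss_T1"] - df["pss_T3"]).to_numpy(dtype=float)
    if effect_kind == "symptomfree":
        return (
            df["pss_T3"].to_numpy(dtype=float) < outcome_config.symptom_free_threshold
        ).astype(float)
    if effect_kind in ("qaly", "qaly_eq5d"):
        prefix = "eq5d" if effect_kind == "qaly_eq5d" else "sf6d"
        u1 = df[f"{prefix}_T1"].to_numpy(dtype=float)
        u2 = df[f"{prefix}_T2"].to_numpy(dtype=float)
        u3 = df[f"{prefix}_T3"].to_numpy(dtype=float)
        if np.isnan(u1).any() or np.isnan(u2).any() or np.isnan(u3).any():
            raise ValueError("utilities contain missing values; impute first")
        w12 = tp.t2_week - tp.t1_week
        w23 = tp.t3_week - tp.t2_week
        return ((u1 + u2) / 2 * w12 + (u2 + u3) / 2 * w23) / tp.weeks_per_year
    raise ValueError(f"unknown effect kind {effect_kind!r}")


def total_cost_column(
    df: pd.DataFrame,
    unit_costs: UnitCostTable,
    exclude_categories: frozenset[str] = frozenset(),
    intervention_offset: float = 0.0,
) -> np.ndarray:
    """Per-participant 6-month total cost under the scenario options.

    Window-level category costs are cumulated by the trapezoid rule
    (W1 + W3 over the 6-month horizon); the flat intervention tariff is a
    one-off added to the treatment arm.
    """
    total = np.zeros(len(df))
    for cat in RECURRING_CATEGORIES:
        if cat in exclude_categories:
            continue
        w1 = df[f"cost_{cat}_W1"].to_numpy(dtype=float)
        w3 = df[f"cost_{cat}_W3"].to_numpy(dtype=float)
        if np.isnan(w1).any() or np.isnan(w3).any():
            raise ValueError(f"cost category {cat!r} has missing windows; impute first")
        total += w1 + w3
    if "intervention" not in exclude_categories:
        total += df["arm01"].to_numpy(dtype=float) * (
            unit_costs.intervention_price + intervention_offset
        )
    return total


# --------------------------------------------------------------------------
# SUR fit and bootstrap
# --------------------------------------------------------------------------


def fit_sur(costs: np.ndarray, effects: np.ndarray, arm01: np.ndarray) -> SurFit:
    """Joint cost/effect regressions on intercept + arm indicator.

    With identical regressors the SUR point estimates equal the group-mean
    differences; the residual cross-equation correlation is reported (0 when
    either equation has no residual variance).
    """
    arm01 = np.asarray(arm01, dtype=float)
    if len(np.unique(arm01)) < 2:
        raise ValueError("both arms required")
    treat = arm01 == 1.0
    delta_cost = float(costs[treat].mean() - costs[~treat].mean())
    delta_effect = float(effects[treat].mean() - effects[~treat].mean())
    resid_c = costs - np.where(treat, costs[treat].mean(), costs[~treat].mean())
    resid_e = effects - np.where(treat, effects[treat].mean(), effects[~treat].mean())
    sc, se_ = resid_c.std(), resid_e.std()
    corr = float(np.corrcoef(resid_c, resid_e)[0, 1]) if sc > 0 and se_ > 0 else 0.0
    return SurFit(delta_cost, delta_effect, corr)


def bootstrap_cloud(
    completed: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    effect_kind: str,
    B: int = 5000,
    seed: int = 0,
) -> IncrementalCloud:
    """Stratified nonparametric bootstrap of the SUR deltas.

    ``completed`` holds one (costs, effects, arm01) triple per imputed
    dataset; the B draws are allocated round-robin across them so each
    contributes equally. Resampling is with replacement within arm. The
    point estimates pool (average) the per-dataset SUR fits.

    The resample indices depend only on (arm sizes, B, seed), so two clouds
    built from the same datasets and seed — e.g. under different scenario
    cost options — pair draw-for-draw.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    m = len(completed)
    fits = [fit_sur(c, e, a) for c, e, a in completed]
    hat_c = float(np.mean([f.delta_cost for f in fits]))
    hat_e = float(np.mean([f.delta_effect for f in fits]))

    rng = np.random.default_rng(seed)
    dc = np.empty(B)
    de = np.empty(B)
    pos = 0
    for j, (costs, effects, arm01) in enumerate(completed):
        b_j = B // m + (1 if j < B % m else 0)
        if b_j == 0:
            continue
        treat = np.flatnonzero(arm01 == 1.0)
        ctrl = np.flatnonzero(arm01 != 1.0)
        ti = treat[rng.integers(0, treat.size, size=(b_j, treat.size))]
        ci = ctrl[rng.integers(0, ctrl.size, size=(b_j, ctrl.size))]
        dc[pos : pos + b_j] = costs[ti].mean(axis=1) - costs[ci].mean(axis=1)
        de[pos : pos + b_j] = effects[ti].mean(axis=1) - effects[ci].mean(axis=1)
        pos += b_j
    return IncrementalCloud(dc, de, hat_c, hat_e, effect_kind, seed)


# --------------------------------------------------------------------------
# decision statistics
# --------------------------------------------------------------------------


def icer(delta_cost: float, delta_effect: float) -> float | str:
    """ICER with dominance semantics.

    More effect at less cost -> "dominant"; less effect at more cost ->
    "dominated"; zero effect difference is undefined and raised, never a
    silent NaN; otherwise the plain ratio.
    """
    if delta_effect == 0:
        raise ZeroDivisionError("ICER undefined: zero incremental effect")
    if delta_effect > 0 and delta_cost < 0:
        return "dominant"
    if delta_effect < 0 and delta_cost > 0:
        return "dominated"
    return delta_cost / delta_effect

def plane_distribution(cloud: IncrementalCloud) -> PlaneDistribution:
    """Quadrant shares (%) of the bootstrap cloud.

    East/west by the sign of the effect (zero effects count east, the
    positive-effect side); north/south by the sign of the cost (zero costs
    count south). Each draw is counted exactly once, so shares sum to 100.
    """
    e = cloud.delta_effects
    c = cloud.delta_costs
    east = e >= 0
    north = c > 0
    n = cloud.B
    return PlaneDistribution(
        ne=float(100.0 * np.count_nonzero(east & north) / n),
        se=float(100.0 * np.count_nonzero(east & ~north) / n),
        sw=float(100.0 * np.count_nonzero(~east & ~north) / n),
        nw=float(100.0 * np.count_nonzero(~east & north) / n),
    )


def ceac(cloud: IncrementalCloud, wtp_grid) -> CeacCurve:
    """Probability of cost-effectiveness per WTP ceiling, by counting draws
    with positive net monetary benefit lambda*dE - dC."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if np.any(grid < 0) or not np.isfinite(grid).all():
        raise ValueError("WTP grid must be finite and nonnegative")
    nmb = grid[:, None] * cloud.delta_effects[None, :] - cloud.delta_costs[None, :]
    return CeacCurve(wtp=grid, probability=(nmb > 0).mean(axis=1))


def percentile_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Percentile-method bootstrap interval (linear interpolation between
    order statistics)."""
    values = np.asarray(values, dtype=float)
    if values.size < 20:
        warnings.warn(
            "fewer than 20 bootstrap draws; percentile interval is unreliable",
            stacklevel=2,
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def icer_interval(cloud: IncrementalCloud, level: float = 0.95) -> dict:
    """ICER uncertainty statement following the dominance-label convention.

    A ratio whose bootstrap cloud spans quadrants has no well-defined CI, so
    the lower end is the label "dominant" whenever draws fall in the
    south-east quadrant, and the upper end is the upper percentile of the
    ratios among north-east draws ("dominant to X"); with no north-east
    draws both ends are dominant.
    """
    e, c = cloud.delta_effects, cloud.delta_costs
    se_mask = (e > 0) & (c < 0)
    ne_mask = (e > 0) & (c > 0)
    upper_q = 1.0 - (1.0 - level) / 2.0
    out: dict = {"point": None, "lower": None, "upper": None}
    try:
        out["point"] = icer(cloud.delta_cost_hat, cloud.delta_effect_hat)
    except ZeroDivisionError:
        out["point"] = "undefined"
    out["lower"] = "dominant" if se_mask.any() else (
        float(np.quantile(c[ne_mask] / e[ne_mask], (1.0 - level) / 2.0))
        if ne_mask.any()
        else "undefined"
    )
    out["upper"] = (
        float(np.quantile(c[ne_mask] / e[ne_mask], upper_q))
        if ne_mask.any()
        else "dominant"
    )
    return out


# --------------------------------------------------------------------------
# scenarios
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    name: str
    exclude_categories: frozenset[str] = frozenset()
    intervention_offset: float = 0.0
    effect_kinds: tuple[str, ...] = ("pss", "symptomfree", "qaly")


def scenario_spec(name: str) -> Scenario:
    if name == "main":
        return Scenario("main")
    if name == "no_inpatient":
        return Scenario("no_inpatient", exclude_categories=frozenset({"inpatient"}))
    if name == "intervention_plus_100":
        return Scenario("intervention_plus_100", intervention_offset=100.0)
    if name == "intervention_minus_100":
        return Scenario("intervention_minus_100", intervention_offset=-100.0)
    if name == "eq5d":
        return Scenario("eq5d", effect_kinds=("qaly_eq5d",))
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")


def run_scenario(
    completed_frames: list[pd.DataFrame],
    scenario: str,
    unit_costs: UnitCostTable,
    B: int = 5000,
    seed: int = 0,
    outcome_config: OutcomeConfig = OutcomeConfig(),
    wtp_grids: dict[str, tuple] | None = None,
) -> dict:
    """Full decision analysis for one scenario on the m completed datasets.

    Returns, per effect kind: pooled incremental cost and effect with
    percentile CIs, the ICER with dominance labels, the plane quadrant
    distribution, and the CEAC. All effect kinds share one set of resample
    indices (same seed), so incremental-cost draws are identical across the
    rows of a scenario, as in a standard trial report.
    """
    spec = scenario_spec(scenario)
    grids = {
        "pss": WTP_GRID_SYMPTOM_FREE,
        "symptomfree": WTP_GRID_SYMPTOM_FREE,
        "qaly": WTP_GRID_QALY,
        "qaly_eq5d": WTP_GRID_QALY,
    }
    if wtp_grids:
        grids.update(wtp_grids)

    missing_cols = [
        c
        for c in (
            ("eq5d_T1", "eq5d_T2", "eq5d_T3") if "qaly_eq5d" in spec.effect_kinds else ()
        )
        if c not in completed_frames[0].columns
    ]
    if missing_cols:
        raise ValueError(
            f"scenario {scenario!r} needs columns {missing_cols} which are absent"
        )

    results: dict = {"scenario": scenario, "B": B, "seed": seed, "effects": {}}
    for kind in spec.effect_kinds:
        triples = []
        for frame in completed_frames:
            costs = total_cost_column(
                frame,
                unit_costs,
                exclude_categories=spec.exclude_categories,
                intervention_offset=spec.intervention_offset,
            )
            effects = effect_column(frame, kind, outcome_config)
            triples.append((costs, effects, frame["arm01"].to_numpy(dtype=float)))
        cloud = bootstrap_cloud(triples, kind, B=B, seed=seed)
        quad = plane_distribution(cloud)
        curve = ceac(cloud, grids[kind])
        ci_c = percentile_ci(cloud.delta_costs)
        ci_e = percentile_ci(cloud.delta_effects)
        results["effects"][kind] = {
            "delta_cost": cloud.delta_cost_hat,
            "delta_cost_ci": ci_c,
            "delta_effect": cloud.delta_effect_hat,
            "delta_effect_ci": ci_e,
            "icer": icer_interval(cloud),
            "plane": quad.as_dict(),
            "ceac": curve,
            "cloud": cloud,
        }
    return results
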