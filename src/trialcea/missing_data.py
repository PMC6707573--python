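"""Intention-to-treat imputation.

Clinical outcomes (follow-up PSS and utilities) get *multiple* imputation:
m completed copies drawn from a Bayesian normal linear model — for each
incomplete column, regress on the baseline predictor set among observed
rows, draw (sigma^2, beta) from the approximate posterior, and impute
predicted values plus residual noise. Costs get single *regression*
imputation: deterministic predicted values from an ordinary least-squares
fit, floored at zero. Observed values are never altered by either routine.

Both routines work on the wide per-participant *analysis frame* built by
:func:`build_analysis_frame`: one row per participant with outcome scores
and per-window per-category costs, which is what the decision analysis
downstream consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .costing import (
    DEFAULT_DRUG_PRICES,
    RECURRING_CATEGORIES,
    DrugPriceTable,
    window_costs,
)
from .trial_data import ParticipantRecord, UnitCostTable

logger = logging.getLogger("trialcea")

#: outcome columns eligible for multiple imputation
OUTCOME_COLS = ("pss_T2", "pss_T3", "sf6d_T2", "sf6d_T3", "eq5d_T2", "eq5d_T3")

#: baseline predictors used by all imputation models (and the dropout model)
PREDICTOR_COLS = ("arm01", "pss_T1", "sf6d_T1", "baseline_total_cost", "wage")

#: admissible ranges for imputed outcome values
_RANGES = {
    "pss_T2": (0.0, 40.0),
    "pss_T3": (0.0, 40.0),
    "sf6d_T2": (0.0, 1.0),
    "sf6d_T3": (0.0, 1.0),
    "eq5d_T2": (-0.59, 1.0),
    "eq5d_T3": (-0.59, 1.0),
}


@dataclass(frozen=True)
class ImputationConfig:
    m_outcome: int = 10
    seed: int = 0
    predictors: tuple[str, ...] = PREDICTOR_COLS

    def __post_init__(self) -> None:
        if self.m_outcome < 1:
            raise ValueError("m_outcome must be >= 1")


def build_analysis_frame(
    records: list[ParticipantRecord],
    unit_costs: UnitCostTable,
    drug_prices: DrugPriceTable = DEFAULT_DRUG_PRICES,
) -> pd.DataFrame:
    """One row per participant: scores, wage, and per-window category costs.

    Missing scores and missing recall windows become NaN cells; the frame is
    the input to both imputation routines and the decision analysis.
    """
    rows = []
    for rec in records:
        row: dict = {
            "id": rec.id,
            "arm": rec.arm,
            "arm01": 1.0 if rec.arm == "ISMI" else 0.0,
            "wage": rec.gross_monthly_wage,
            "dropout": rec.dropout,
        }
        for t in ("T1", "T2", "T3"):
            row[f"pss_{t}"] = np.nan if rec.pss[t] is None else float(rec.pss[t])
            row[f"sf6d_{t}"] = (
                np.nan if rec.utility_sf6d[t] is None else rec.utility_sf6d[t]
            )
            row[f"eq5d_{t}"] = (
                np.nan if rec.utility_eq5d[t] is None else rec.utility_eq5d[t]
            )
        for w in ("W1", "W3"):
            win = rec.resource_use.get(w)
            if win is None:
                for cat in RECURRING_CATEGORIES:
                    row[f"cost_{cat}_{w}"] = np.nan
            else:
                wc = window_costs(win, unit_costs, rec.gross_monthly_wage, drug_prices)
                for cat in RECURRING_CATEGORIES:
                    row[f"cost_{cat}_{w}"] = wc[cat]
        rows.append(row)
    df = pd.DataFrame(rows)
    df["baseline_total_cost"] = df[[f"cost_{c}_W1" for c in RECURRING_CATEGORIES]].sum(
        axis=1
    )
    return df


def _design(df: pd.DataFrame, predictors) -> np.ndarray:
    return np.column_stack(
        [np.ones(len(df))] + [df[p].to_numpy(dtype=float) for p in predictors]
    )


def _check_predictors(df: pd.DataFrame, predictors) -> None:
    for p in predictors:
        if p not in df.columns:
            raise ValueError(f"predictor column {p!r} missing")
        if df[p].isna().all():
            raise ValueError(f"predictor column {p!r} is entirely missing")
        if df[p].isna().any():
            raise ValueError(
                f"predictor column {p!r} has missing values; "
                "imputation predictors must be complete at baseline"
            )


def impute_outcomes(
    df: pd.DataFrame, config: ImputationConfig = ImputationConfig()
) -> list[pd.DataFrame]:
    """Multiple imputation of missing outcome scores.

    Returns ``m_outcome`` completed copies. For each incomplete outcome
    column a normal linear model is fit on the observed rows; each copy
    imputes with a fresh posterior draw of the coefficients and residual
    variance, so imputations vary across copies while observed values are
    untouched. Imputed values are clamped to the instrument's range and PSS
    scores are rounded to integers.
    """
    targets = [c for c in OUTCOME_COLS if c in df.columns and df[c].isna().any()]
    if targets:
        _check_predictors(df, config.predictors)
    rng = np.random.default_rng(config.seed)
    completed: list[pd.DataFrame] = []
    for _ in range(config.m_outcome):
        out = df.copy()
        for col in targets:
            obs = df[col].notna()
            X = _design(df.loc[obs], config.predictors)
            y = df.loc[obs, col].to_numpy(dtype=float)
            n, k = X.shape
            if n <= k:
                raise ValueError(f"too few observed rows to impute {col!r}")
            beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta_hat
            dof = n - k
            sigma2_hat = float(resid @ resid) / dof
            # posterior draws: sigma^2 from scaled inverse chi-square, then
            # beta | sigma^2 ~ N(beta_hat, sigma^2 (X'X)^-1)
            sigma2 = sigma2_hat * dof / rng.chisquare(dof)
            xtx_inv = np.linalg.pinv(X.T @ X)
            cov = sigma2 * (xtx_inv + xtx_inv.T) / 2.0  # enforce symmetry
            beta = rng.multivariate_normal(
                beta_hat, cov, check_valid="ignore", method="svd"
            )
            miss = df[col].isna()
            Xm = _design(df.loc[miss], config.predictors)
            draws = Xm @ beta + rng.normal(0.0, np.sqrt(sigma2), miss.sum())
            lo, hi = _RANGES[col]
            draws = np.clip(draws, lo, hi)
            if col.startswith("pss_"):
                draws = np.rint(draws)
            out.loc[miss, col] = draws
        completed.append(out)
    return completed


def impute_costs(
    df: pd.DataFrame, config: ImputationConfig = ImputationConfig()
) -> pd.DataFrame:
    """Regression imputation of missing follow-up-window category costs.

    Deterministic predicted values from an OLS fit on arm, the same
    category's baseline-window cost, baseline total cost and wage, floored
    at zero. Falls back to arm-mean imputation (with a logged warning) when
    the design is singular.
    """
    out = df.copy()
    for cat in RECURRING_CATEGORIES:
        col = f"cost_{cat}_W3"
        if col not in df.columns or not df[col].isna().any():
            continue
        predictors = ["arm01", f"cost_{cat}_W1", "baseline_total_cost", "wage"]
        _check_predictors(df, predictors)
        obs = df[col].notna()
        miss = ~obs
        X = _design(df.loc[obs], predictors)
        y = df.loc[obs, col].to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            logger.warning(
                "singular design imputing %s; falling back to arm means", col
            )
            arm_means = df.loc[obs].groupby("arm01")[col].mean()
            preds = df.loc[miss, "arm01"].map(arm_means).to_numpy(dtype=float)
        else:
            model = sm.OLS(y, X).fit()
            Xm = _design(df.loc[miss], predictors)
            preds = model.predict(Xm)
        out.loc[miss, col] = np.maximum(preds, 0.0)
    return out


@dataclass
class DropoutFit:
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    separation: bool = False


def dropout_model(
    df: pd.DataFrame, predictors: tuple[str, ...] = PREDICTOR_COLS
) -> DropoutFit:
    """Logistic regression of dropout on the baseline predictor set.

    Used for reporting predictors of attrition, not for weighting. Perfect
    separation (e.g. dropout deterministic in one arm) is flagged rather
    than raised.
    """
    y = df["dropout"].astype(float).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one dropout and one completer")
    _check_predictors(df, predictors)
    X = pd.DataFrame(
        _design(df, predictors), columns=["const", *predictors], index=df.index
    )
    separation = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if not fit.mle_retvals.get("converged", True) or np.abs(
            fit.params.to_numpy()
        ).max() > 1e3:
            separation = True
        params, bse, z = fit.params, fit.bse, fit.tvalues
    except Exception:  # statsmodels raises PerfectSeparationError and kin
        separation = True
        params = pd.Series(np.nan, index=X.columns)
        bse = pd.Series(np.nan, index=X.columns)
        z = pd.Series(np.nan, index=X.columns)
    return DropoutFit(params=params, bse=bse, zvalues=z, separation=separation)
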