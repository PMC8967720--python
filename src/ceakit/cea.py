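"""Within-trial cost-utility analysis.

Covariate-adjusted incremental costs and QALYs from generalised linear
models, ICER / dominance classification, within-arm case-resampling
bootstrap, cost-effectiveness acceptability curves and net monetary
benefit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

FAMILIES = ("gaussian_identity", "gamma_log")

#: default willingness-to-pay grid, GBP per QALY
DEFAULT_LAMBDA_GRID = np.arange(0, 50_001, 500, dtype=float)


@dataclass(frozen=True)
class ICERResult:
    """Dominance label or ICER, optionally rounded to a reporting granularity."""

    label: str
    value: float | None = None
    rounded: float | None = None

    def __str__(self) -> str:
        if self.value is None:
            return self.label
        shown = self.rounded if self.rounded is not None else self.value
        return f"£{shown:,.0f} per QALY"


@dataclass
class CEEstimate:
    """Incremental cost and QALYs (intervention minus control)."""

    delta_cost: float
    delta_qaly: float
    ci_cost: tuple[float, float] | None = None
    ci_qaly: tuple[float, float] | None = None
    icer: ICERResult | None = None


@dataclass
class CEACCurve:
    """Probability cost-effective over a willingness-to-pay grid."""

    lambda_grid: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        if self.lambda_grid.size == 0:
            raise ValueError("lambda grid must be non-empty")
        if np.any(np.diff(self.lambda_grid) <= 0):
            raise ValueError("lambda grid must be strictly increasing")
        if self.lambda_grid.shape != self.probability.shape:
            raise ValueError("grid and probability lengths differ")
        if ((self.probability < 0) | (self.probability > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lambda": self.lambda_grid, "probability": self.probability}
        )


def net_monetary_benefit(delta_cost: float, delta_qaly: float, lam: float) -> float:
    """lambda x delta_QALY - delta_cost."""
    if lam < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return lam * delta_qaly - delta_cost


def classify_icer(
    delta_cost: float, delta_qaly: float, rounding: float | None = None
) -> ICERResult:
    """Dominance label or ICER for an incremental (cost, QALY) pair.

    Cheaper-and-better is dominant, dearer-and-worse is dominated;
    otherwise the ICER is reported raw and, if requested, rounded
    half-up to the given money granularity.
    """
    if delta_qaly == 0:
        if delta_cost > 0:
            return ICERResult("dominated (no QALY gain)")
        if delta_cost < 0:
            return ICERResult("cost saving (no QALY change)")
        return ICERResult("indifferent")
    if delta_cost < 0 and delta_qaly > 0:
        return ICERResult("dominant")
    if delta_cost > 0 and delta_qaly < 0:
        return ICERResult("dominated")
    raw = delta_cost / delta_qaly
    rounded = None
    if rounding is not None:
        if rounding <= 0:
            raise ValueError("rounding granularity must be > 0")
        rounded = float(np.floor(raw / rounding + 0.5) * rounding)
    return ICERResult("icer", value=raw, rounded=rounded)


def _design(
    frame: pd.DataFrame, arm: str, covariates: Sequence[str]
) -> tuple[np.ndarray, int]:
    """Design matrix [intercept | arm | covariates]; categoricals dummy-coded.

    Returns the matrix and the column index of the arm indicator (always 1).
    """
    cols = [np.ones(len(frame)), frame[arm].to_numpy(dtype=float)]
    for cov in covariates:
        series = frame[cov]
        if pd.api.types.is_numeric_dtype(series):
            cols.append(series.to_numpy(dtype=float))
        else:
            dummies = pd.get_dummies(series, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
    return np.column_stack(cols), 1


def _ols_arm_effect(X: np.ndarray, y: np.ndarray, arm_idx: int) -> tuple[float, float]:
    """Arm coefficient and its classical variance from OLS normal equations."""
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        raise ValueError("more parameters than observations")
    sigma2 = (resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(xtx)
    return float(beta[arm_idx]), float(cov[arm_idx, arm_idx])


def adjusted_increment(
    frame: pd.DataFrame,
    outcome: str,
    arm: str = "arm",
    covariates: Sequence[str] = (),
    family: str = "gaussian_identity",
) -> tuple[float, float]:
    """Adjusted between-arm difference in an outcome and its variance.

    ``gaussian_identity`` returns the arm coefficient of a linear model.
    ``gamma_log`` fits a Gamma GLM with log link and returns the average
    marginal effect of arm (mean difference between everyone-treated and
    everyone-control predictions), with a delta-method variance.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    y = frame[outcome].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("outcome has missing values; impute first")
    X, arm_idx = _design(frame, arm, covariates)

    if family == "gaussian_identity":
        return _ols_arm_effect(X, y, arm_idx)

    if (y <= 0).any():
        raise ValueError(
            "gamma_log requires strictly positive outcomes; "
            "use family='gaussian_identity'"
        )
    res = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log())).fit()
    X1 = X.copy()
    X1[:, arm_idx] = 1.0
    X0 = X.copy()
    X0[:, arm_idx] = 0.0
    mu1 = np.exp(X1 @ res.params)
    mu0 = np.exp(X0 @ res.params)
    ame = float(np.mean(mu1 - mu0))
    # delta method: gradient of the AME w.r.t. beta
    grad = (X1 * mu1[:, None] - X0 * mu0[:, None]).mean(axis=0)
    var = float(grad @ res.cov_params() @ grad)
    return ame, var


@dataclass
class BootstrapResult:
    """Joint (delta_cost, delta_qaly) bootstrap draws and derived intervals."""

    draws: np.ndarray  # (B, 2) columns: delta_cost, delta_qaly
    ci_cost: tuple[float, float]
    ci_qaly: tuple[float, float]
    icer_ci: tuple[float, float] | None
    icer_ci_method: str


def bootstrap_ce(
    frame: pd.DataFrame,
    cost_col: str = "total_cost",
    qaly_col: str = "qaly",
    arm: str = "arm",
    covariates: Sequence[str] = (),
    B: int = 10_000,
    seed: int | None = None,
) -> BootstrapResult:
    """Within-arm case-resampling bootstrap of the adjusted increments.

    Each replicate resamples participants with replacement separately in
    each arm and refits the gaussian adjusted-increment models for cost
    and QALYs.  Percentile intervals are reported for each delta; the
    ICER interval uses the ratio percentile when all QALY draws share a
    sign and net-benefit (CEAC) inversion otherwise.
    """
    if B < 100:
        raise ValueError("B < 100 refused: percentile intervals are unstable")
    rng = np.random.default_rng(seed)
    X, arm_idx = _design(frame, arm, covariates)
    Y = frame[[cost_col, qaly_col]].to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("outcomes have missing values; impute first")
    arm_vals = frame[arm].to_numpy(dtype=float)
    idx_by_arm = [np.flatnonzero(arm_vals == a) for a in (0, 1)]
    if any(ix.size == 0 for ix in idx_by_arm):
        raise ValueError("both arms must be non-empty")

    draws = np.empty((B, 2))
    for b in range(B):
        idx = np.concatenate(
            [rng.choice(ix, size=ix.size, replace=True) for ix in idx_by_arm]
        )
        Xb, Yb = X[idx], Y[idx]
        beta = np.linalg.solve(Xb.T @ Xb, Xb.T @ Yb)
        draws[b, 0] = beta[arm_idx, 0]
        draws[b, 1] = beta[arm_idx, 1]

    ci_cost = tuple(np.percentile(draws[:, 0], [2.5, 97.5]))
    ci_qaly = tuple(np.percentile(draws[:, 1], [2.5, 97.5]))
    icer_ci, method = icer_percentile_ci(draws)
    return BootstrapResult(
        draws=draws,
        ci_cost=ci_cost,
        ci_qaly=ci_qaly,
        icer_ci=icer_ci,
        icer_ci_method=method,
    )


def icer_percentile_ci(
    draws: np.ndarray, alpha: float = 0.05
) -> tuple[tuple[float, float] | None, str]:
    """Percentile CI for the ICER from joint (delta_cost, delta_qaly) draws.

    When every QALY draw has the same sign the ratio percentile is well
    defined.  When the cloud spans quadrants the ratio is not monotone,
    so the interval is found on the net-benefit scale: the bounds are the
    thresholds at which the probability of positive net benefit crosses
    alpha/2 and 1 - alpha/2.
    """
    dc, dq = draws[:, 0], draws[:, 1]
    lo_p, hi_p = 100 * alpha / 2, 100 * (1 - alpha / 2)
    if (dq > 0).all():
        lo, hi = np.percentile(dc / dq, [lo_p, hi_p])
        return (float(lo), float(hi)), "ratio_percentile"
    if (dq < 0).all():
        lo, hi = np.percentile(dc / dq, [lo_p, hi_p])
        return (float(lo), float(hi)), "ratio_percentile"
    grid = np.arange(0, 500_001, 50, dtype=float)
    accept = ((grid[:, None] * dq[None, :] - dc[None, :]) > 0).mean(axis=1)
    crosses_lo = np.flatnonzero(accept >= alpha / 2)
    crosses_hi = np.flatnonzero(accept >= 1 - alpha / 2)
    # an interval bound is unbounded when the acceptance curve never
    # reaches the corresponding probability level
    lo = float(grid[crosses_lo[0]]) if crosses_lo.size else float("inf")
    hi = float(grid[crosses_hi[0]]) if crosses_hi.size else float("inf")
    return (lo, hi), "net_benefit_inversion"


def ceac(
    draws: np.ndarray, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID
) -> CEACCurve:
    """Cost-effectiveness acceptability curve from joint delta draws.

    probability(lambda) = fraction of draws with positive net monetary
    benefit at that threshold.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("no draws supplied")
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    dc, dq = draws[:, 0], draws[:, 1]
    nmb = lambda_grid[:, None] * dq[None, :] - dc[None, :]
    return CEACCurve(lambda_grid=lambda_grid, probability=(nmb > 0).mean(axis=1))
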