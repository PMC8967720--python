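"""Multiple imputation by chained equations with predictive mean matching,
and Rubin's-rules pooling.

PMM draws each imputed value from the observed support of its variable:
for every missing cell, the k observed cases whose (Bayesian-drawn)
predicted means are closest to the missing case's predicted mean form a
donor pool, and one donor's observed value is copied.  This guarantees
imputed values are always plausible observed values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ImputationConfig:
    m: int = 50
    k_donors: int = 5
    iterations: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.k_donors < 1:
            raise ValueError("k_donors must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def _bayes_linear_draw(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior draw (beta_hat, beta_draw) for a normal linear model.

    Standard non-informative posterior: sigma^2 from a scaled
    inverse-chi-square, beta ~ N(beta_hat, sigma^2 (X'X)^-1).  A small
    ridge keeps near-collinear sweeps stable.
    """
    n, p = X.shape
    xtx = X.T @ X + 1e-8 * np.eye(p)
    xty = X.T @ y
    beta_hat = np.linalg.solve(xtx, xty)
    resid = y - X @ beta_hat
    df = max(n - p, 1)
    sigma2 = (resid @ resid) / rng.chisquare(df)
    cov = sigma2 * np.linalg.inv(xtx)
    # cholesky with jitter fallback for degenerate designs
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(p))
    beta_draw = beta_hat + chol @ rng.standard_normal(p)
    return beta_hat, beta_draw


def _pmm_one_variable(
    y: np.ndarray,
    X: np.ndarray,
    miss: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Impute the missing entries of ``y`` in place; returns y."""
    obs = ~miss
    beta_hat, beta_draw = _bayes_linear_draw(X[obs], y[obs], rng)
    # type-1 PMM: observed cases scored with beta_hat, missing with the draw
    pred_obs = X[obs] @ beta_hat
    pred_mis = X[miss] @ beta_draw
    k_eff = min(k, obs.sum())
    dist = np.abs(pred_obs[None, :] - pred_mis[:, None])
    donor_idx = np.argpartition(dist, k_eff - 1, axis=1)[:, :k_eff]
    choice = rng.integers(0, k_eff, size=donor_idx.shape[0])
    donors = donor_idx[np.arange(donor_idx.shape[0]), choice]
    y_obs = y[obs]
    y[miss] = y_obs[donors]
    return y


def pmm_impute(
    data: pd.DataFrame,
    impute_vars: Sequence[str],
    predictors: Sequence[str],
    config: ImputationConfig | None = None,
) -> list[pd.DataFrame]:
    """Chained-equation PMM imputation.

    Returns ``config.m`` completed copies of ``data``: observed cells are
    untouched, every imputed cell holds an observed donor value of its
    variable, and results are reproducible given ``config.seed``.
    Variables in ``impute_vars`` may contain missing values; variables in
    ``predictors`` must be fully observed and numeric.
    """
    config = config or ImputationConfig()
    for col in list(impute_vars) + list(predictors):
        if col not in data.columns:
            raise KeyError(f"column {col!r} not in data")
        if not pd.api.types.is_numeric_dtype(data[col]):
            raise ValueError(f"column {col!r} must be numeric for PMM")
    for col in predictors:
        if data[col].isna().any():
            raise ValueError(f"predictor {col!r} has missing values")
    for col in impute_vars:
        if data[col].notna().sum() == 0:
            raise ValueError(f"variable {col!r} has no observed values")

    impute_vars = [c for c in impute_vars]
    needs = [c for c in impute_vars if data[c].isna().any()]
    n = len(data)
    pred_mat = data[list(predictors)].to_numpy(dtype=float)
    intercept = np.ones((n, 1))
    y_all = {c: data[c].to_numpy(dtype=float) for c in impute_vars}
    miss_all = {c: np.isnan(y_all[c]) for c in impute_vars}

    master = np.random.SeedSequence(config.seed)
    completed: list[pd.DataFrame] = []
    for child in master.spawn(config.m):
        rng = np.random.default_rng(child)
        current = {c: y_all[c].copy() for c in impute_vars}
        # initial fill: random draws from the observed support
        for c in needs:
            obs_vals = current[c][~miss_all[c]]
            current[c][miss_all[c]] = rng.choice(obs_vals, size=miss_all[c].sum())
        for _ in range(config.iterations if needs else 0):
            for c in needs:
                others = [v for v in impute_vars if v != c]
                X = np.hstack(
                    [intercept, pred_mat]
                    + [current[v][:, None] for v in others]
                )
                current[c] = _pmm_one_variable(
                    current[c], X, miss_all[c], config.k_donors, rng
                )
        out = data.copy()
        for c in impute_vars:
            out[c] = current[c]
        completed.append(out)
    return completed


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of per-imputation estimates."""

    estimate: float
    within_variance: float
    between_variance: float
    total_variance: float
    degrees_of_freedom: float
    ci_low: float
    ci_high: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_variance))


def pool_estimates(
    estimates: Sequence[tuple[float, float]],
    df_complete: float | None = None,
    alpha: float = 0.05,
) -> PooledEstimate:
    """Pool (estimate, variance) pairs across imputations.

    Total variance is W + (1 + 1/m) B.  Degrees of freedom use the
    classic (m-1)/lambda^2 rule, refined by the Barnard-Rubin
    small-sample adjustment when ``df_complete`` is supplied.  The CI is
    a t interval.
    """
    m = len(estimates)
    if m < 2:
        raise ValueError("pooling requires m >= 2 imputations")
    ests = np.array([e for e, _ in estimates], dtype=float)
    variances = np.array([v for _, v in estimates], dtype=float)
    if (variances < 0).any():
        raise ValueError("variances must be >= 0")
    qbar = float(ests.mean())
    W = float(variances.mean())
    B = float(ests.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B

    if T == 0.0 or B == 0.0:
        df = np.inf
    else:
        lam = (1.0 + 1.0 / m) * B / T
        df = (m - 1) / lam**2
        if df_complete is not None:
            df_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - lam)
            df = 1.0 / (1.0 / df + 1.0 / df_obs)

    half = stats.t.ppf(1 - alpha / 2, df) * np.sqrt(T) if T > 0 else 0.0
    return PooledEstimate(
        estimate=qbar,
        within_variance=W,
        between_variance=B,
        total_variance=T,
        degrees_of_freedom=float(df),
        ci_low=qbar - half,
        ci_high=qbar + half,
        m=m,
    )
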