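"""Multiple imputation by chained equations and Rubin's-rules pooling.

The chained-equations sampler fills each incomplete variable in turn from a
conditional model given all other variables, cycling until the chains have
mixed, and repeats the whole process ``m`` times with independent seeds to
produce ``m`` completed datasets. Conditional models follow standard MICE
practice: Bayesian linear regression with predictive mean matching (5 donors)
for continuous variables, and bootstrap-refitted (multinomial) logistic
models for binary and ordered-categorical variables. When the table carries a
right-censored outcome, the imputation models condition on the event
indicator together with a Nelson-Aalen cumulative-hazard transform of
follow-up time, the standard way to keep survival information in the
predictor set.

Estimates computed on each completed dataset are combined with Rubin's rules:
the pooled point estimate is the mean, and the pooled variance adds the
average within-imputation variance to the between-imputation variance
inflated by ``(1 + 1/m)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import NelsonAalenFitter
from scipy import stats
from sklearn.linear_model import LogisticRegression

__all__ = ["ImputedDatasetSet", "PooledEstimate", "mice_impute", "pool_rubin", "pool_metric"]

#: Predictive-mean-matching donor pool size.
PMM_DONORS = 5
#: Columns never used as predictors nor imputed (identifiers, simulation
#: truths, derived subgroup flags).
NON_PREDICTOR_PREFIXES = ("true_t_", "sub_")
NON_PREDICTOR_COLUMNS = ("id",)


@dataclass
class ImputedDatasetSet:
    """``m`` completed copies of one input table, plus provenance."""

    m: int
    datasets: list[pd.DataFrame]
    seed: int
    methods: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self):
        return self.m


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    within_var: float
    between_var: float
    total_var: float
    se: float
    ci_low: float
    ci_high: float
    dof: float
    m: int


def _infer_method(series: pd.Series) -> str:
    if series.dropna().isin([0, 1, True, False]).all():
        return "logistic"
    # small integer support -> ordered categorical (e.g. dipstick 0..3)
    vals = series.dropna().unique()
    if len(vals) <= 6 and np.allclose(vals, np.round(vals)):
        return "polytomous"
    return "pmm"


def _predictor_frame(table: pd.DataFrame, exclude: str) -> pd.DataFrame:
    """Numeric design frame from all columns except the one being imputed."""
    cols = [
        c
        for c in table.columns
        if c != exclude
        and c not in NON_PREDICTOR_COLUMNS
        and not any(c.startswith(p) for p in NON_PREDICTOR_PREFIXES)
    ]
    frame = table[cols].copy()
    if "time" in frame.columns and "event" in frame.columns:
        # survival outcome enters as event indicator + cumulative-hazard transform
        naf = NelsonAalenFitter()
        naf.fit(frame["time"], event_observed=(frame["event"] == 1))
        frame["cumhaz"] = naf.predict(frame["time"]).to_numpy()
        frame["event"] = (frame["event"] == 1).astype(float)
        frame = frame.drop(columns=["time"])
    obj_cols = [c for c in frame.columns if frame[c].dtype == object or frame[c].dtype.name == "category"]
    frame = pd.get_dummies(frame, columns=obj_cols, drop_first=True, dtype=float)
    frame = frame.astype(float)
    # standardize for numerical stability of the conditional models
    sd = frame.std().replace(0.0, 1.0)
    return (frame - frame.mean()) / sd


def _draw_linear(rng: np.random.Generator, X: np.ndarray, y: np.ndarray):
    """Posterior draw of Gaussian linear-model parameters (ridge-stabilized)."""
    n, p = X.shape
    ridge = 1e-6 * np.eye(p)
    xtx = X.T @ X + ridge
    beta_hat = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    cov = sigma2 * np.linalg.inv(xtx)
    beta_draw = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    return beta_hat, beta_draw


def _impute_pmm(rng, X_obs, y_obs, X_mis):
    beta_hat, beta_draw = _draw_linear(rng, X_obs, y_obs)
    yhat_obs = X_obs @ beta_hat
    yhat_mis = X_mis @ beta_draw
    # 5 nearest observed donors per missing cell, one chosen at random
    order = np.argsort(np.abs(yhat_obs[None, :] - yhat_mis[:, None]), axis=1, kind="stable")
    k = min(PMM_DONORS, len(y_obs))
    picks = order[np.arange(len(yhat_mis)), rng.integers(k, size=len(yhat_mis))]
    return y_obs[picks]


def _impute_categorical(rng, X_obs, y_obs, X_mis):
    """Multinomial (or binary) logit refit on a bootstrap resample, then draw."""
    levels = np.unique(y_obs)
    if len(levels) == 1:
        return np.full(len(X_mis), levels[0])
    idx = rng.integers(len(y_obs), size=len(y_obs))
    yb = y_obs[idx]
    if len(np.unique(yb)) < 2:  # degenerate bootstrap; fall back to observed rows
        idx = np.arange(len(y_obs))
        yb = y_obs
    model = LogisticRegression(max_iter=500, C=1e4)
    model.fit(X_obs[idx], yb)
    proba = model.predict_proba(X_mis)
    cum = np.cumsum(proba, axis=1)
    u = rng.uniform(size=len(X_mis))
    choice = (u[:, None] > cum).sum(axis=1)
    return model.classes_[np.minimum(choice, len(model.classes_) - 1)]


def mice_impute(
    table: pd.DataFrame,
    m: int = 10,
    seed: int = 0,
    n_cycles: int = 10,
    methods: dict[str, str] | None = None,
) -> ImputedDatasetSet:
    """Run ``m`` independent chained-equation chains over the incomplete columns.

    Each chain starts from a random fill drawn from the observed marginals and
    sweeps the incomplete variables (least missing first) ``n_cycles`` times.
    Observed cells are never altered, so they are identical across the ``m``
    completed datasets. Deterministic for a fixed seed.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    incomplete = [c for c in table.columns if table[c].isna().any()]
    for col in incomplete:
        if table[col].isna().all():
            raise ValueError(f"column {col!r} is entirely missing; nothing to condition on")
    if not incomplete:
        return ImputedDatasetSet(m, [table.copy() for _ in range(m)], seed, {})
    fully_observed = [c for c in table.columns if not table[c].isna().any()]
    if not fully_observed:
        raise ValueError("need at least one fully observed column")

    col_methods = {c: (methods or {}).get(c) or _infer_method(table[c]) for c in incomplete}
    order = sorted(incomplete, key=lambda c: table[c].isna().sum())
    obs_mask = {c: table[c].notna().to_numpy() for c in incomplete}

    datasets = []
    for child in np.random.SeedSequence(seed).spawn(m):
        rng = np.random.default_rng(child)
        df = table.copy()
        for col in order:  # random starting fill from observed values
            miss = ~obs_mask[col]
            pool = df.loc[obs_mask[col], col].to_numpy()
            df.loc[miss, col] = pool[rng.integers(len(pool), size=miss.sum())]
        for _ in range(n_cycles):
            for col in order:
                miss = ~obs_mask[col]
                X = _predictor_frame(df, exclude=col)
                X = np.column_stack([np.ones(len(X)), X.to_numpy()])
                y_obs = df.loc[obs_mask[col], col].to_numpy(dtype=float)
                X_obs, X_mis = X[obs_mask[col]], X[miss]
                if col_methods[col] == "pmm":
                    filled = _impute_pmm(rng, X_obs, y_obs, X_mis)
                else:
                    filled = _impute_categorical(rng, X_obs, y_obs, X_mis)
                df.loc[miss, col] = np.asarray(filled, dtype=float)
        datasets.append(df)
    return ImputedDatasetSet(m, datasets, seed, col_methods)


def pool_rubin(estimates, variances) -> PooledEstimate:
    """Combine per-imputation estimates and variances with Rubin's rules.

    Total variance is ``W + (1 + 1/m) B`` with ``W`` the mean within-imputation
    variance and ``B`` the between-imputation sample variance; the 95% CI uses
    Rubin's small-sample t degrees of freedom.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    m = len(est)
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 imputations")
    if len(var) != m:
        raise ValueError("estimates and variances must have equal length")
    if np.any(var < 0):
        raise ValueError("variances must be nonnegative")
    qbar = float(est.mean())
    within = float(var.mean())
    between = float(est.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    se = math.sqrt(total)
    if between > 0:
        dof = (m - 1) * (1.0 + within / ((1.0 + 1.0 / m) * between)) ** 2
        tcrit = stats.t.ppf(0.975, dof)
    else:
        dof = math.inf
        tcrit = stats.norm.ppf(0.975)
    return PooledEstimate(
        estimate=qbar,
        within_var=within,
        between_var=between,
        total_var=total,
        se=se,
        ci_low=qbar - tcrit * se,
        ci_high=qbar + tcrit * se,
        dof=dof,
        m=m,
    )


def pool_metric(values, variances) -> PooledEstimate:
    """Rubin pooling applied to performance metrics (AUC, PE, PCF, PNF).

    Same arithmetic as :func:`pool_rubin`; the per-imputation variances are
    typically bootstrap variances of the metric on the validation set.
    """
    return pool_rubin(values, variances)
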