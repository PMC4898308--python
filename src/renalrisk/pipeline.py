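"""End-to-end analysis orchestration.

The full procedure mirrors split-sample external validation with multiply
imputed data:

1. split the cohort once into training (2/3) and validation (1/3) sets,
   stratified on eGFR quintiles;
2. run chained-equation imputation separately within each set (m completed
   pairs);
3. for each subgroup, model and imputation pair: fit the Cox model on the
   subgroup's training members, freeze coefficients and Breslow baseline,
   and predict horizon-specific ESRD risk for the subgroup's validation
   members;
4. evaluate AUC, prediction error, PCF(q) and PNF(p) per horizon, with
   bootstrap standard errors;
5. pool metrics and log hazard ratios across imputations with Rubin's rules.

Death is censoring throughout (cause-specific ESRD hazard). No validation
subject ever influences a fitted coefficient or the baseline hazard; the
frozen :class:`~renalrisk.cox_engine.CoxFit` boundary enforces this.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cox_engine import fit_cox, model_spec, predict_risk
from .imputation import mice_impute, pool_metric, pool_rubin
from .risk_metrics import (
    auc_t,
    horizon_classify,
    pcf,
    pnf,
    prediction_error,
    risk_distribution_summary,
)
from .synthetic_cohort import SUBGROUPS

logger = logging.getLogger("renalrisk")

__all__ = ["AnalysisConfig", "AnalysisResult", "stratified_split", "run_analysis", "compare_models"]


@dataclass
class AnalysisConfig:
    """All knobs of the orchestrated analysis."""

    train_frac: float = 2.0 / 3.0
    n_strata: int = 5  # eGFR quantile bins for the stratified split
    m: int = 10
    n_cycles: int = 10
    horizons: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0)
    models: tuple[str, ...] = ("model1", "model2", "model3")
    subgroups: tuple[str, ...] = ("all",) + SUBGROUPS
    q_values: tuple[float, ...] = (0.1, 0.2)
    p_values: tuple[float, ...] = (0.8, 0.9)
    bootstrap_B: int = 200
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")
        h = np.asarray(self.horizons, dtype=float)
        if np.any(h <= 0) or np.any(np.diff(h) <= 0):
            raise ValueError("horizons must be positive and strictly ascending")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass
class AnalysisResult:
    report: pd.DataFrame  # subgroup, model, horizon, metric, estimate, se
    hazard_ratios: pd.DataFrame
    risk_summaries: dict = field(default_factory=dict)  # (subgroup, horizon) -> summary


def stratified_split(
    cohort: pd.DataFrame,
    train_frac: float = 2.0 / 3.0,
    n_strata: int = 5,
    seed: int = 0,
    strat_col: str = "egfr",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded train/validation split stratified on eGFR quantile bins.

    Within each stratum ``ceil(train_frac * size)`` subjects go to training,
    so per-stratum proportions match by construction. A singleton stratum is
    allocated to training with a warning. The returned frames are disjoint and
    exhaustive.
    """
    if len(cohort) == 0:
        raise ValueError("cannot split an empty cohort")
    rng = np.random.default_rng(seed)
    strata = pd.qcut(cohort[strat_col], q=n_strata, labels=False, duplicates="drop")
    train_idx = []
    for _, members in cohort.groupby(strata, sort=True):
        idx = members.index.to_numpy()
        if len(idx) == 1:
            warnings.warn("stratum of size 1 allocated to training", stacklevel=2)
            train_idx.append(idx)
            continue
        perm = rng.permutation(idx)
        n_train = math.ceil(train_frac * len(idx))
        train_idx.append(perm[:n_train])
    train_idx = np.concatenate(train_idx)
    mask = cohort.index.isin(train_idx)
    return cohort[mask].copy(), cohort[~mask].copy()


def _subgroup_members(df: pd.DataFrame, subgroup: str) -> pd.DataFrame:
    if subgroup == "all":
        return df
    return df[df[f"sub_{subgroup}"].astype(bool)]


def _metric_suite(config: AnalysisConfig):
    suite = {"auc": auc_t, "pe": prediction_error}
    for q in config.q_values:
        suite[f"pcf_{q:g}"] = lambda r, o, q=q: pcf(r, o, q)
    for p in config.p_values:
        suite[f"pnf_{p:g}"] = lambda r, o, p=p: pnf(r, o, p)
    return suite


def _bootstrap_variances(suite, risks, times, events, horizon, B, seed) -> dict[str, float]:
    """Joint bootstrap: one set of resamples feeds every metric."""
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {name: [] for name in suite}
    n = len(risks)
    draws, cap = 0, 10 * B
    done = 0
    while done < B:
        idx = rng.integers(n, size=n)
        draws += 1
        try:
            out = horizon_classify(times[idx], events[idx], horizon)
            vals = {name: fn(risks[idx], out) for name, fn in suite.items()}
        except (ValueError, RuntimeError):
            if draws - done > cap:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        for name, v in vals.items():
            samples[name].append(v)
        done += 1
    return {name: float(np.var(v, ddof=1)) for name, v in samples.items()}


def run_analysis(cohort: pd.DataFrame, config: AnalysisConfig | None = None) -> AnalysisResult:
    """Run the full frozen-transport analysis on one cohort table.

    Returns the tidy performance report (one row per subgroup, model, horizon
    and metric, with Rubin-pooled estimate and SE), the pooled log hazard
    ratios, and base-model risk-distribution summaries per subgroup and
    horizon. Fully deterministic for a fixed ``config.seed``.
    """
    config = config or AnalysisConfig()
    config.validate()
    state = np.random.SeedSequence(config.seed).generate_state(4)
    split_seed, imp_train_seed, imp_val_seed, boot_seed = (int(s % (2**31 - 1)) for s in state)

    train, val = stratified_split(cohort, config.train_frac, config.n_strata, split_seed)
    logger.info("split: n_train=%d n_val=%d seed=%d", len(train), len(val), split_seed)
    imp_train = mice_impute(train, m=config.m, seed=imp_train_seed, n_cycles=config.n_cycles)
    imp_val = mice_impute(val, m=config.m, seed=imp_val_seed, n_cycles=config.n_cycles)

    suite = _metric_suite(config)
    report_rows, hr_rows = [], []
    summaries: dict = {}
    base_model = config.models[0]

    for subgroup in config.subgroups:
        for model_name in config.models:
            spec = model_spec(model_name)
            # metric values / variances per horizon across imputations
            acc: dict[tuple[float, str], list[float]] = {}
            accv: dict[tuple[float, str], list[float]] = {}
            coef_acc: dict[str, list[float]] = {}
            coef_var: dict[str, list[float]] = {}
            for i, (tr_i, va_i) in enumerate(zip(imp_train, imp_val)):
                tr = _subgroup_members(tr_i, subgroup)
                va = _subgroup_members(va_i, subgroup)
                try:
                    fit = fit_cox(tr, spec)
                except Exception as err:
                    logger.warning(
                        "fit unavailable: subgroup=%s model=%s imp=%d (%s)",
                        subgroup, model_name, i, err,
                    )
                    for h in config.horizons:
                        for name in suite:
                            acc.setdefault((h, name), []).append(np.nan)
                            accv.setdefault((h, name), []).append(np.nan)
                    continue
                for term in fit.coefficients.index:
                    coef_acc.setdefault(term, []).append(float(fit.coefficients[term]))
                    coef_var.setdefault(term, []).append(float(fit.covariance.loc[term, term]))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    preds = predict_risk(fit, va, config.horizons)
                times = va["time"].to_numpy(dtype=float)
                events = va["event"].to_numpy()
                for h in config.horizons:
                    risks = preds.loc[preds["horizon"] == h, "risk"].to_numpy()
                    try:
                        out = horizon_classify(times, events, h)
                        if not out.is_case.any() or not out.is_control.any():
                            raise ValueError("no cases or no controls")
                        values = {name: fn(risks, out) for name, fn in suite.items()}
                        variances = _bootstrap_variances(
                            suite, risks, times, events, h,
                            config.bootstrap_B, seed=boot_seed + 7919 * i + int(h),
                        )
                    except (ValueError, RuntimeError) as err:
                        logger.warning(
                            "metrics unavailable: subgroup=%s model=%s horizon=%s imp=%d (%s)",
                            subgroup, model_name, h, i, err,
                        )
                        values = {name: np.nan for name in suite}
                        variances = {name: np.nan for name in suite}
                    for name in suite:
                        acc.setdefault((h, name), []).append(values[name])
                        accv.setdefault((h, name), []).append(variances[name])
                    if model_name == base_model and i == 0 and (subgroup, h) not in summaries:
                        try:
                            summaries[(subgroup, h)] = risk_distribution_summary(risks, out)
                        except (ValueError, UnboundLocalError):
                            pass

            for (h, name), vals in acc.items():
                vars_ = accv[(h, name)]
                if len(vals) >= 2 and not any(np.isnan(vals)):
                    pooled = pool_metric(vals, vars_)
                    est, se = pooled.estimate, pooled.se
                elif not any(np.isnan(vals)):
                    est, se = float(vals[0]), float(np.sqrt(vars_[0]))
                else:
                    est, se = np.nan, np.nan
                report_rows.append(
                    {"subgroup": subgroup, "model": model_name, "horizon": h,
                     "metric": name, "estimate": est, "se": se}
                )
            for term, vals in coef_acc.items():
                if len(vals) >= 2:
                    pooled = pool_rubin(vals, coef_var[term])
                    log_hr, se, lo, hi = pooled.estimate, pooled.se, pooled.ci_low, pooled.ci_high
                else:
                    log_hr, se = vals[0], math.sqrt(coef_var[term][0])
                    lo, hi = log_hr - 1.96 * se, log_hr + 1.96 * se
                hr_rows.append(
                    {"subgroup": subgroup, "model": model_name, "term": term,
                     "log_hr": log_hr, "se": se, "hr": math.exp(log_hr),
                     "hr_ci_low": math.exp(lo), "hr_ci_high": math.exp(hi)}
                )

    report = pd.DataFrame(report_rows)
    return AnalysisResult(report=report, hazard_ratios=pd.DataFrame(hr_rows), risk_summaries=summaries)


def compare_models(report_a: pd.DataFrame, report_b: pd.DataFrame) -> pd.DataFrame:
    """Paired metric differences (b - a) on a shared subgroup x horizon grid.

    Both inputs are tidy report tables; the SE of each difference combines the
    two pooled SEs in quadrature. A grid mismatch raises.
    """
    keys = ["subgroup", "horizon", "metric"]
    a = report_a.set_index(keys).sort_index()
    b = report_b.set_index(keys).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("report grids (subgroup x horizon x metric) do not match")
    out = pd.DataFrame(index=a.index)
    out["difference"] = b["estimate"] - a["estimate"]
    out["se"] = np.sqrt(a["se"] ** 2 + b["se"] ** 2)
    return out.reset_index()
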