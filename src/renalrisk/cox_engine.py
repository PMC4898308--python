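"""Cox proportional-hazards fitting and frozen-model risk transport.

The workflow mirrors external validation of a survival risk model: fit the
partial likelihood on a training set, record the coefficients together with
the Breslow baseline cumulative hazard, then apply both *unchanged* to new
subjects to obtain horizon-specific event probabilities

    risk(t | x) = 1 - exp(-H0(t) * exp(beta' (x - x_ref))),

where ``x_ref`` holds the training means of continuous terms (categorical
terms are reference-coded against the largest training category). Death and
administrative end of follow-up are treated as censoring, so the model targets
the cause-specific ESRD hazard.

Coefficient estimation goes through lifelines; the Breslow baseline, the
design-matrix contract (centering, reference coding, the eGFR-by-proteinuria
interaction) and the frozen transport are defined here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

__all__ = [
    "ModelSpec",
    "CoxFit",
    "model_spec",
    "build_design",
    "fit_cox",
    "breslow_baseline",
    "predict_risk",
]

CONTINUOUS_TERMS = ("age", "egfr", "albumin", "calcium", "cholesterol", "hemoglobin", "phosphorus")
CATEGORICAL_TERMS = ("sex", "race", "insurance")
FLAG_TERMS = ("diabetes", "cvd", "hypertension", "substance_abuse", "chronic_viral")
#: Ordinal dipstick proteinuria enters as indicators against none/trace (0).
PROTEINURIA_LEVELS = (1, 2, 3)

_MODEL1 = ["age", "sex", "race", "egfr", "proteinuria"]
_MODEL2 = _MODEL1 + ["insurance", "diabetes", "cvd", "hypertension", "substance_abuse", "chronic_viral"]
_MODEL3 = _MODEL2 + ["albumin", "calcium", "cholesterol", "hemoglobin"]


@dataclass(frozen=True)
class ModelSpec:
    """Ordered covariate list plus interaction pairs for one risk model."""

    name: str
    covariates: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()


def model_spec(name: str) -> ModelSpec:
    """The three nested EHR risk models.

    model1: age, sex, race-ethnicity, eGFR, dipstick proteinuria and the
    eGFR-by-proteinuria interaction. model2 adds insurance and comorbidity
    flags; model3 adds serum albumin, calcium, cholesterol and hemoglobin.
    """
    try:
        covs = {"model1": _MODEL1, "model2": _MODEL2, "model3": _MODEL3}[name]
    except KeyError:
        raise ValueError(f"unknown model spec {name!r}") from None
    return ModelSpec(name, tuple(covs), (("egfr", "proteinuria"),))


@dataclass
class DesignInfo:
    """Frozen design-matrix contract: column order, centering, reference levels."""

    columns: list[str]
    centering: dict[str, float]
    reference_levels: dict[str, str]
    levels: dict[str, list[str]]


def _categorical_columns(df: pd.DataFrame, term: str, info: DesignInfo) -> pd.DataFrame:
    observed = set(df[term].astype(str).unique())
    known = set(info.levels[term]) | {info.reference_levels[term]}
    unseen = observed - known
    if unseen:
        raise ValueError(f"unseen level(s) {sorted(unseen)} for covariate {term!r}")
    out = {}
    for level in info.levels[term]:
        out[f"{term}[{level}]"] = (df[term].astype(str) == level).astype(float)
    return pd.DataFrame(out, index=df.index)


def build_design(
    df: pd.DataFrame, spec: ModelSpec, info: DesignInfo | None = None
) -> tuple[pd.DataFrame, DesignInfo]:
    """Design matrix for ``spec``, reusing a training contract when given.

    With ``info=None`` the contract is derived from ``df`` (training):
    continuous terms centered at their means, categorical terms coded against
    the largest category. With a contract supplied (validation), the same
    centering and coding are applied and unseen levels raise.
    """
    derive = info is None
    if derive:
        info = DesignInfo(columns=[], centering={}, reference_levels={}, levels={})
    blocks = []
    for term in spec.covariates:
        if term in CONTINUOUS_TERMS:
            if derive:
                info.centering[term] = float(df[term].mean())
            blocks.append((df[term].astype(float) - info.centering[term]).rename(term).to_frame())
        elif term in CATEGORICAL_TERMS:
            if derive:
                counts = df[term].astype(str).value_counts()
                ref = counts.index[0]
                info.reference_levels[term] = ref
                info.levels[term] = [lv for lv in counts.index if lv != ref]
            blocks.append(_categorical_columns(df, term, info))
        elif term == "proteinuria":
            vals = df["proteinuria"].astype(float)
            if vals.isna().any():
                raise ValueError("proteinuria must be complete (impute first)")
            cols = {f"proteinuria[{lv}]": (vals == lv).astype(float) for lv in PROTEINURIA_LEVELS}
            blocks.append(pd.DataFrame(cols, index=df.index))
            if derive:
                info.reference_levels["proteinuria"] = "0"
                info.levels["proteinuria"] = [str(lv) for lv in PROTEINURIA_LEVELS]
        elif term in FLAG_TERMS:
            blocks.append(df[term].astype(float).rename(term).to_frame())
        else:
            raise ValueError(f"unknown covariate {term!r}")
    if not blocks:
        X = pd.DataFrame(index=df.index)
        info.columns = []
        return X, info
    for left, right in spec.interactions:
        if left != "egfr" or right != "proteinuria":
            raise ValueError(f"unsupported interaction {(left, right)!r}")
        egfr_c = df["egfr"].astype(float) - info.centering.get("egfr", 0.0)
        cols = {
            f"egfr:proteinuria[{lv}]": egfr_c * (df["proteinuria"].astype(float) == lv)
            for lv in PROTEINURIA_LEVELS
        }
        blocks.append(pd.DataFrame(cols, index=df.index))
    X = pd.concat(blocks, axis=1)
    if derive:
        info.columns = list(X.columns)
    else:
        X = X[info.columns]
    return X, info


@dataclass
class CoxFit:
    """A frozen, transportable Cox fit.

    Holds per-term log hazard ratios, their covariance, the Breslow baseline
    cumulative hazard as a right-continuous step function over training event
    times, and the design contract used to reproduce the linear predictor on
    new data.
    """

    coefficients: pd.Series
    covariance: pd.DataFrame
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    design: DesignInfo
    spec: ModelSpec
    n_events: int = 0
    max_time: float = field(default=np.inf)

    def cumulative_hazard(self, t) -> np.ndarray:
        """H0(t): 0 before the first event, step up at each event time."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.baseline_times, t, side="right")
        H = np.concatenate([[0.0], self.baseline_cumhaz])
        return H[idx]

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        X, _ = build_design(df, self.spec, self.design)
        return X.to_numpy() @ self.coefficients.to_numpy()

    def to_json(self) -> str:
        payload = {
            "spec": {"name": self.spec.name, "covariates": list(self.spec.covariates),
                     "interactions": [list(p) for p in self.spec.interactions]},
            "coefficients": self.coefficients.to_dict(),
            "covariance": {"index": list(self.covariance.index),
                           "values": self.covariance.to_numpy().tolist()},
            "baseline_times": self.baseline_times.tolist(),
            "baseline_cumhaz": self.baseline_cumhaz.tolist(),
            "design": {"columns": self.design.columns, "centering": self.design.centering,
                       "reference_levels": self.design.reference_levels, "levels": self.design.levels},
            "n_events": self.n_events,
            "max_time": self.max_time,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CoxFit":
        d = json.loads(text)
        spec = ModelSpec(d["spec"]["name"], tuple(d["spec"]["covariates"]),
                         tuple(tuple(p) for p in d["spec"]["interactions"]))
        idx = d["covariance"]["index"]
        return cls(
            coefficients=pd.Series(d["coefficients"]).reindex(d["design"]["columns"]),
            covariance=pd.DataFrame(d["covariance"]["values"], index=idx, columns=idx),
            baseline_times=np.asarray(d["baseline_times"], dtype=float),
            baseline_cumhaz=np.asarray(d["baseline_cumhaz"], dtype=float),
            design=DesignInfo(**d["design"]),
            spec=spec,
            n_events=d["n_events"],
            max_time=d["max_time"],
        )


def _check_collinearity(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    scale = np.linalg.norm(arr, axis=0)
    if np.any(scale == 0):
        dead = [c for c, s in zip(X.columns, scale) if s == 0]
        raise np.linalg.LinAlgError(f"constant-zero design column(s): {dead}")
    _, r = np.linalg.qr(arr / scale)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-8 * diag.max()
    if bad.any():
        offending = [c for c, b in zip(X.columns, bad) if b]
        raise np.linalg.LinAlgError(f"collinear design column(s): {offending}")


def _breslow_score_hessian(X: np.ndarray, t: np.ndarray, e: np.ndarray, beta: np.ndarray):
    """Score, Hessian and log-likelihood of the Breslow-ties partial likelihood.

    Single descending-time sweep maintaining risk-set sums S0, S1, S2; tied
    events share one risk set.
    """
    n, p = X.shape
    lp = X @ beta
    lp -= lp.max()  # guard exp overflow; cancels in the ratios
    w = np.exp(lp)
    order = np.argsort(-t, kind="stable")
    score = np.zeros(p)
    hess = np.zeros((p, p))
    loglik = 0.0
    S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        current = t[order[i]]
        while j < n and t[order[j]] == current:  # admit whole tied group first
            k = order[j]
            S0 += w[k]
            S1 += w[k] * X[k]
            S2 += w[k] * np.outer(X[k], X[k])
            j += 1
        for k in order[i:j]:
            if e[k]:
                xbar = S1 / S0
                score += X[k] - xbar
                hess += S2 / S0 - np.outer(xbar, xbar)
                loglik += lp[k] - np.log(S0)
        i = j
    return score, hess, loglik


def _newton_polish(X, t, e, beta0, score_tol=1e-8, rel_ll_tol=1e-9, max_iter=25):
    """Tighten a partial-likelihood optimum by full Newton-Raphson steps.

    Converged when every score component is below ``score_tol`` or the
    relative log-likelihood change drops below ``rel_ll_tol``. Returns the
    coefficients and the inverse observed information (covariance).
    """
    beta = np.asarray(beta0, dtype=float).copy()
    score, hess, ll = _breslow_score_hessian(X, t, e, beta)
    for _ in range(max_iter):
        if np.max(np.abs(score)) < score_tol:
            break
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            break
        candidate = beta + step
        s2, h2, ll2 = _breslow_score_hessian(X, t, e, candidate)
        if not np.isfinite(ll2) or ll2 < ll - 1e-10:
            break  # lifelines optimum already at least as good
        beta, score, hess = candidate, s2, h2
        if abs(ll2 - ll) < rel_ll_tol * max(abs(ll), 1.0):
            ll = ll2
            break
        ll = ll2
    cov = np.linalg.inv(hess)
    return beta, cov


def breslow_baseline(durations, event_observed, linear_predictor) -> tuple[np.ndarray, np.ndarray]:
    """Breslow estimator of the baseline cumulative hazard.

    At each distinct event time the hazard increments by (number of events)
    divided by the sum of exp(linear predictor) over the risk set. With a null
    linear predictor this is exactly the Nelson-Aalen estimator; simultaneous
    events share a single risk set (Breslow tie handling).
    """
    t = np.asarray(durations, dtype=float)
    e = np.asarray(event_observed, dtype=bool)
    lp = np.asarray(linear_predictor, dtype=float)
    if not e.any():
        return np.array([]), np.array([])
    order = np.argsort(t, kind="stable")
    t, e, lp = t[order], e[order], lp[order]
    w = np.exp(lp)
    # risk-set sum of weights at or after each time, then collapse to event times
    rev_cumsum = np.cumsum(w[::-1])[::-1]
    event_times, first_idx = np.unique(t[e], return_index=True)
    increments = np.empty_like(event_times)
    for k, et in enumerate(event_times):
        at_risk_from = np.searchsorted(t, et, side="left")
        denom = rev_cumsum[at_risk_from]
        if denom <= 0:
            raise ValueError(f"empty risk set at event time {et}")
        d = int(np.sum(e & (t == et)))
        increments[k] = d / denom
    return event_times, np.cumsum(increments)


def fit_cox(
    training: pd.DataFrame,
    spec: ModelSpec,
    duration_col: str = "time",
    event_col: str = "event",
    event_code: int = 1,
) -> CoxFit:
    """Fit the cause-specific ESRD Cox model on a (complete) training table.

    Any outcome other than ``event_code`` counts as censoring. Raises when no
    events are present or the design matrix is collinear (the offending
    columns are named in the error).
    """
    events = (training[event_col] == event_code).astype(int)
    if events.sum() == 0:
        raise ValueError("training set contains no events")
    X, info = build_design(training, spec)
    durations = training[duration_col].to_numpy(dtype=float)
    if X.shape[1] == 0:
        # null model: Breslow baseline reduces to the Nelson-Aalen estimator
        times, cumhaz = breslow_baseline(durations, events.to_numpy(), np.zeros(len(X)))
        return CoxFit(
            coefficients=pd.Series(dtype=float),
            covariance=pd.DataFrame(),
            baseline_times=times,
            baseline_cumhaz=cumhaz,
            design=info,
            spec=spec,
            n_events=int(events.sum()),
            max_time=float(durations.max()),
        )
    _check_collinearity(X)

    frame = X.copy()
    frame["_T"] = training[duration_col].to_numpy(dtype=float)
    frame["_E"] = events.to_numpy()
    cph = CoxPHFitter()
    # Newton-Raphson with step damping fallback: near-separated designs
    # (few events, many indicator terms) can overshoot at full step size
    last_err = None
    for options in ({}, {"step_size": 0.5}, {"step_size": 0.25}, {"step_size": 0.1}):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(frame, duration_col="_T", event_col="_E", fit_options=options or None)
            last_err = None
            break
        except Exception as err:  # lifelines ConvergenceError
            last_err = err
    if last_err is not None:
        raise last_err
    # polish to the Breslow-ties optimum (score < 1e-8) and take the
    # covariance from the observed information there
    beta, cov_arr = _newton_polish(
        X.to_numpy(), frame["_T"].to_numpy(), frame["_E"].to_numpy(dtype=bool),
        cph.params_.reindex(info.columns).to_numpy(),
    )
    coefs = pd.Series(beta, index=info.columns)
    cov = pd.DataFrame(cov_arr, index=info.columns, columns=info.columns)

    lp = X.to_numpy() @ coefs.to_numpy()
    times, cumhaz = breslow_baseline(frame["_T"].to_numpy(), frame["_E"].to_numpy(), lp)
    return CoxFit(
        coefficients=coefs,
        covariance=cov,
        baseline_times=times,
        baseline_cumhaz=cumhaz,
        design=info,
        spec=spec,
        n_events=int(events.sum()),
        max_time=float(frame["_T"].max()),
    )


def predict_risk(fit: CoxFit, validation: pd.DataFrame, horizons) -> pd.DataFrame:
    """Horizon-specific event probabilities from a frozen fit.

    Returns a long table (id, horizon, risk) with
    ``risk = 1 - exp(-H0(h) exp(lp))``; nothing is re-estimated on the
    validation data. Horizons beyond the training follow-up range trigger a
    warning (the baseline hazard is flat beyond the last training event).
    """
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    beyond = horizons[horizons > fit.max_time]
    if beyond.size:
        warnings.warn(
            f"horizon(s) {beyond.tolist()} exceed the training follow-up range "
            f"({fit.max_time:.2f} y); baseline hazard extrapolated as constant",
            stacklevel=2,
        )
    lp = fit.linear_predictor(validation)
    H0 = fit.cumulative_hazard(horizons)
    ids = validation["id"].to_numpy() if "id" in validation.columns else validation.index.to_numpy()
    rows = []
    for h, H in zip(horizons, H0):
        risk = 1.0 - np.exp(-H * np.exp(lp))
        rows.append(pd.DataFrame({"id": ids, "horizon": h, "risk": risk}))
    return pd.concat(rows, ignore_index=True)
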