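"""Horizon-specific evaluation of survival risk predictions under censoring.

All criteria share one substrate: at a horizon ``t`` each subject is a *case*
(observed ESRD by ``t``), a *control* (still under observation beyond ``t``)
or *ambiguous* (censored before ``t``). Right censoring is corrected by
inverse-probability-of-censoring weights (IPCW): cases weigh ``1/G(T-)`` and
controls ``1/G(t)``, with ``G`` the Kaplan-Meier estimate of the censoring
survival function (event roles reversed); ambiguous subjects get weight 0.

On that substrate the module provides

* ``auc_t``       - cumulative-case / dynamic-control time-dependent AUC,
* ``prediction_error`` - the IPCW Brier score at the horizon,
* ``pcf``         - proportion of cases captured when the fraction ``q`` of
                    the population at highest predicted risk is followed,
* ``pnf``         - smallest fraction of the population whose follow-up
                    captures a proportion ``p`` of cases (grid inversion of
                    the PCF curve),

plus bootstrap standard errors and risk-distribution summaries (densities of
predicted risk among progressors/non-progressors with the q80/q90 follow-up
thresholds). AUC measures ranking everywhere on the risk scale; PCF/PNF
measure *risk concentration* — they are high only when the cases crowd into a
small top slice of the risk distribution, which is why the two can disagree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "CensoringDistribution",
    "HorizonOutcomes",
    "horizon_classify",
    "auc_t",
    "prediction_error",
    "pcf",
    "pcf_curve",
    "pnf",
    "bootstrap_se",
    "RiskDistributionSummary",
    "risk_distribution_summary",
]

CASE, CONTROL, AMBIGUOUS = "case", "control", "ambiguous"
#: Default grid step for inverting the PCF curve.
PNF_GRID_STEP = 0.001


@dataclass
class CensoringDistribution:
    """Kaplan-Meier estimate of G(t) = P(censoring time > t)."""

    times: np.ndarray
    survival: np.ndarray

    @classmethod
    def fit(cls, times, censored) -> "CensoringDistribution":
        kmf = KaplanMeierFitter()
        kmf.fit(times, event_observed=np.asarray(censored, dtype=bool))
        sf = kmf.survival_function_
        return cls(times=sf.index.to_numpy(dtype=float), survival=sf.iloc[:, 0].to_numpy())

    def g(self, t) -> np.ndarray:
        """Right-continuous G(t)."""
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="right") - 1
        surv = np.concatenate([[1.0], self.survival])
        return surv[idx + 1]

    def g_minus(self, t) -> np.ndarray:
        """Left limit G(t-)."""
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="left") - 1
        surv = np.concatenate([[1.0], self.survival])
        return surv[idx + 1]


@dataclass
class HorizonOutcomes:
    """Case/control/ambiguous status and IPCW weight per subject at one horizon."""

    horizon: float
    status: np.ndarray  # of {"case", "control", "ambiguous"}
    weight: np.ndarray

    @property
    def is_case(self) -> np.ndarray:
        return self.status == CASE

    @property
    def is_control(self) -> np.ndarray:
        return self.status == CONTROL

    @property
    def n(self) -> int:
        return len(self.status)

    def __len__(self) -> int:
        return self.n


def horizon_classify(times, events, horizon: float, censor_km: CensoringDistribution | None = None,
                     event_code: int = 1) -> HorizonOutcomes:
    """Classify subjects at a horizon and attach IPCW weights.

    ``events`` uses the cohort coding (0 censored, 1 ESRD, 2 death); death is
    censoring for the ESRD endpoint. When ``censor_km`` is omitted it is
    estimated from the same sample with the event roles reversed. Raises when
    the censoring survival function reaches 0 at a point where a weight is
    needed (advising a shorter horizon).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    is_event = e == event_code
    if censor_km is None:
        censor_km = CensoringDistribution.fit(t, ~is_event)
    status = np.full(t.shape, AMBIGUOUS, dtype=object)
    status[(t <= horizon) & is_event] = CASE
    status[t > horizon] = CONTROL
    weight = np.zeros(t.shape)
    case = status == CASE
    ctrl = status == CONTROL
    g_case = censor_km.g_minus(t[case])
    g_ctrl = censor_km.g(np.full(ctrl.sum(), horizon)) if ctrl.any() else np.array([])
    if (case.any() and np.any(g_case <= 0)) or (ctrl.any() and np.any(g_ctrl <= 0)):
        raise ValueError(
            f"censoring survival reaches 0 before horizon {horizon}; "
            "reduce the horizon or supply more follow-up"
        )
    weight[case] = 1.0 / g_case
    weight[ctrl] = 1.0 / g_ctrl
    return HorizonOutcomes(horizon=float(horizon), status=status.astype(str), weight=weight)


def _case_control(risks, outcomes: HorizonOutcomes):
    r = np.asarray(risks, dtype=float)
    if r.shape[0] != outcomes.n:
        raise ValueError("risks and outcomes length mismatch")
    return r, outcomes.is_case, outcomes.is_control


def auc_t(risks, outcomes: HorizonOutcomes) -> float:
    """IPCW time-dependent AUC (cumulative cases vs dynamic controls).

    Weighted proportion of (case, control) pairs ranked correctly by predicted
    risk, ties counting one half; pair weight is the product of member IPCW
    weights. With no censoring this is exactly the Mann-Whitney statistic.
    """
    r, case, ctrl = _case_control(risks, outcomes)
    if not case.any() or not ctrl.any():
        raise ValueError("AUC needs at least one case and one control")
    w = outcomes.weight
    rc, wc = r[case], w[case]
    rk, wk = r[ctrl], w[ctrl]
    order = np.argsort(rk, kind="stable")
    rk, wk = rk[order], wk[order]
    cum = np.concatenate([[0.0], np.cumsum(wk)])
    below = cum[np.searchsorted(rk, rc, side="left")]
    upto = cum[np.searchsorted(rk, rc, side="right")]
    tied = upto - below
    num = float(np.sum(wc * (below + 0.5 * tied)))
    denom = float(wc.sum() * wk.sum())
    return num / denom


def prediction_error(risks, outcomes: HorizonOutcomes) -> float:
    """IPCW Brier score at the horizon: (1/n) sum w_i (case_i - risk_i)^2."""
    r = np.asarray(risks, dtype=float)
    ind = outcomes.is_case.astype(float)
    return float(np.sum(outcomes.weight * (ind - r) ** 2) / outcomes.n)


def _sorted_masses(risks, outcomes: HorizonOutcomes, estimator: str):
    """Population mass and captured-case mass per distinct risk, highest first."""
    r = np.asarray(risks, dtype=float)
    if estimator == "observed":
        capture = np.where(outcomes.is_case, outcomes.weight, 0.0)
    elif estimator == "model":
        capture = r.copy()  # expected events under the model
    else:
        raise ValueError(f"unknown PCF estimator {estimator!r}")
    order = np.argsort(-r, kind="stable")
    r_sorted, cap_sorted = r[order], capture[order]
    # collapse ties so boundary mass can be pro-rated within a tied group
    distinct, start = np.unique(-r_sorted, return_index=True)
    bounds = np.append(start, len(r_sorted))
    counts = np.diff(bounds)
    cap = np.add.reduceat(cap_sorted, bounds[:-1])
    return counts, cap, len(r_sorted)


def pcf_curve(risks, outcomes: HorizonOutcomes, qs, estimator: str = "observed") -> np.ndarray:
    """PCF evaluated at each population fraction in ``qs``.

    Subjects are followed from the top of the predicted-risk distribution;
    a risk-tied group straddling the q boundary contributes pro rata. The
    observed estimator counts IPCW case mass; the model-based variant counts
    expected events (the sum of predicted risks) instead.
    """
    qs = np.atleast_1d(np.asarray(qs, dtype=float))
    if np.any((qs <= 0) | (qs > 1)):
        raise ValueError("q must lie in (0, 1]")
    counts, cap, n = _sorted_masses(risks, outcomes, estimator)
    total = cap.sum()
    if total <= 0:
        raise ValueError("no case mass at this horizon")
    cum_pop = np.concatenate([[0.0], np.cumsum(counts) / n])
    cum_cap = np.concatenate([[0.0], np.cumsum(cap)])
    # piecewise-linear interpolation of captured mass vs population fraction
    captured = np.interp(qs, cum_pop, cum_cap)
    return captured / total


def pcf(risks, outcomes: HorizonOutcomes, q: float, estimator: str = "observed") -> float:
    """Proportion of cases captured when following the top fraction ``q``."""
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    return float(pcf_curve(risks, outcomes, [q], estimator)[0])


def pnf(risks, outcomes: HorizonOutcomes, p: float, grid_step: float = PNF_GRID_STEP,
        estimator: str = "observed") -> float:
    """Smallest population fraction whose follow-up captures proportion ``p`` of cases.

    Inverts the PCF curve on a fixed grid (default step 0.001). If even the
    full population cannot reach ``p`` (possible only for the model-based
    estimator), returns 1.0 with a warning.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    n_steps = int(round(1.0 / grid_step))
    qs = np.linspace(grid_step, 1.0, n_steps)
    curve = pcf_curve(risks, outcomes, qs, estimator)
    hit = np.nonzero(curve >= p)[0]
    if hit.size == 0:
        warnings.warn(f"PCF never reaches p={p}; returning 1.0", stacklevel=2)
        return 1.0
    return float(min(qs[hit[0]], 1.0))


def bootstrap_se(
    metric,
    risks,
    times,
    events,
    horizon: float,
    B: int = 200,
    seed: int = 0,
    max_redraws: int | None = None,
) -> float:
    """Nonparametric bootstrap SE of a horizon metric.

    Resamples subjects with replacement, re-estimates the censoring
    Kaplan-Meier within each resample, and recomputes ``metric(risks,
    outcomes)``. Resamples without cases are redrawn (capped at 10 per
    requested resample).
    """
    if B < 50:
        raise ValueError("use at least B=50 bootstrap resamples")
    r = np.asarray(risks, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    rng = np.random.default_rng(seed)
    cap = max_redraws if max_redraws is not None else 10 * B
    redraws = 0
    values = []
    while len(values) < B:
        idx = rng.integers(len(r), size=len(r))
        try:
            out = horizon_classify(t[idx], e[idx], horizon)
            values.append(metric(r[idx], out))
        except ValueError:
            redraws += 1
            if redraws > cap:
                raise RuntimeError("too many degenerate bootstrap resamples (no cases)")
    return float(np.std(values, ddof=1))


@dataclass
class RiskDistributionSummary:
    """Densities of predicted risk for progressors vs non-progressors.

    ``q80``/``q90`` are the risk cutoffs above which 80% / 90% of the
    (weighted) progressor mass lies; capturing more progressors requires the
    lower cutoff, so ``q90 <= q80``.
    """

    horizon: float
    grid: np.ndarray
    density_progressors: np.ndarray
    density_nonprogressors: np.ndarray
    q80: float
    q90: float
    n_cases: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "horizon": self.horizon,
                "risk": self.grid,
                "density_progressors": self.density_progressors,
                "density_nonprogressors": self.density_nonprogressors,
            }
        )


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, alpha: float) -> float:
    """Smallest value v with weighted CDF(v) >= alpha."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cdf = np.cumsum(w) / w.sum()
    return float(v[np.searchsorted(cdf, alpha - 1e-12, side="left")])


def _density(values: np.ndarray, weights: np.ndarray, grid: np.ndarray) -> np.ndarray:
    if len(values) < 2 or np.ptp(values) < 1e-12:
        out = np.zeros_like(grid)
        out[np.argmin(np.abs(grid - values.mean()))] = 1.0 / max(grid[1] - grid[0], 1e-12)
        return out
    kde = stats.gaussian_kde(values, weights=weights)
    return kde(grid)


def risk_distribution_summary(
    risks, outcomes: HorizonOutcomes, grid_size: int = 256
) -> RiskDistributionSummary:
    """Summarize how predicted risk separates progressors from non-progressors."""
    r, case, ctrl = _case_control(risks, outcomes)
    if not case.any():
        raise ValueError("no progressors at this horizon")
    w = outcomes.weight
    grid = np.linspace(0.0, 1.0, grid_size)
    q80 = _weighted_quantile(r[case], w[case], 0.20)
    q90 = _weighted_quantile(r[case], w[case], 0.10)
    return RiskDistributionSummary(
        horizon=outcomes.horizon,
        grid=grid,
        density_progressors=_density(r[case], w[case], grid),
        density_nonprogressors=_density(r[ctrl], w[ctrl], grid) if ctrl.any() else np.zeros_like(grid),
        q80=q80,
        q90=q90,
        n_cases=int(case.sum()),
    )
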