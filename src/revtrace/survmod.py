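"""Survival association of reversion emergence.

Reversion counts enter as a time-varying covariate in counting-process
(start, stop, event] format, updated at each sampling day up to a chosen
treatment cycle. The Cox partial likelihood with Efron tie correction is
maximized by Newton iteration; proportional hazards are checked with the
global scaled-Schoenfeld score test; landmark Kaplan-Meier curves and
Kendall rank correlations complete the picture.

Cycle-day convention: C{k}D1 = 28 * (k-1) days from treatment start (28-day
cycles, so the fourth cycle starts at 16 weeks); 1 month = 30.44 days.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

DAYS_PER_MONTH = 30.44
CYCLE_DAYS = 28.0

__all__ = [
    "SurvivalRecord",
    "CoxFit",
    "KMResult",
    "cycle_day",
    "build_counting_process",
    "fit_cox_tv",
    "schoenfeld_test",
    "kaplan_meier",
    "landmark_groups",
    "kendall_tau",
]


# ---------------------------------------------------------------------------
# Types and time conventions
# ---------------------------------------------------------------------------

@dataclass
class SurvivalRecord:
    """Per-patient survival times (months) with event flags."""

    patient: str
    rpfs_months: float
    rpfs_event: int
    os_months: float
    os_event: int

    def __post_init__(self) -> None:
        if self.rpfs_months <= 0 or self.os_months <= 0:
            raise ValueError("survival times must be positive")
        if self.rpfs_event not in (0, 1) or self.os_event not in (0, 1):
            raise ValueError("event flags must be 0 or 1")


@dataclass
class CoxFit:
    """Single-covariate (or small multivariable) Cox fit summary."""

    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n_events: int
    separation: bool = False
    schoenfeld_p: float | None = None

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta[0]))

    @property
    def ci(self) -> tuple[float, float]:
        b, s = float(self.beta[0]), float(self.se[0])
        return (float(np.exp(b - 1.96 * s)), float(np.exp(b + 1.96 * s)))

    @property
    def p(self) -> float:
        s = float(self.se[0])
        if not math.isfinite(s) or s == 0:
            return float("nan")
        z = float(self.beta[0]) / s
        return 2.0 * stats.norm.sf(abs(z))


def cycle_day(label: str) -> float:
    """Days from treatment start for a cycle label like 'C4D1'."""
    m = re.fullmatch(r"C(\d+)D1", label)
    if not m:
        raise ValueError(f"unrecognized cycle label {label!r}")
    return CYCLE_DAYS * (int(m.group(1)) - 1)


# ---------------------------------------------------------------------------
# Counting-process construction
# ---------------------------------------------------------------------------

def build_counting_process(
    longit: pd.DataFrame,
    surv: pd.DataFrame,
    cutpoint: int | str = 1,
    through_cycle: str | None = "C5D1",
    endpoint: str = "rpfs",
) -> pd.DataFrame:
    """(start, stop, event, covariate] intervals with a time-varying count.

    ``longit`` needs columns patient, day, count (the running number of
    distinct reversions detected by that day); ``surv`` needs patient,
    {endpoint}_months, {endpoint}_event. Only samples drawn at or before
    ``through_cycle`` update the covariate. With an integer ``cutpoint`` c,
    the covariate is the indicator count >= c; with ``cutpoint='continuous'``
    it is the raw count. Times are in months from treatment start.
    """
    t_col, e_col = f"{endpoint}_months", f"{endpoint}_event"
    for col in ("patient", "day", "count"):
        if col not in longit.columns:
            raise ValueError(f"longit missing column {col!r}")
    for col in ("patient", t_col, e_col):
        if col not in surv.columns:
            raise ValueError(f"surv missing column {col!r}")
    max_day = cycle_day(through_cycle) if through_cycle is not None else math.inf

    rows = []
    for _, s in surv.iterrows():
        pid = s["patient"]
        t_end = float(s[t_col])
        event = int(s[e_col])
        recs = longit[longit["patient"] == pid].sort_values("day")
        if len(recs) == 0 or float(recs["day"].iloc[0]) > 0:
            raise ValueError(f"patient {pid} lacks a baseline (day 0) record")
        recs = recs[recs["day"] <= max_day]
        times = recs["day"].to_numpy(dtype=float) / DAYS_PER_MONTH
        counts = recs["count"].to_numpy()
        if times[-1] > t_end + 1e-9:
            raise ValueError(f"patient {pid}: sample day after event time")

        def covariate(c: float) -> float:
            return float(c) if cutpoint == "continuous" else float(c >= cutpoint)

        # collapse consecutive identical covariate values
        breaks = [0.0]
        values = [covariate(counts[0])]
        for t, c in zip(times[1:], counts[1:]):
            v = covariate(c)
            if v != values[-1]:
                breaks.append(t)
                values.append(v)
        breaks.append(t_end)
        for k in range(len(values)):
            start, stop = breaks[k], breaks[k + 1]
            if stop <= start:
                continue
            rows.append(
                {"patient": pid, "start": start, "stop": stop,
                 "event": event if k == len(values) - 1 else 0,
                 "covariate": values[k]}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cox partial likelihood (Efron ties), Newton maximization
# ---------------------------------------------------------------------------

def _efron_loglik(
    beta: np.ndarray,
    start: np.ndarray,
    stop: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """(loglik, gradient, negative Hessian) of the Efron partial likelihood."""
    p = X.shape[1]
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    event_times = np.unique(stop[event == 1])
    for t in event_times:
        D = (stop == t) & (event == 1)
        R = (start < t) & (t <= stop)
        m = int(D.sum())
        wR, XR = w[R], X[R]
        wD, XD = w[D], X[D]
        S0R = wR.sum()
        S1R = XR.T @ wR
        S2R = (XR * wR[:, None]).T @ XR
        S0D = wD.sum()
        S1D = XD.T @ wD
        S2D = (XD * wD[:, None]).T @ XD
        ll += float(eta[D].sum())
        for j in range(m):
            frac = j / m
            s0 = S0R - frac * S0D
            s1 = S1R - frac * S1D
            s2 = S2R - frac * S2D
            ll -= math.log(s0)
            mu = s1 / s0
            grad -= mu
            info += s2 / s0 - np.outer(mu, mu)
        grad += XD.sum(axis=0)
    return ll, grad, info


def fit_cox_tv(
    intervals: pd.DataFrame,
    covariates: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
    beta_cap: float = 15.0,
) -> CoxFit:
    """Newton-Raphson fit of the counting-process Cox model with Efron ties.

    ``intervals`` needs columns start, stop, event, and the covariate
    column(s) (default ['covariate']). Iterates to |delta beta| < ``tol``.
    Monotone likelihood (complete separation) is detected when the estimate
    runs away; the coefficient is then capped at ``beta_cap`` and flagged.
    """
    covariates = covariates or ["covariate"]
    start = intervals["start"].to_numpy(dtype=float)
    stop = intervals["stop"].to_numpy(dtype=float)
    event = intervals["event"].to_numpy(dtype=int)
    X = intervals[covariates].to_numpy(dtype=float)
    n_events = int(event.sum())
    if n_events < 1:
        raise ValueError("need at least one event")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("covariate does not vary")
    p = X.shape[1]
    beta = np.zeros(p)
    separation = False
    for _ in range(max_iter):
        ll, grad, info = _efron_loglik(beta, start, stop, event, X)
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            separation = True
            break
        # step-halving for stability
        step = 1.0
        new_beta = beta + delta
        new_ll = _efron_loglik(new_beta, start, stop, event, X)[0]
        while new_ll < ll - 1e-12 and step > 1e-4:
            step /= 2
            new_beta = beta + step * delta
            new_ll = _efron_loglik(new_beta, start, stop, event, X)[0]
        beta = new_beta
        if np.abs(beta).max() > beta_cap:
            separation = True
            beta = np.clip(beta, -beta_cap, beta_cap)
            break
        if np.abs(step * delta).max() < tol:
            break
    if separation:
        warnings.warn("monotone partial likelihood: coefficient capped", stacklevel=2)
    ll, _, info = _efron_loglik(beta, start, stop, event, X)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
    return CoxFit(beta=beta, se=se, loglik=ll, n_events=n_events, separation=separation)


# ---------------------------------------------------------------------------
# Schoenfeld global test
# ---------------------------------------------------------------------------

def schoenfeld_test(
    fit: CoxFit, intervals: pd.DataFrame, covariates: list[str] | None = None
) -> tuple[float, float]:
    """Global proportional-hazards score test on scaled Schoenfeld residuals.

    Schoenfeld residuals at each event time are regressed on the
    Kaplan-Meier-transformed event time g(t) = 1 - KM(t-); the global
    chi-square statistic follows Grambsch & Therneau with the average
    information substituted for the per-event variance. With one covariate the
    global statistic is the covariate's individual statistic.
    """
    covariates = covariates or ["covariate"]
    start = intervals["start"].to_numpy(dtype=float)
    stop = intervals["stop"].to_numpy(dtype=float)
    event = intervals["event"].to_numpy(dtype=int)
    X = intervals[covariates].to_numpy(dtype=float)
    d = int(event.sum())
    if d < 2:
        raise ValueError("need at least 2 events")
    beta = fit.beta
    w = np.exp(X @ beta)

    # per-event residuals (one per event, Breslow-style risk-set mean)
    ev_idx = np.where(event == 1)[0]
    order = np.argsort(stop[ev_idx], kind="stable")
    ev_idx = ev_idx[order]
    times = stop[ev_idx]
    resid = np.zeros((d, X.shape[1]))
    for k, i in enumerate(ev_idx):
        t = stop[i]
        R = (start < t) & (t <= stop)
        mu = (X[R] * w[R][:, None]).sum(axis=0) / w[R].sum()
        resid[k] = X[i] - mu

    # KM transform of event times (based on the event-time distribution)
    kmf = KaplanMeierFitter()
    kmf.fit(stop, event_observed=event, entry=start)
    surv = kmf.survival_function_at_times(times).to_numpy()
    g = 1.0 - surv
    g = g - g.mean()

    _, _, info = _efron_loglik(beta, start, stop, event, X)
    vbar = info / d
    num = resid.T @ g                      # (p,)
    denom = float(g @ g)
    try:
        chi2 = float(num @ np.linalg.solve(vbar * denom, num))
    except np.linalg.LinAlgError:
        return math.nan, math.nan
    pval = float(stats.chi2.sf(chi2, df=X.shape[1]))
    return chi2, pval


# ---------------------------------------------------------------------------
# Kaplan-Meier and landmark grouping
# ---------------------------------------------------------------------------

@dataclass
class KMResult:
    """Per-group product-limit curves with medians, CIs and a risk table."""

    curves: dict[str, pd.DataFrame]       # index time, columns KM_estimate, ci_lower, ci_upper
    medians: dict[str, float]             # NaN = not reached
    risk_table: pd.DataFrame              # group x tick -> at-risk count


def kaplan_meier(
    times: np.ndarray,
    events: np.ndarray,
    groups: np.ndarray | None = None,
    ticks: list[float] | None = None,
) -> KMResult:
    """Product-limit survival estimates per group (Greenwood CIs).

    The median is the first time the survival estimate drops to 0.5 or below;
    with all observations censored it is reported as NaN (not reached).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if groups is None:
        groups = np.zeros(len(times), dtype=int)
    groups = np.asarray(groups)
    if ticks is None:
        ticks = list(np.linspace(0, float(times.max()), 5))
    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    risk_rows = {}
    for g in pd.unique(groups):
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], event_observed=events[mask], label=str(g))
        df = kmf.survival_function_.copy()
        ci = kmf.confidence_interval_
        df.columns = ["KM_estimate"]
        df["ci_lower"] = ci.iloc[:, 0].to_numpy()
        df["ci_upper"] = ci.iloc[:, 1].to_numpy()
        curves[str(g)] = df
        # median = first time the survival estimate reaches 0.5 or below
        at_or_below = df.index[df["KM_estimate"] <= 0.5 + 1e-12]
        medians[str(g)] = float(at_or_below[0]) if len(at_or_below) else math.nan
        at_risk = [
            int(((times[mask] >= t)).sum()) for t in ticks
        ]
        risk_rows[str(g)] = at_risk
    risk_table = pd.DataFrame(risk_rows, index=ticks).T
    risk_table.columns = [f"t={t:g}" for t in ticks]
    return KMResult(curves=curves, medians=medians, risk_table=risk_table)


def landmark_groups(
    longit: pd.DataFrame,
    surv: pd.DataFrame,
    landmark_cycle: str = "C4D1",
    threshold: int = 1,
    endpoint: str = "rpfs",
) -> pd.DataFrame:
    """Survival table with a landmark covariate group per patient.

    The group is 1 when the patient's running reversion count at (or last
    before) the landmark cycle day is >= ``threshold``; only information
    available by the landmark is used. Time is measured from treatment start.
    """
    lday = cycle_day(landmark_cycle)
    t_col, e_col = f"{endpoint}_months", f"{endpoint}_event"
    rows = []
    for _, s in surv.iterrows():
        pid = s["patient"]
        recs = longit[(longit["patient"] == pid) & (longit["day"] <= lday)]
        if len(recs) == 0:
            raise ValueError(f"patient {pid} has no record by {landmark_cycle}")
        count = int(recs.sort_values("day")["count"].iloc[-1])
        rows.append(
            {"patient": pid, "time": float(s[t_col]), "event": int(s[e_col]),
             "count_at_landmark": count, "group": int(count >= threshold)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rank correlation
# ---------------------------------------------------------------------------

def kendall_tau(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Kendall's tau-b with tie correction; p from the normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("all-tied vector: tau undefined")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
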