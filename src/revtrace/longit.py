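"""Longitudinal reversion dynamics: per-timepoint summaries and emergence rates.

Per sample, reversion calls are condensed to a count, a summed allele-fraction
mass and a Shannon diversity index over supporting-read proportions. Across a
cohort, per-patient reversion emergence rates (reversions/month) are estimated
with a Gaussian linear mixed model carrying a random intercept and random
slope per patient, fitted by maximum likelihood; per-patient slopes are the
fixed slope plus the empirical-Bayes (BLUP) slope deviation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from .reversion import ReversionCall

DAYS_PER_MONTH = 30.44

__all__ = [
    "LongitudinalRecord",
    "RateModelFit",
    "shannon_index",
    "summarize_timepoint",
    "annotate_first_seen",
    "cumulative_distinct",
    "fit_reversion_rate",
    "max_reversions",
]


@dataclass
class LongitudinalRecord:
    """Per-patient, per-timepoint reversion summary."""

    patient: str
    timepoint: str            # e.g. C1D1 ... C9D1, EOT
    day: float                # days from treatment start
    n_reversions: int
    af_mass: float            # summed reversion allele fraction
    shannon_h: float          # nats
    pathogenic_af: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_reversions < 0:
            raise ValueError("n_reversions must be >= 0")
        if not (0.0 <= self.af_mass <= 1.0):
            raise ValueError("af_mass must be in [0,1]")


@dataclass
class RateModelFit:
    """Random-intercept/random-slope LMM fit of reversion counts over months."""

    beta0: float
    beta1: float              # fixed slope, reversions/month
    var_b0: float
    var_b1: float
    cov_b01: float
    sigma2: float
    per_patient_slope: dict[str, float]
    per_patient_intercept: dict[str, float]
    loglik: float
    converged: bool


def shannon_index(weights: np.ndarray | list[float]) -> float:
    """Shannon diversity H = -sum p_i ln p_i over positive weights (nats)."""
    w = np.asarray(weights, dtype=float)
    w = w[w > 0]
    if w.size <= 1:
        return 0.0
    p = w / w.sum()
    return float(-(p * np.log(p)).sum())


def summarize_timepoint(
    calls: list[ReversionCall],
    total_reads: int,
    patient: str,
    timepoint: str,
    day: float,
    pathogenic_af: float = float("nan"),
) -> LongitudinalRecord:
    """Condense one sample's calls to a LongitudinalRecord.

    Shannon proportions are supporting-read counts over the summed support of
    all calls in the sample; a single call (or none) gives H = 0.
    """
    supports = np.array([c.support_reads for c in calls], dtype=float)
    af_mass = float(sum(c.support_reads for c in calls) / total_reads) if total_reads else 0.0
    return LongitudinalRecord(
        patient=patient,
        timepoint=timepoint,
        day=day,
        n_reversions=len(calls),
        af_mass=min(af_mass, 1.0),
        shannon_h=shannon_index(supports),
        pathogenic_af=pathogenic_af,
    )


def annotate_first_seen(
    calls_by_timepoint: dict[str, list[ReversionCall]],
    order: list[str] | None = None,
    baseline_label: str | None = None,
) -> None:
    """Stamp each call's first_seen with the earliest timepoint showing the
    same left-aligned event identity; flag events already present at baseline."""
    labels = order if order is not None else list(calls_by_timepoint)
    first: dict[tuple, str] = {}
    for label in labels:
        for call in calls_by_timepoint.get(label, []):
            key = call.event_key()
            if key not in first:
                first[key] = label
    for label in labels:
        for call in calls_by_timepoint.get(label, []):
            call.first_seen = first[call.event_key()]
            if baseline_label is not None:
                call.baseline_detected = first[call.event_key()] == baseline_label
    return None


def cumulative_distinct(
    calls_by_timepoint: dict[str, list[ReversionCall]], order: list[str]
) -> dict[str, int]:
    """Running count of distinct reversion identities observed by each timepoint."""
    seen: set[tuple] = set()
    out: dict[str, int] = {}
    for label in order:
        for call in calls_by_timepoint.get(label, []):
            seen.add(call.event_key())
        out[label] = len(seen)
    return out


def fit_reversion_rate(
    records: pd.DataFrame,
    random_effects: bool = True,
) -> RateModelFit:
    """Per-patient reversion emergence rates from a random-slope LMM.

    ``records`` needs columns patient, day, n_reversions. Days are converted
    to months (1 month = 30.44 days) and a Gaussian LMM
    ``n_reversions ~ 1 + month`` with per-patient random intercept and slope
    is fitted by maximum likelihood (ML rather than REML, so log-likelihoods
    are comparable across fixed-effect structures). Per-patient slopes are
    beta1 plus the empirical-Bayes slope deviation. With
    ``random_effects=False`` the model collapses to pooled OLS, with all
    variance components zero.
    """
    required = {"patient", "day", "n_reversions"}
    if not required <= set(records.columns):
        raise ValueError(f"records must carry columns {sorted(required)}")
    df = records.copy()
    df["month"] = df["day"] / DAYS_PER_MONTH
    patients = df["patient"].unique()
    if len(patients) < 2:
        raise ValueError("need at least 2 patients")
    if df["month"].nunique() < 2:
        raise ValueError("singular design: all observations at one timepoint")

    if not random_effects:
        X = sm.add_constant(df["month"].to_numpy())
        ols = sm.OLS(df["n_reversions"].to_numpy(), X).fit()
        b0, b1 = float(ols.params[0]), float(ols.params[1])
        return RateModelFit(
            beta0=b0, beta1=b1, var_b0=0.0, var_b1=0.0, cov_b01=0.0,
            sigma2=float(ols.scale),
            per_patient_slope={p: b1 for p in patients},
            per_patient_intercept={p: b0 for p in patients},
            loglik=float(ols.llf), converged=True,
        )

    # degenerate case: per-patient data exactly linear (zero residual). The
    # marginal likelihood is maximized in the sigma^2 -> 0 limit, where the
    # empirical-Bayes slopes equal the per-patient least-squares slopes; the
    # numerical optimizer cannot reach that boundary, so handle it directly.
    coefs = {}
    rss = 0.0
    scale_ref = 0.0
    for p, grp in df.groupby("patient"):
        x = grp["month"].to_numpy()
        y = grp["n_reversions"].to_numpy(dtype=float)
        if len(grp) >= 2 and np.ptp(x) > 0:
            b1, b0 = np.polyfit(x, y, 1)
            coefs[str(p)] = (float(b0), float(b1))
            rss += float(np.sum((y - (b0 + b1 * x)) ** 2))
            scale_ref += float(np.sum(y**2)) + 1.0
    if coefs and len(coefs) == len(patients) and rss <= 1e-12 * scale_ref:
        b0s = np.array([c[0] for c in coefs.values()])
        b1s = np.array([c[1] for c in coefs.values()])
        cov = np.cov(np.vstack([b0s, b1s]), ddof=0) if len(coefs) > 1 else np.zeros((2, 2))
        return RateModelFit(
            beta0=float(b0s.mean()), beta1=float(b1s.mean()),
            var_b0=float(cov[0, 0]), var_b1=float(cov[1, 1]), cov_b01=float(cov[0, 1]),
            sigma2=0.0,
            per_patient_slope={p: c[1] for p, c in coefs.items()},
            per_patient_intercept={p: c[0] for p, c in coefs.items()},
            loglik=float("nan"), converged=True,
        )

    exog = sm.add_constant(df["month"].to_numpy())
    model = MixedLM(
        endog=df["n_reversions"].to_numpy(),
        exog=exog,
        groups=df["patient"].to_numpy(),
        exog_re=exog,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=False, method="lbfgs", maxiter=500)
            if not fit.converged:
                fit = model.fit(reml=False, method="powell", maxiter=2000)
        except Exception:
            fit = model.fit(reml=False, method="powell", maxiter=2000)

    b0, b1 = float(fit.fe_params[0]), float(fit.fe_params[1])
    cov_re = np.asarray(fit.cov_re)
    re = fit.random_effects
    slopes = {str(p): b1 + float(re[p].iloc[1]) for p in re}
    intercepts = {str(p): b0 + float(re[p].iloc[0]) for p in re}
    return RateModelFit(
        beta0=b0,
        beta1=b1,
        var_b0=float(cov_re[0, 0]),
        var_b1=float(cov_re[1, 1]),
        cov_b01=float(cov_re[0, 1]),
        sigma2=float(fit.scale),
        per_patient_slope=slopes,
        per_patient_intercept=intercepts,
        loglik=float(fit.llf),
        converged=bool(fit.converged),
    )


def max_reversions(records: pd.DataFrame) -> pd.Series:
    """Maximum reversion count per patient across all timepoints."""
    if len(records) == 0:
        raise ValueError("no records")
    return records.groupby("patient")["n_reversions"].max()
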