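"""Kaplan-Meier, log-rank and Cox proportional-hazards analysis of genes.

Local replacement for web-based survival lookups: patients are dichotomized
by a gene's expression at the median, overall survival is compared between
the high and low groups via the product-limit estimator and the log-rank
test, and hazard ratios with Wald 95% confidence intervals come from a Cox
proportional-hazards fit.

KM estimation and the log-rank statistic delegate to ``lifelines``; the Cox
partial likelihood is maximized here by Newton-Raphson with Breslow tie
handling (Efron available behind a flag), tolerance 1e-8 on the coefficient
change, at most 50 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .errors import SurvivalError


@dataclass
class SurvivalCohort:
    """Per-subject survival records.

    ``data`` must carry positive ``time`` and binary ``event`` columns;
    optional columns include ``group`` ({"high", "low"}), ``expression`` and
    arbitrary covariates.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise SurvivalError(f"cohort missing required column {col!r}")
        if (self.data["time"] <= 0).any():
            raise SurvivalError("all survival times must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise SurvivalError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class CoxFit:
    """A converged Cox proportional-hazards fit (Wald inference)."""

    coefficients: pd.Series
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    standard_errors: pd.Series
    p_values: pd.Series
    log_partial_likelihood: float
    n_iterations: int
    achieved_tolerance: float


@dataclass
class GeneSurvivalReport:
    """Bundled high-vs-low report for one gene."""

    gene: str
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    logrank_chi2: float
    logrank_p: float
    km_high: pd.DataFrame
    km_low: pd.DataFrame
    n_high: int
    n_low: int


def dichotomize_by_median(expression: np.ndarray | pd.Series) -> np.ndarray:
    """Split subjects into "high"/"low" at the median.

    Values strictly above the median are "high"; ties at the median go to
    "low".
    """
    values = np.asarray(expression, dtype=float)
    if values.size < 2:
        raise SurvivalError("need >= 2 subjects to dichotomize")
    med = np.median(values)
    high = values > med
    if high.all() or not high.any():
        raise SurvivalError("expression admits no median split (all values equal?)")
    return np.where(high, "high", "low")


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate over distinct event times.

    Returns a frame indexed by time with columns ``survival`` (S(t)),
    ``at_risk`` and ``events``; censored-only times change the risk set
    only.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame({
        "survival": surv.to_numpy(),
        "at_risk": table["at_risk"].to_numpy(),
        "events": table["observed"].to_numpy(),
    }, index=surv.index.rename("time"))
    return out


def logrank_test(cohort_a: SurvivalCohort, cohort_b: SurvivalCohort) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    if len(cohort_a) == 0 or len(cohort_b) == 0:
        raise SurvivalError("both groups must be non-empty")
    if int(cohort_a.data["event"].sum() + cohort_b.data["event"].sum()) == 0:
        raise SurvivalError("log-rank test undefined with no events")
    res = _ll_logrank(
        cohort_a.data["time"], cohort_b.data["time"],
        event_observed_A=cohort_a.data["event"],
        event_observed_B=cohort_b.data["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def _partial_likelihood_parts(beta, times, events, x, ties):
    """Breslow/Efron log partial likelihood, gradient, Hessian."""
    eta = x @ beta
    w = np.exp(np.clip(eta, -700.0, 700.0))
    order = np.argsort(-times, kind="stable")  # decreasing time
    loglik = 0.0
    grad = np.zeros_like(beta)
    hess = np.zeros((beta.size, beta.size))

    # cumulative risk-set sums built walking from the largest time down
    s0 = 0.0
    s1 = np.zeros_like(beta)
    s2 = np.zeros((beta.size, beta.size))
    i = 0
    n = times.size
    while i < n:
        t = times[order[i]]
        j = i
        while j < n and times[order[j]] == t:
            idx = order[j]
            xi = x[idx]
            s0 += w[idx]
            s1 += w[idx] * xi
            s2 += w[idx] * np.outer(xi, xi)
            j += 1
        deaths = [order[k] for k in range(i, j) if events[order[k]] == 1]
        d = len(deaths)
        if d:
            xd = x[deaths]
            wd = w[deaths]
            loglik += float(eta[deaths].sum())
            if ties == "breslow":
                mean = s1 / s0
                loglik -= d * np.log(s0)
                grad += xd.sum(axis=0) - d * mean
                hess -= d * (s2 / s0 - np.outer(mean, mean))
            else:  # efron
                d0 = wd.sum()
                d1 = (wd[:, None] * xd).sum(axis=0)
                d2 = (wd[:, None, None] * xd[:, :, None] * xd[:, None, :]).sum(axis=0)
                for ell in range(d):
                    c = ell / d
                    a0 = s0 - c * d0
                    a1 = s1 - c * d1
                    a2 = s2 - c * d2
                    mean = a1 / a0
                    loglik -= np.log(a0)
                    grad -= mean
                    hess -= a2 / a0 - np.outer(mean, mean)
                grad += xd.sum(axis=0)
        i = j
    return loglik, grad, hess


def cox_fit(cohort: SurvivalCohort, covariates: list[str],
            ties: str = "breslow") -> CoxFit:
    """Newton-Raphson maximization of the Cox partial likelihood.

    Categorical covariates must be pre-encoded as numeric columns. Raises
    :class:`SurvivalError` on non-convergence, a singular information
    matrix, or monotone likelihood (perfect separation).
    """
    if ties not in ("breslow", "efron"):
        raise SurvivalError(f"unknown tie handling {ties!r}")
    if int(cohort.data["event"].sum()) == 0:
        raise SurvivalError("Cox fit requires at least one event")
    x = cohort.data[covariates].to_numpy(dtype=float)
    x = x - x.mean(axis=0)  # centering for numerical stability
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise SurvivalError("design matrix is rank deficient")
    times = cohort.data["time"].to_numpy(dtype=float)
    events = cohort.data["event"].to_numpy(dtype=int)

    beta = np.zeros(x.shape[1])
    tol, max_iter = 1e-8, 50
    loglik, grad, hess = _partial_likelihood_parts(beta, times, events, x, ties)
    achieved = np.inf
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise SurvivalError(f"singular information matrix: {exc}") from exc
        # step halving keeps the likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            new_ll, new_grad, new_hess = _partial_likelihood_parts(
                cand, times, events, x, ties)
            if np.isfinite(new_ll) and new_ll >= loglik - 1e-12:
                break
            scale *= 0.5
        else:
            raise SurvivalError("Cox fit: step halving failed to improve")
        achieved = float(np.max(np.abs(cand - beta)))
        beta, loglik, grad, hess = cand, new_ll, new_grad, new_hess
        if achieved < tol:
            break
    else:
        raise SurvivalError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(last coefficient change {achieved:.2e})"
        )
    if np.max(np.abs(beta)) > 15:
        raise SurvivalError(
            "monotone partial likelihood detected (perfect separation): "
            f"|beta| reached {np.max(np.abs(beta)):.1f}"
        )
    info = -hess
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    idx = pd.Index(covariates)
    return CoxFit(
        coefficients=pd.Series(beta, index=idx),
        hazard_ratios=pd.Series(np.exp(beta), index=idx),
        ci_lower=pd.Series(np.exp(beta - 1.96 * se), index=idx),
        ci_upper=pd.Series(np.exp(beta + 1.96 * se), index=idx),
        standard_errors=pd.Series(se, index=idx),
        p_values=pd.Series(p, index=idx),
        log_partial_likelihood=float(loglik),
        n_iterations=it,
        achieved_tolerance=achieved,
    )


def gene_survival_report(gene: str, expression, cohort: SurvivalCohort,
                         ties: str = "breslow") -> GeneSurvivalReport:
    """High-vs-low survival report for one gene (median dichotomization)."""
    values = np.asarray(expression, dtype=float)
    if values.size != len(cohort):
        raise SurvivalError(
            f"expression length {values.size} does not match cohort size "
            f"{len(cohort)}"
        )
    groups = dichotomize_by_median(values)
    df = cohort.data.copy()
    df["_high"] = (groups == "high").astype(float)
    high = SurvivalCohort(df[df["_high"] == 1.0])
    low = SurvivalCohort(df[df["_high"] == 0.0])
    chi2, p = logrank_test(high, low)
    fit = cox_fit(SurvivalCohort(df), ["_high"], ties=ties)
    return GeneSurvivalReport(
        gene=gene,
        hazard_ratio=float(fit.hazard_ratios.iloc[0]),
        ci_lower=float(fit.ci_lower.iloc[0]),
        ci_upper=float(fit.ci_upper.iloc[0]),
        logrank_chi2=chi2,
        logrank_p=p,
        km_high=km_estimate(high.data["time"], high.data["event"]),
        km_low=km_estimate(low.data["time"], low.data["event"]),
        n_high=len(high),
        n_low=len(low),
    )
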