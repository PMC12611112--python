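"""Time-to-onset (TTO) analysis with a two-parameter Weibull model.

TTO for a report is the number of days from the earliest primary-suspect
therapy start date to the adverse-event date; only day-precision dates enter
by default.  Outliers are removed with Tukey fences on the interquartile
range, quartiles use linear interpolation between order statistics
(positions 1 + (n-1)p, the "type 7" convention), and the kept sample is fit
by maximum likelihood to the Weibull density

    f(t) = (beta/alpha) * (t/alpha)^(beta-1) * exp(-(t/alpha)^beta),

whose shape parameter beta classifies the hazard: beta < 1 means a
decreasing hazard ("early failure" — events cluster soon after therapy
start), beta > 1 an increasing hazard ("wear-out"), beta = 1 the
constant-hazard exponential ("random").  Confidence intervals come from the
observed information on (log alpha, log beta), exponentiated so the bounds
stay positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .faers_io import CaseRecord


def compute_tto(record: CaseRecord, drug: str,
                impute_month_to_day1: bool = False) -> float | None:
    """Days from the drug's earliest primary-suspect start to the event.

    Returns ``None`` when either date is missing or below day precision
    (unless month-precision imputation to day 1 is enabled), or when the
    difference is not strictly positive.
    """

    def usable(date):
        if date is None:
            return None
        if date.precision == "day":
            return date.to_date()
        if date.precision == "month" and impute_month_to_day1:
            import datetime
            return datetime.date(date.year, date.month, 1)
        return None

    event = usable(record.event_dt)
    if event is None:
        return None
    starts = [usable(d.start_dt) for d in record.drugs
              if d.canonical == drug and d.role == "PS"]
    starts = [s for s in starts if s is not None]
    if not starts:
        return None
    days = (event - min(starts)).days
    return float(days) if days > 0 else None


def quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, q1, q3) by linear interpolation between order statistics."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


@dataclass(slots=True)
class TtoSample:
    """Kept onset times (days) after outlier exclusion."""

    drug: str
    values: list[float]
    excluded_outliers: list[float]

    @property
    def n_kept(self) -> int:
        return len(self.values)


def iqr_filter(values: Sequence[float], k: float = 1.5,
               drug: str = "") -> TtoSample:
    """Tukey-fence outlier exclusion: keep values in
    [Q1 - k*IQR, Q3 + k*IQR]."""
    if len(values) == 0:
        raise ValueError("empty sample")
    _, q1, q3 = quartiles(values)
    iqr = q3 - q1
    low, high = q1 - k * iqr, q3 + k * iqr
    kept = [v for v in values if low <= v <= high]
    out = [v for v in values if not (low <= v <= high)]
    return TtoSample(drug=drug, values=kept, excluded_outliers=out)


@dataclass(slots=True)
class WeibullFit:
    """Maximum-likelihood Weibull fit of a TTO sample."""

    scale_alpha: float
    scale_ci95: tuple[float, float]
    shape_beta: float
    shape_ci95: tuple[float, float]
    median_days: float              # empirical sample median
    iqr_days: tuple[float, float]   # empirical (q1, q3)
    n: int
    failure_type: str               # early | random | wear-out
    ci_excludes_one: bool           # whether the beta CI excludes 1
    n_iterations: int

    @property
    def fitted_median(self) -> float:
        """Model median alpha * (ln 2)^(1/beta)."""
        return self.scale_alpha * math.log(2) ** (1 / self.shape_beta)


class WeibullFitError(RuntimeError):
    pass


def _negloglik_and_grad(theta: np.ndarray, x: np.ndarray):
    """Negative log-likelihood and gradient in (log alpha, log beta)."""
    log_alpha, log_beta = theta
    beta = math.exp(log_beta)
    z = np.log(x) - log_alpha          # log(t/alpha)
    bz = beta * z
    ebz = np.exp(bz)
    n = x.size
    nll = -(n * log_beta - n * log_alpha + (beta - 1) * np.sum(z) - np.sum(ebz))
    # d nll / d log_alpha and d log_beta
    d_la = -(-n * beta + beta * np.sum(ebz))   # note: -(dll/dla)
    d_lb = -(n + beta * np.sum(z) - np.sum(bz * ebz))
    return nll, np.array([d_la, d_lb])


def classify_failure(beta: float, beta_ci: tuple[float, float],
                     tol: float = 1e-6) -> tuple[str, bool]:
    """(failure type, whether the CI excludes 1).

    The label follows the point estimate: below 1 "early", above 1
    "wear-out", within ``tol`` of 1 "random".  Whether the interval
    excludes 1 is reported alongside rather than deciding the label.
    """
    excludes = beta_ci[0] > 1.0 or beta_ci[1] < 1.0
    if abs(beta - 1.0) <= tol:
        return "random", excludes
    return ("early" if beta < 1.0 else "wear-out"), excludes


def fit_weibull(sample: TtoSample, grad_tol: float = 1e-8,
                max_iter: int = 200) -> WeibullFit:
    """Fit Weibull(alpha, beta) to the kept sample by maximum likelihood.

    Optimizes the log-likelihood in (log alpha, log beta); declares
    convergence when the gradient norm drops below ``grad_tol`` (within
    ``max_iter`` iterations).  95% CIs are Wald intervals on the log
    parameters from the observed information, exponentiated.
    """
    x = np.asarray(sample.values, dtype=float)
    if x.size < 3:
        raise WeibullFitError(f"need at least 3 onset times, got {x.size}")
    if np.any(x <= 0):
        raise WeibullFitError("onset times must be positive")
    if np.ptp(x) == 0:
        raise WeibullFitError("degenerate sample: all onset times identical")

    theta0 = np.array([math.log(float(np.mean(x))), 0.0])
    res = optimize.minimize(
        _negloglik_and_grad, theta0, args=(x,), jac=True, method="BFGS",
        options={"gtol": grad_tol, "maxiter": max_iter})
    grad_norm = float(np.linalg.norm(res.jac))
    if grad_norm > max(grad_tol, 1e-5 * (1 + abs(res.fun))):
        raise WeibullFitError(
            f"no convergence after {res.nit} iterations "
            f"(|grad| = {grad_norm:.3g}); trace: {res.message}")

    log_alpha, log_beta = res.x
    hess = _numerical_hessian(res.x, x)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:
        raise WeibullFitError("singular observed information") from exc
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    alpha = math.exp(log_alpha)
    beta = math.exp(log_beta)
    alpha_ci = (alpha * math.exp(-1.96 * se[0]), alpha * math.exp(1.96 * se[0]))
    beta_ci = (beta * math.exp(-1.96 * se[1]), beta * math.exp(1.96 * se[1]))
    med, q1, q3 = quartiles(sample.values)
    ftype, excludes = classify_failure(beta, beta_ci)
    return WeibullFit(
        scale_alpha=alpha, scale_ci95=alpha_ci,
        shape_beta=beta, shape_ci95=beta_ci,
        median_days=med, iqr_days=(q1, q3),
        n=x.size, failure_type=ftype, ci_excludes_one=excludes,
        n_iterations=res.nit,
    )


def _numerical_hessian(theta: np.ndarray, x: np.ndarray,
                       eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of the negative log-likelihood from its
    analytic gradient."""
    hess = np.empty((2, 2))
    for j in range(2):
        step = np.zeros(2)
        step[j] = eps
        _, g_plus = _negloglik_and_grad(theta + step, x)
        _, g_minus = _negloglik_and_grad(theta - step, x)
        hess[:, j] = (g_plus - g_minus) / (2 * eps)
    return (hess + hess.T) / 2


def cumulative_incidence(values: Sequence[float]) -> list[tuple[float, float]]:
    """Empirical CDF step points at sorted distinct onset times."""
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("empty sample")
    distinct, counts = np.unique(arr, return_counts=True)
    cum = np.cumsum(counts) / arr.size
    return [(float(v), float(f)) for v, f in zip(distinct, cum)]


def tto_sample_for_drug(records: Sequence[CaseRecord], drug: str,
                        k: float = 1.5,
                        impute_month_to_day1: bool = False) -> TtoSample:
    """Collect onset times for a drug's primary-suspect reports and apply
    the IQR outlier filter."""
    values = []
    for record in records:
        days = compute_tto(record, drug, impute_month_to_day1)
        if days is not None:
            values.append(days)
    if not values:
        return TtoSample(drug=drug, values=[], excluded_outliers=[])
    return iqr_filter(values, k=k, drug=drug)
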