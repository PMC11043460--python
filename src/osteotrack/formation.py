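"""Formation-time estimation: interpolated onset ages and censored Weibull MLE.

The age at which an osteophyte first appears is never observed directly —
radiographs are taken at follow-up visits, not continuously.  Two stages
recover the formation-age distribution:

1. Per vertebra, the formation age tau is estimated as the zero-ORI crossing
   of the straight line through the first and last positive-ORI observations
   (the growth trend is linear in the mean, so the two-point line is an
   unbiased backcast).
2. Across vertebrae, the Weibull(a, b) law of the formation age is fitted by
   maximum likelihood; osteophyte-free vertebrae enter as right-censored at
   their last-visit age.

The log-likelihood with N interpolated event ages tau_i and censoring ages
tau_k is

    l(a, b) = N log b - b N log a + (b - 1) sum_i log tau_i
              - sum_i (tau_i / a)^b - sum_k (tau_k / a)^b
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .exceptions import (
    DegenerateSeriesError,
    EstimationError,
    InsufficientDataError,
    ParameterError,
)
from .io import VertebraSeries, WeibullParams, logger

__all__ = [
    "FormationData",
    "interpolate_formation_time",
    "formation_data_from_cohort",
    "weibull_censored_loglik",
    "WeibullFormationMLE",
    "fit_weibull",
]

_EPS_AGE = 1e-6

EULER_GAMMA = 0.5772156649015329


@dataclass(frozen=True)
class FormationData:
    """Event (interpolated) and right-censoring formation ages, in years."""

    event_times: np.ndarray
    censor_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "event_times", np.asarray(self.event_times, float))
        object.__setattr__(self, "censor_times", np.asarray(self.censor_times, float))
        if self.event_times.size < 1:
            raise InsufficientDataError("at least one event time required")
        if np.any(self.event_times <= 0) or np.any(self.censor_times <= 0):
            raise ParameterError("all formation/censoring times must be > 0")

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)

    @property
    def n_censored(self) -> int:
        return int(self.censor_times.size)


def interpolate_formation_time(
    series: VertebraSeries, *, nonpositive: str = "clamp"
) -> float:
    """Backcast the formation age from the first/last positive observations.

    The line through (age_first_pos, ori_first_pos) and
    (age_last_pos, ori_last_pos) is extended to ORI = 0.  The crossing is
    clamped into (0, age_first_pos]; a crossing earlier than half the
    first-positive age is kept but triggers a warning, since the two-point
    line is then extrapolating far beyond the data.

    ``nonpositive`` controls a crossing at or before age 0 (physically
    impossible): ``"clamp"`` warns and returns a small epsilon age,
    ``"raise"`` raises :class:`DegenerateSeriesError` so callers can drop
    the series as an unreliable backcast.
    """
    pos = series.positive_records
    if series.censored:
        raise DegenerateSeriesError(f"series {series.key} is censored; no formation time")
    if len(pos) < 2 or pos[-1].age <= pos[0].age:
        raise InsufficientDataError(
            f"series {series.key}: two distinct positive-ORI ages required"
        )
    t0, x0 = pos[0].age, pos[0].ori
    t1, x1 = pos[-1].age, pos[-1].ori
    if x0 == 0.0:  # zero exactly at an observation: formation at that visit
        return t0
    slope = (x1 - x0) / (t1 - t0)
    if slope <= 0:
        raise DegenerateSeriesError(
            f"series {series.key}: non-increasing trend, formation time unidentifiable"
        )
    tau = t0 - x0 / slope
    if tau <= 0:
        if nonpositive == "raise":
            raise DegenerateSeriesError(
                f"series {series.key}: backcast formation age {tau:.2f} <= 0"
            )
        warnings.warn(
            f"series {series.key}: interpolated formation age {tau:.2f} <= 0; "
            f"clamped to {_EPS_AGE}",
            stacklevel=2,
        )
        return _EPS_AGE
    if tau < 0.5 * t0:
        warnings.warn(
            f"series {series.key}: interpolated formation age {tau:.2f} is earlier than "
            f"half the first positive-observation age {t0:.2f}; the two-point line is "
            "extrapolating far outside the data",
            stacklevel=2,
        )
    return min(tau, t0)


def formation_data_from_cohort(
    cohort: list[VertebraSeries],
) -> tuple[FormationData, list[VertebraSeries]]:
    """Interpolate every usable series; censored series become censor times.

    Returns the pooled formation data and the cohort with ``tau_hat`` filled
    in on the event series (order preserved, unusable series passed through).
    """
    events, censors, out = [], [], []
    n_skipped = 0
    for s in cohort:
        if s.censored:
            censors.append(s.censor_age)
            out.append(s)
        elif s.usable_for_interpolation:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    tau = interpolate_formation_time(s, nonpositive="raise")
            except DegenerateSeriesError:
                n_skipped += 1
                out.append(s)
                continue
            events.append(tau)
            out.append(s.with_tau(tau))
        else:
            n_skipped += 1
            out.append(s)
    if n_skipped:
        logger.info("formation interpolation skipped %d unusable series", n_skipped)
    logger.info(
        "formation data: %d events, %d censored", len(events), len(censors)
    )
    return FormationData(np.array(events), np.array(censors)), out


def weibull_censored_loglik(a: float, b: float, data: FormationData) -> float:
    """Right-censored Weibull log-likelihood at (a, b)."""
    if not (a > 0 and b > 0):
        raise ParameterError(f"scale and shape must be > 0, got a={a}, b={b}")
    tau = data.event_times
    n = data.n_events
    ll = (
        n * math.log(b)
        - b * n * math.log(a)
        + (b - 1.0) * float(np.sum(np.log(tau)))
        - float(np.sum((tau / a) ** b))
        - float(np.sum((data.censor_times / a) ** b))
    )
    return ll


def _loglik_grad(a: float, b: float, data: FormationData) -> np.ndarray:
    """Analytic gradient of the censored log-likelihood in (a, b)."""
    tau, cen = data.event_times, data.censor_times
    n = data.n_events
    alltimes = np.concatenate([tau, cen])
    z = (alltimes / a) ** b
    da = -b * n / a + (b / a) * np.sum(z)
    db = n / b - n * math.log(a) + np.sum(np.log(tau)) - np.sum(z * np.log(alltimes / a))
    return np.array([da, db])


class WeibullFormationMLE(BaseEstimator):
    """Censored-Weibull maximum-likelihood estimator of the formation-age law.

    Parameters
    ----------
    fix_shape : float, optional
        Hold the shape b at this value and solve the scale in closed form
        (b = 1 reduces to the exponential total-time-on-test estimator).
    gtol : float
        Gradient-norm tolerance of the optimiser (in log-parameters).

    Attributes
    ----------
    a_, b_ : float
        Fitted scale (years) and shape.
    se_a_, se_b_ : float
        Standard errors from the observed information matrix.
    loglik_ : float
        Log-likelihood at the optimum.
    n_events_, n_censored_ : int
    """

    def __init__(self, fix_shape: float | None = None, gtol: float = 1e-8):
        self.fix_shape = fix_shape
        self.gtol = gtol

    def fit(self, data: FormationData) -> "WeibullFormationMLE":
        tau = data.event_times
        if self.fix_shape is not None:
            b = float(self.fix_shape)
            if b <= 0:
                raise ParameterError("fix_shape must be > 0")
            total = float(np.sum(tau**b) + np.sum(data.censor_times**b))
            a = (total / data.n_events) ** (1.0 / b)
            self.a_, self.b_ = a, b
        else:
            if np.unique(tau).size < 2:
                raise InsufficientDataError(
                    "free-shape fit needs >= 2 distinct event times"
                )
            theta0 = np.log(self._moment_start(tau))

            def neg(theta: np.ndarray) -> tuple[float, np.ndarray]:
                a, b = np.exp(theta)
                g = _loglik_grad(a, b, data) * np.array([a, b])  # chain rule
                return -weibull_censored_loglik(a, b, data), -g

            res = optimize.minimize(
                neg, theta0, jac=True, method="BFGS", options={"gtol": self.gtol}
            )
            if not res.success and np.linalg.norm(res.jac) > 1e-4:
                raise EstimationError(f"Weibull MLE did not converge: {res.message}")
            self.a_, self.b_ = (float(v) for v in np.exp(res.x))
            ll0 = weibull_censored_loglik(*np.exp(theta0), data)
            if weibull_censored_loglik(self.a_, self.b_, data) < ll0 - 1e-9:
                raise EstimationError("optimum below the moment-matched start")
        self.loglik_ = weibull_censored_loglik(self.a_, self.b_, data)
        self.n_events_ = data.n_events
        self.n_censored_ = data.n_censored
        self.se_a_, self.se_b_ = self._standard_errors(data)
        logger.info(
            "Weibull fit: a=%.4f (SE %.3g), b=%.4f (SE %.3g), loglik=%.4f",
            self.a_, self.se_a_, self.b_, self.se_b_, self.loglik_,
        )
        return self

    @staticmethod
    def _moment_start(tau: np.ndarray) -> np.ndarray:
        """Gumbel moment-matching on log event ages."""
        s = float(np.std(np.log(tau), ddof=1))
        b0 = math.pi / (math.sqrt(6.0) * max(s, 1e-3))
        a0 = math.exp(float(np.mean(np.log(tau))) + EULER_GAMMA / b0)
        return np.array([a0, b0])

    def _standard_errors(self, data: FormationData) -> tuple[float, float]:
        """Observed-information SEs via central-difference Hessian."""
        a, b = self.a_, self.b_
        h = np.array([a, b]) * 1e-5

        def ll(p: np.ndarray) -> float:
            return weibull_censored_loglik(p[0], p[1], data)

        H = np.empty((2, 2))
        p0 = np.array([a, b])
        for i in range(2):
            for j in range(2):
                pp = p0.copy(); pp[i] += h[i]; pp[j] += h[j]
                pm = p0.copy(); pm[i] += h[i]; pm[j] -= h[j]
                mp = p0.copy(); mp[i] -= h[i]; mp[j] += h[j]
                mm = p0.copy(); mm[i] -= h[i]; mm[j] -= h[j]
                H[i, j] = (ll(pp) - ll(pm) - ll(mp) + ll(mm)) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(-H)
            if cov[0, 0] <= 0 or cov[1, 1] <= 0:
                return float("nan"), float("nan")
            return float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        except np.linalg.LinAlgError:
            return float("nan"), float("nan")

    @property
    def params_(self) -> WeibullParams:
        return WeibullParams(a=self.a_, b=self.b_)


def fit_weibull(
    data: FormationData, *, fix_shape: float | None = None, gtol: float = 1e-8
) -> WeibullFormationMLE:
    """Functional wrapper over :class:`WeibullFormationMLE`."""
    return WeibullFormationMLE(fix_shape=fix_shape, gtol=gtol).fit(data)
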