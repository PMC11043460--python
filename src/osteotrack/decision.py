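"""Decision support: remaining time to pain onset for a patient measured now.

Given a current ORI x0 below the threshold c, the Wiener process' stationary
independent increments make the remaining passage time inverse-Gaussian with
an effective barrier c - x0:

    S_rem ~ IG((c - x0)/mu, (c - x0)^2/sigma^2),   E[S_rem] = (c - x0)/mu.

The workflow bundles the predicted 10-year ORI band anchored at x0, the
remaining-onset density/survival, its mean, and the ages at which survival
drops through clinician-chosen cut-points (e.g. 80% and 50%), which delimit
observation / physical-therapy / medication phases in the report narrative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import invgauss

from .exceptions import ParameterError
from .io import PainThreshold, SurvivalCurve, WienerParams, logger
from .model import predicted_growth_band

__all__ = [
    "PatientState",
    "RemainingTtoop",
    "remaining_ttoop_distribution",
    "survival_epochs",
    "plan_report",
]


@dataclass(frozen=True)
class PatientState:
    """A patient's current measurement plus the population growth law."""

    current_ori: float
    current_age: float
    threshold: PainThreshold
    params: WienerParams

    def __post_init__(self) -> None:
        if self.current_ori < 0:
            raise ParameterError("current ORI must be >= 0")
        if self.current_age <= 0:
            raise ParameterError("current age must be > 0")

    @property
    def effective_threshold(self) -> float:
        return self.threshold.c - self.current_ori


@dataclass
class RemainingTtoop:
    """Distribution of the years remaining until the threshold is reached."""

    mean: float
    effective_threshold: float
    _mu_ig: float = field(repr=False, default=0.0)  # scipy shape = m/lambda
    _lam: float = field(repr=False, default=0.0)
    immediate: bool = False

    def pdf(self, s):
        if self.immediate:
            return np.zeros_like(np.asarray(s, dtype=float))
        return invgauss.pdf(s, self._mu_ig, scale=self._lam)

    def survival(self, s):
        if self.immediate:
            return np.zeros_like(np.asarray(s, dtype=float)) + 0.0
        return invgauss.sf(s, self._mu_ig, scale=self._lam)

    def survival_curve(self, horizon: float = 10.0, n: int = 512) -> SurvivalCurve:
        grid = np.linspace(0.0, horizon, n)
        surv = np.ones_like(grid) * 0.0 if self.immediate else self.survival(grid)
        surv = np.minimum.accumulate(np.clip(surv, 0.0, 1.0))
        return SurvivalCurve(grid, surv, kind="model")


def remaining_ttoop_distribution(state: PatientState) -> RemainingTtoop:
    """IG law of the remaining time to onset of pain for this patient.

    If the current ORI already meets the threshold, a zero-remaining-time
    result is returned with a warning rather than an error.
    """
    ce = state.effective_threshold
    if ce <= 0:
        logger.warning(
            "current ORI %.3f already at/above threshold %.3f; remaining time 0",
            state.current_ori, state.threshold.c,
        )
        return RemainingTtoop(mean=0.0, effective_threshold=0.0, immediate=True)
    mu, sig = state.params.mu, state.params.sigma
    m = ce / mu
    lam = ce**2 / sig**2
    return RemainingTtoop(mean=m, effective_threshold=ce, _mu_ig=m / lam, _lam=lam)


def survival_epochs(
    state: PatientState,
    cut_points: tuple[float, ...] = (0.8, 0.5),
    horizon: float = 10.0,
    tol: float = 1e-4,
) -> dict[float, float]:
    """Years until the remaining-onset survival drops through each cut-point.

    Cut-points must be strictly decreasing in (0, 1].  A cut-point not
    reached within the horizon maps to ``inf`` (beyond-horizon).
    """
    cps = tuple(cut_points)
    if any(not (0 < p <= 1) for p in cps):
        raise ParameterError("cut-points must lie in (0, 1]")
    if any(b >= a for a, b in zip(cps, cps[1:])):
        raise ParameterError("cut-points must be strictly decreasing")
    rem = remaining_ttoop_distribution(state)
    out: dict[float, float] = {}
    for p in cps:
        if rem.immediate or p == 1.0:
            out[p] = 0.0
            continue
        if rem.survival(horizon) > p:
            out[p] = math.inf
            continue
        out[p] = float(
            optimize.brentq(lambda s: rem.survival(s) - p, 0.0, horizon, xtol=tol)
        )
    return out


_PHASES = (
    "observation (survival above the first cut-point)",
    "physical therapy (survival between cut-points)",
    "medication / specialist referral (survival below the last cut-point)",
)


def plan_report(
    state: PatientState,
    cut_points: tuple[float, ...] = (0.8, 0.5),
    horizon_years: float = 10.0,
    coverage: float = 0.95,
    n_grid: int = 121,
) -> dict:
    """Structured treatment-planning report for one patient.

    Bundles the ORI band over the horizon (anchored at the current ORI),
    the remaining-onset distribution and mean, the survival epochs for the
    cut-points, and a phase narrative.  Deterministic: identical inputs
    yield identical reports.
    """
    rem = remaining_ttoop_distribution(state)
    epochs = survival_epochs(state, cut_points, horizon=horizon_years)
    grid = np.linspace(0.0, horizon_years, n_grid)
    band = predicted_growth_band(grid, state.params, coverage, anchor=state.current_ori)
    lines = [
        f"Current ORI {state.current_ori:.4f} at age {state.current_age:.2f} y; "
        f"threshold {state.threshold.c:.4f} (effective margin "
        f"{max(rem.effective_threshold, 0.0):.4f}).",
    ]
    if rem.immediate:
        lines.append("Threshold already reached: immediate clinical attention phase.")
    else:
        lines.append(f"Mean remaining time to onset of pain: {rem.mean:.2f} years.")
        for (p, e), phase in zip(sorted(epochs.items(), reverse=True), _PHASES):
            when = "beyond horizon" if math.isinf(e) else f"{e:.2f} y"
            lines.append(f"Survival {p:.0%} epoch at {when}: enter {phase}.")
    return {
        "patient": state,
        "band": band,
        "remaining": rem,
        "epochs": epochs,
        "mean_remaining_years": rem.mean,
        "narrative": "\n".join(lines),
    }
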