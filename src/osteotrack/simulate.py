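"""Synthetic longitudinal cohorts with the model's exact generative structure.

Each vertebra draws a formation age tau from Weibull(a, b); before tau its
ORI is exactly 0, after tau the ORI follows a Wiener path with drift mu and
diffusion sigma (independent Gaussian increments between visits).  Visits
are aperiodic: gaps uniform within a configured range inside an observation
window, at least three visits per vertebra.  Vertebrae whose tau falls past
their last visit are emitted fully censored (all-zero series), mirroring the
osteophyte-free fraction seen in follow-up cohorts.

The generator returns the true formation ages alongside the cohort so that
estimation stages can be scored against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import DesignError, ParameterError
from .io import (
    LUMBAR_PARAMS,
    ModelParams,
    VertebraSeries,
    VisitRecord,
    WeibullParams,
    WienerParams,
)

__all__ = [
    "SimulationDesign",
    "simulate_formation_times",
    "simulate_growth_path",
    "simulate_cohort",
    "lumbar_like_design",
    "cervical_like_design",
]


@dataclass
class SimulationDesign:
    """Study design for one synthetic cohort.

    ``visit_interval_range`` bounds the uniform aperiodic gap between
    consecutive visits, in years.  ``clamp_negative`` reflects what the
    imaging pipeline would report (an osteophyte cannot have negative
    length); it is off by default so that the recorded values are exactly
    the Wiener path the growth likelihood models.
    """

    n_vertebrae: int
    params: ModelParams
    study_start_age: float = 35.0
    study_end_age: float = 80.0
    visit_interval_range: tuple[float, float] = (0.5, 2.0)
    measurement_noise_sd: float = 0.0
    clamp_negative: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.visit_interval_range
        if not (0 < lo <= hi):
            raise DesignError(f"need 0 < min gap <= max gap, got {self.visit_interval_range}")
        if not self.study_start_age < self.study_end_age:
            raise DesignError("study_start_age must precede study_end_age")
        if self.n_vertebrae < 1:
            raise DesignError("n_vertebrae must be >= 1")
        if self.measurement_noise_sd < 0:
            raise DesignError("measurement_noise_sd must be >= 0")
        window = self.study_end_age - self.study_start_age
        if window < 2 * lo:
            raise DesignError(
                f"window of {window:.2f} y cannot fit 3 visits at minimum gap {lo:.2f} y"
            )


def lumbar_like_design(n_vertebrae: int = 103, seed: int = 0, **kw) -> SimulationDesign:
    """Design mimicking the published lumbar cohort (n=103, L1-L5)."""
    return SimulationDesign(n_vertebrae=n_vertebrae, params=LUMBAR_PARAMS, seed=seed, **kw)


def cervical_like_design(n_vertebrae: int = 29, seed: int = 0, **kw) -> SimulationDesign:
    """Design mimicking the published cervical cohort (n=29, C3-C7)."""
    from .io import CERVICAL_PARAMS

    return SimulationDesign(n_vertebrae=n_vertebrae, params=CERVICAL_PARAMS, seed=seed, **kw)


def simulate_formation_times(
    n: int, params: WeibullParams, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw n i.i.d. Weibull(a, b) formation ages (years)."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # standard Weibull variate: a * (-log U)^(1/b)
    return params.a * rng.weibull(params.b, size=n)


def simulate_growth_path(
    tau: float,
    params: WienerParams,
    visit_ages: np.ndarray,
    seed: int | np.random.Generator = 0,
    *,
    clamp_negative: bool = False,
) -> np.ndarray:
    """ORI values at the given visit ages for a vertebra formed at ``tau``.

    Zero before formation; afterwards a Wiener path started at (tau, 0) with
    N(mu*dt, sigma^2*dt) increments between consecutive post-formation epochs.
    """
    visit_ages = np.asarray(visit_ages, dtype=float)
    if visit_ages.ndim != 1 or np.any(np.diff(visit_ages) <= 0):
        raise ParameterError("visit ages must be strictly increasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ori = np.zeros_like(visit_ages)
    post = visit_ages > tau
    if post.any():
        epochs = np.concatenate([[tau], visit_ages[post]])
        dt = np.diff(epochs)
        incr = params.mu * dt + params.sigma * np.sqrt(dt) * rng.standard_normal(dt.size)
        ori[post] = np.cumsum(incr)
    if clamp_negative:
        ori = np.maximum(ori, 0.0)
    return ori


def _visit_schedule(design: SimulationDesign, rng: np.random.Generator) -> np.ndarray:
    """Aperiodic visit ages: uniform gaps inside the window, >= 3 visits."""
    lo, hi = design.visit_interval_range
    for _ in range(1000):
        ages = [design.study_start_age + rng.uniform(0.0, lo)]
        while True:
            nxt = ages[-1] + rng.uniform(lo, hi)
            if nxt > design.study_end_age:
                break
            ages.append(nxt)
        if len(ages) >= 3:
            return np.array(ages)
    raise DesignError("could not fit 3 visits inside the observation window")


def simulate_cohort(
    design: SimulationDesign,
) -> tuple[list[VertebraSeries], pd.DataFrame]:
    """Generate one cohort plus the hidden truth table of formation ages.

    Returns ``(series_list, truth)`` where ``truth`` has columns
    ``vertebra_id`` and ``true_tau``.  Identical designs (including seed)
    yield identical cohorts.
    """
    rng = np.random.default_rng(design.seed)
    taus = simulate_formation_times(design.n_vertebrae, design.params.weibull, rng)
    series: list[VertebraSeries] = []
    rows = []
    for i, tau in enumerate(taus):
        vid = f"V{i:05d}"
        ages = _visit_schedule(design, rng)
        ori = simulate_growth_path(
            tau,
            design.params.wiener,
            ages,
            rng,
            clamp_negative=False,
        )
        if design.measurement_noise_sd > 0:
            noise = design.measurement_noise_sd * rng.standard_normal(ages.size)
            ori = np.where(ages > tau, ori + noise, ori)
        if design.clamp_negative:
            ori = np.maximum(ori, 0.0)
        recs = [
            VisitRecord(subject_id=vid, vertebra_id=vid, age=float(a), ori=float(x))
            for a, x in zip(ages, ori)
        ]
        series.append(VertebraSeries(recs, allow_negative=not design.clamp_negative))
        rows.append((vid, float(tau)))
    truth = pd.DataFrame(rows, columns=["vertebra_id", "true_tau"])
    return series, truth
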