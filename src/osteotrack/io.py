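"""Core domain types, the cohort-table file dialect, and configuration.

A *cohort file* is a UTF-8 CSV with a header row and one radiographic visit
per row::

    subject_id,vertebra_id,age,ori
    P01,C3,50.12,0.0
    P01,C3,52.40,0.02

``age`` is the decimal age in years at the visit (callers pre-convert dates;
no date arithmetic is performed, which also keeps visit dates out of the
data). ``ori`` is the osteophyte ratio index — osteophyte length divided by
vertebral body width on the same lateral radiograph — so it is dimensionless
and independent of the radiographic scale plate.

A vertebra whose every visit records ORI 0 has not developed an osteophyte
by its last follow-up and is *right-censored* for the formation-time model.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import CohortFormatError, ParameterError, SeriesValidationError

__all__ = [
    "VisitRecord",
    "VertebraSeries",
    "WeibullParams",
    "WienerParams",
    "ModelParams",
    "PainThreshold",
    "SurvivalCurve",
    "CERVICAL_PARAMS",
    "LUMBAR_PARAMS",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "load_config",
    "get_logger",
]

COHORT_COLUMNS = ("subject_id", "vertebra_id", "age", "ori")

logger = logging.getLogger("osteotrack")


def get_logger(logfile: Optional[str] = None) -> logging.Logger:
    """Package logger: stderr always, plus an optional file sink."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    if logfile is not None:
        logger.addHandler(logging.FileHandler(logfile))
    return logger


@dataclass(frozen=True)
class VisitRecord:
    """One radiographic observation of one vertebra."""

    subject_id: str
    vertebra_id: str
    age: float  # years since birth
    ori: float  # dimensionless osteophyte ratio index

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise SeriesValidationError(
                f"age must be positive, got {self.age} "
                f"({self.subject_id}/{self.vertebra_id})"
            )


@dataclass
class VertebraSeries:
    """Time-ordered follow-up series for one vertebra.

    ``censored`` is True iff every visit records ORI 0 (no osteophyte by the
    last visit); then ``censor_age`` holds the last-visit age and ``tau_hat``
    is absent.  ``allow_negative`` relaxes the ORI >= 0 check for synthetic
    cohorts generated without clamping, where an unreflected Wiener path may
    dip below zero shortly after formation.
    """

    records: list[VisitRecord]
    tau_hat: Optional[float] = None
    allow_negative: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise SeriesValidationError("a series needs at least one record")
        ages = [r.age for r in self.records]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise SeriesValidationError(
                f"ages not strictly increasing in series {self.key}: {ages}"
            )
        if not self.allow_negative and any(r.ori < 0 for r in self.records):
            raise SeriesValidationError(f"negative ORI in series {self.key}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.records[0].subject_id, self.records[0].vertebra_id)

    @property
    def ages(self) -> np.ndarray:
        return np.array([r.age for r in self.records])

    @property
    def oris(self) -> np.ndarray:
        return np.array([r.ori for r in self.records])

    @property
    def censored(self) -> bool:
        return all(r.ori == 0 for r in self.records)

    @property
    def censor_age(self) -> Optional[float]:
        return self.records[-1].age if self.censored else None

    @property
    def positive_records(self) -> list[VisitRecord]:
        return [r for r in self.records if r.ori > 0]

    @property
    def usable_for_interpolation(self) -> bool:
        """Two distinct positive-ORI ages are needed to draw the line."""
        pos = self.positive_records
        return len(pos) >= 2 and pos[-1].age > pos[0].age

    def with_tau(self, tau_hat: float) -> "VertebraSeries":
        return replace(self, tau_hat=tau_hat)


@dataclass(frozen=True)
class WeibullParams:
    """Scale ``a`` (years) and shape ``b`` of the formation-age distribution."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ParameterError(f"Weibull scale and shape must be > 0, got {self}")

    @property
    def mean(self) -> float:
        """a * Gamma(1 + 1/b), the mean formation age in years."""
        return self.a * math.gamma(1.0 + 1.0 / self.b)


@dataclass(frozen=True)
class WienerParams:
    """Drift ``mu`` (ORI/year) and diffusion ``sigma`` (ORI/sqrt-year)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.mu > 0 and self.sigma > 0):
            raise ParameterError(f"drift and diffusion must be > 0, got {self}")


@dataclass(frozen=True)
class ModelParams:
    """Full model: formation-time law plus post-formation growth law."""

    weibull: WeibullParams
    wiener: WienerParams


@dataclass(frozen=True)
class PainThreshold:
    """Maximum clinically acceptable ORI, in (0, 1]."""

    c: float

    def __post_init__(self) -> None:
        if not (0 < self.c <= 1):
            raise ParameterError(f"pain threshold must be in (0, 1], got {self.c}")


# Published population-level estimates (Wiener drift/diffusion and Weibull
# formation-age parameters) for the two spinal regions.
CERVICAL_PARAMS = ModelParams(
    WeibullParams(a=52.5216, b=5.7469), WienerParams(mu=0.0145553, sigma=0.0113259)
)
LUMBAR_PARAMS = ModelParams(
    WeibullParams(a=54.9779, b=2.3443), WienerParams(mu=0.012836, sigma=0.024040)
)


@dataclass
class SurvivalCurve:
    """Tabulated survival function with an optional confidence band."""

    times: np.ndarray
    survival: np.ndarray
    ci_lower: Optional[np.ndarray] = None
    ci_upper: Optional[np.ndarray] = None
    kind: str = "model"  # "model" | "kaplan_meier"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.shape != self.survival.shape:
            raise SeriesValidationError("times and survival must align")
        if np.any(np.diff(self.times) < 0):
            raise SeriesValidationError("times must be non-decreasing")
        if np.any(self.survival > 1 + 1e-12) or np.any(self.survival < -1e-12):
            raise SeriesValidationError("survival values must lie in [0, 1]")
        if np.any(np.diff(self.survival) > 1e-12):
            raise SeriesValidationError("survival must be non-increasing")

    def at(self, t: float) -> float:
        """Right-continuous step lookup (previous value carried forward)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


def read_cohort(path: str | Path, *, delimiter: str = ",") -> list[VertebraSeries]:
    """Read a cohort CSV into validated, age-sorted vertebra series.

    Rows are grouped by (subject_id, vertebra_id) and sorted by age within
    each group; exact duplicate (vertebra, age) rows are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise CohortFormatError(f"cohort file not found: {path}")
    frame = pd.read_csv(path, sep=delimiter, dtype={"subject_id": str, "vertebra_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortFormatError(f"cohort file {path} missing column(s): {missing}")
    if frame["ori"].isna().any() or frame["age"].isna().any():
        raise CohortFormatError(f"cohort file {path} has unparseable age/ori values")
    if (frame["ori"] < 0).any():
        bad = frame.loc[frame["ori"] < 0].iloc[0]
        raise SeriesValidationError(
            f"negative ORI for {bad['subject_id']}/{bad['vertebra_id']} at age {bad['age']}"
        )
    series: list[VertebraSeries] = []
    for (sid, vid), grp in frame.groupby(["subject_id", "vertebra_id"], sort=True):
        if grp["age"].duplicated().any():
            raise SeriesValidationError(f"duplicate visit age in series {sid}/{vid}")
        grp = grp.sort_values("age")
        recs = [
            VisitRecord(str(sid), str(vid), float(r.age), float(r.ori))
            for r in grp.itertuples()
        ]
        series.append(VertebraSeries(recs))
    n_cens = sum(s.censored for s in series)
    logger.info(
        "read %d series (%d censored) from %s", len(series), n_cens, path
    )
    return series


def cohort_to_frame(cohort: Iterable[VertebraSeries]) -> pd.DataFrame:
    rows = [
        (r.subject_id, r.vertebra_id, r.age, r.ori)
        for s in cohort
        for r in s.records
    ]
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def write_cohort(cohort: Sequence[VertebraSeries], path: str | Path) -> Path:
    """Write series back to the CSV dialect; inverse of :func:`read_cohort`."""
    path = Path(path)
    cohort_to_frame(cohort).to_csv(path, index=False, float_format="%.12g")
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML config of model parameters / thresholds / design settings."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise CohortFormatError(f"config {path} must be a mapping")
    return cfg
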