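"""Observer-agreement statistics for paired ORI measurements.

Reliability of the osteophyte ratio index between observers (or between two
rounds of the same observer) is summarised by the intraclass correlation
coefficient — two-way random effects, absolute agreement, single
measurement (ICC(2,1)) — with an F-based 95% CI, plus the mean percentage
difference |a - b| / |a| * 100 across items.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg

from .exceptions import InsufficientDataError, ParameterError
from .io import logger

__all__ = ["PairedMeasurements", "AgreementResult", "icc", "percentage_difference", "icc_band"]

ICC_BANDS = ((0.50, "poor"), (0.75, "moderate"), (0.90, "good"), (float("inf"), "excellent"))


def icc_band(value: float) -> str:
    """Qualitative reliability band: <=0.50 poor, <=0.75 moderate,
    <=0.90 good, above that excellent."""
    for cut, label in ICC_BANDS:
        if value <= cut:
            return label
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class PairedMeasurements:
    """Two equal-length measurement vectors on the same items."""

    values_a: np.ndarray
    values_b: np.ndarray
    item_ids: Optional[Sequence] = None

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)
        if a.shape != b.shape or a.ndim != 1:
            raise ParameterError("values_a and values_b must be equal-length vectors")
        if a.size < 3:
            raise InsufficientDataError("at least 3 paired items required")
        if np.isnan(a).any() or np.isnan(b).any():
            raise ParameterError("missing entries are not allowed after pairing")

    @property
    def n(self) -> int:
        return int(self.values_a.size)


@dataclass(frozen=True)
class AgreementResult:
    """ICC point estimate, 95% CI, qualitative band, and mean PD."""

    icc: float
    ci_lower: float
    ci_upper: float
    band: str
    pd_mean: float
    n_items: int


def icc(pairs: PairedMeasurements, *, consistency: bool = False) -> AgreementResult:
    """ICC with 95% CI for a pair of measurement vectors.

    Default form is two-way random, absolute agreement, single measurement
    (ICC(2,1)); ``consistency`` switches to the two-way mixed consistency
    form (ICC(3,1)).
    """
    n = pairs.n
    long = pd.DataFrame(
        {
            "item": np.tile(np.arange(n), 2),
            "rater": np.repeat(["a", "b"], n),
            "value": np.concatenate([pairs.values_a, pairs.values_b]),
        }
    )
    if np.var(long["value"]) == 0:
        raise ParameterError("zero total variance; ICC undefined")
    table = pg.intraclass_corr(
        data=long, targets="item", raters="rater", ratings="value"
    ).set_index("Type")
    wanted = ("ICC3", "ICC(C,1)") if consistency else ("ICC2", "ICC(A,1)")
    label = next(lbl for lbl in wanted if lbl in table.index)
    row = table.loc[label]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    est = float(row["ICC"])
    lo, hi = (float(v) for v in row[ci_col])
    result = AgreementResult(
        icc=est,
        ci_lower=lo,
        ci_upper=hi,
        band=icc_band(est),
        pd_mean=percentage_difference(pairs),
        n_items=n,
    )
    logger.info("ICC=%.4f [%.4f, %.4f] (%s), mean PD=%.2f%%",
                est, lo, hi, result.band, result.pd_mean)
    return result


def percentage_difference(pairs: PairedMeasurements, summary: str = "mean") -> float:
    """Mean (or median) of the per-item |a - b| / |a| * 100.

    The first-listed vector is the baseline.  Items whose baseline is 0 are
    excluded (the formula divides by the baseline); their count is logged.
    """
    a, b = pairs.values_a, pairs.values_b
    keep = a != 0
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("percentage difference: excluded %d zero-baseline items", n_dropped)
    if not keep.any():
        raise ParameterError("all baseline values are zero; PD undefined")
    pd_items = np.abs(a[keep] - b[keep]) / np.abs(a[keep]) * 100.0
    if summary == "mean":
        return float(np.mean(pd_items))
    if summary == "median":
        return float(np.median(pd_items))
    raise ParameterError(f"unknown summary {summary!r}")
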