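"""End-to-end cohort fitting: interpolation -> Weibull MLE -> Wiener MLE."""

from __future__ import annotations

from dataclasses import dataclass

from .formation import FormationData, WeibullFormationMLE, formation_data_from_cohort
from .growth import IncrementData, WienerGrowthMLE, extract_increments
from .io import ModelParams, VertebraSeries, VisitRecord

__all__ = ["CohortFit", "fit_cohort"]


@dataclass
class CohortFit:
    """Everything estimated from one cohort, plus the held-out observations."""

    params: ModelParams
    formation: WeibullFormationMLE
    growth: WienerGrowthMLE
    formation_data: FormationData
    increment_data: IncrementData
    cohort_with_tau: list[VertebraSeries]
    held_out: list[VisitRecord]

    @property
    def tau_by_series(self) -> dict:
        return {
            s.key: s.tau_hat for s in self.cohort_with_tau if s.tau_hat is not None
        }


def fit_cohort(
    cohort: list[VertebraSeries],
    censor_time: float | None = None,
    *,
    anchor_at_formation: bool = True,
    unbiased_sigma: bool = False,
) -> CohortFit:
    """Fit the full formation-and-growth model to a longitudinal cohort.

    ``censor_time`` (elapsed years since each series' estimated formation
    age) splits growth observations into a fitting set and a held-out
    validation set; ``None`` uses all post-formation data.
    """
    fdata, cohort_tau = formation_data_from_cohort(cohort)
    wfit = WeibullFormationMLE().fit(fdata)
    inc, held_out = extract_increments(
        cohort_tau, censor_time, anchor_at_formation=anchor_at_formation
    )
    gfit = WienerGrowthMLE(unbiased=unbiased_sigma).fit(inc)
    return CohortFit(
        params=ModelParams(weibull=wfit.params_, wiener=gfit.params_),
        formation=wfit,
        growth=gfit,
        formation_data=fdata,
        increment_data=inc,
        cohort_with_tau=cohort_tau,
        held_out=held_out,
    )
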