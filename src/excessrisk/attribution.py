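"""Attributable fractions and excess-cancer accounting for flagged rate ratios.

For each flagged (cancer type, exposure) pair the attributable fraction in the
exposed is (RR - 1)/RR; multiplied by the number of observed events among
exposed women it gives the excess count (negative for protective associations).
Totals are reported per scenario: only associations consistent with randomised
trials, or all flagged associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, DataError
from .regression import RateRatioEstimate

#: default trial-consistency map: (exposure, cancer type) -> supported by trials
DEFAULT_TRIAL_CONSISTENCY = {
    ("radiotherapy", "breast"): True,
    ("radiotherapy", "contralateral_breast"): True,
    ("radiotherapy", "lung"): True,
    ("endocrine", "uterus"): True,
    ("endocrine", "breast"): True,
    ("endocrine", "contralateral_breast"): True,
    ("chemotherapy", "leukaemia"): True,
}


def attributable_fraction(rr: float) -> float:
    """(RR - 1) / RR; negative when the exposure is protective."""
    if not (rr > 0):
        raise ConfigurationError(f"rate ratio must be > 0, got {rr}")
    return (rr - 1.0) / rr


def population_excess(o_total: float, e_total: float) -> float:
    """Cohort-level excess over the general population: O - E."""
    if o_total < 0 or e_total < 0:
        raise ConfigurationError("totals must be non-negative")
    return o_total - e_total


@dataclass
class AttributionResult:
    per_pair: pd.DataFrame           # exposure, cancer_type, rr, af, exposed, excess, ...
    total_trial_consistent: float
    total_all_flagged: float
    total_second_cancers: float | None = None
    total_population_excess: float | None = None

    def proportions(self, scenario: str = "trial_consistent") -> dict[str, float]:
        total = {"trial_consistent": self.total_trial_consistent,
                 "all_flagged": self.total_all_flagged}[scenario]
        out = {}
        if self.total_second_cancers:
            out["of_all_second_cancers"] = total / self.total_second_cancers
        if self.total_population_excess:
            out["of_population_excess"] = total / self.total_population_excess
        return out


def excess_counts(estimates: list[RateRatioEstimate],
                  exposed_counts: dict[tuple[str, str], float],
                  trial_consistency: dict[tuple[str, str], bool] | None = None,
                  total_second_cancers: float | None = None,
                  total_population_excess: float | None = None) -> AttributionResult:
    """Excess counts per flagged estimate plus scenario sums.

    ``exposed_counts`` maps (exposure, cancer type) to the observed number of
    target events among exposed women; every flagged estimate must be covered.
    """
    consistency = DEFAULT_TRIAL_CONSISTENCY if trial_consistency is None \
        else trial_consistency
    rows = []
    tot_tc = 0.0
    tot_all = 0.0
    for est in estimates:
        if not est.flagged:
            continue
        key = (est.exposure, est.cancer_type)
        if key not in exposed_counts:
            raise DataError(
                f"no exposed event count supplied for flagged pair {key}")
        af = attributable_fraction(est.rr)
        excess = af * exposed_counts[key]
        consistent = bool(consistency.get(key, False))
        rows.append({"exposure": est.exposure, "cancer_type": est.cancer_type,
                     "period": est.period, "rr": est.rr, "af": af,
                     "exposed_events": exposed_counts[key], "excess": excess,
                     "trial_consistent": consistent})
        tot_all += excess
        if consistent:
            tot_tc += excess
    per_pair = pd.DataFrame(rows, columns=["exposure", "cancer_type", "period",
                                           "rr", "af", "exposed_events",
                                           "excess", "trial_consistent"])
    return AttributionResult(per_pair=per_pair,
                             total_trial_consistent=tot_tc,
                             total_all_flagged=tot_all,
                             total_second_cancers=total_second_cancers,
                             total_population_excess=total_population_excess)
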