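"""QUANTEC parotid guideline checks and predictive-value computation.

The QUANTEC guideline for limiting severe xerostomia: at least one
parotid gland receives a mean dose of <= 20 Gy, or both glands receive
<= 25 Gy.  Validation classifies each analysis unit by a dose cutoff
(dose <= cutoff predicts no xerostomia) and summarizes the resulting
2x2 confusion counts as sensitivity, specificity, prevalence, PPV and
NPV, where

    PPV = sens * prev / [sens * prev + (1 - spec)(1 - prev)]
    NPV = spec * (1 - prev) / [(1 - sens) * prev + spec * (1 - prev)].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "meets_quantec", "classify_by_cutoff",
           "ppv", "npv", "predictive_values_at_cutoffs", "DEFAULT_CUTOFFS"]

#: Cutoff panel: the two QUANTEC doses plus the SEF- and QoL-fitted TD50s.
DEFAULT_CUTOFFS = (20.0, 25.0, 43.6, 44.1)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 classification counts at a dose cutoff."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("at least one observation required")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else math.nan

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else math.nan

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.total

    @property
    def ppv(self) -> float:
        """Count-based PPV tp/(tp+fp); NaN when nothing is predicted positive."""
        d = self.tp + self.fp
        return self.tp / d if d else math.nan

    @property
    def npv(self) -> float:
        """Count-based NPV tn/(tn+fn); NaN when nothing is predicted negative."""
        d = self.tn + self.fn
        return self.tn / d if d else math.nan


def meets_quantec(gland_doses) -> bool:
    """True iff the gland-dose pair satisfies the QUANTEC guideline:
    min dose <= 20 Gy or all doses <= 25 Gy."""
    doses = list(gland_doses)
    if not 1 <= len(doses) <= 2:
        raise ValueError("provide the mean doses of 1-2 parotid glands")
    return min(doses) <= 20.0 or max(doses) <= 25.0


def classify_by_cutoff(dose: float, cutoff: float) -> bool:
    """Predict xerostomia iff dose > cutoff (dose at or below the cutoff
    predicts the lack of xerostomia)."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if not cutoff > 0:
        raise ValueError("cutoff must be > 0")
    return dose > cutoff


def ppv(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Positive predictive value from sensitivity, specificity, prevalence."""
    _check_unit_interval(sensitivity, specificity, prevalence)
    num = sensitivity * prevalence
    denom = num + (1.0 - specificity) * (1.0 - prevalence)
    return num / denom if denom > 0 else math.nan


def npv(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Negative predictive value from sensitivity, specificity, prevalence."""
    _check_unit_interval(sensitivity, specificity, prevalence)
    num = specificity * (1.0 - prevalence)
    denom = (1.0 - sensitivity) * prevalence + num
    return num / denom if denom > 0 else math.nan


def _check_unit_interval(*values: float) -> None:
    for v in values:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"rates must lie in [0, 1], got {v}")


def confusion_at_cutoff(doses, events, cutoff: float) -> ConfusionCounts:
    """Confusion counts of the cutoff classifier against observed events."""
    doses = np.asarray(doses, dtype=float)
    events = np.asarray(events, dtype=bool)
    if doses.size == 0:
        raise ValueError("units must be non-empty")
    predicted = doses > cutoff
    return ConfusionCounts(
        tp=int(np.sum(predicted & events)),
        fp=int(np.sum(predicted & ~events)),
        tn=int(np.sum(~predicted & ~events)),
        fn=int(np.sum(~predicted & events)),
    )


def predictive_values_at_cutoffs(doses, events,
                                 cutoffs=DEFAULT_CUTOFFS) -> pd.DataFrame:
    """Tabulate confusion counts and PPV/NPV (percent) per dose cutoff.

    PPV/NPV are computed from the rate formulas; these agree exactly with
    the count ratios tp/(tp+fp) and tn/(tn+fn) whenever both are defined.
    Undefined values (no predicted positives/negatives) are reported NaN.
    """
    rows = []
    for cutoff in cutoffs:
        c = confusion_at_cutoff(doses, events, cutoff)
        sens, spec, prev = c.sensitivity, c.specificity, c.prevalence
        if math.isnan(sens) or math.isnan(spec):
            ppv_f = c.ppv  # fall back on count ratio when a rate is undefined
            npv_f = c.npv
        else:
            ppv_f = ppv(sens, spec, prev) if (c.tp + c.fp) else math.nan
            npv_f = npv(sens, spec, prev) if (c.tn + c.fn) else math.nan
        rows.append({"cutoff_gy": cutoff, "tp": c.tp, "fp": c.fp,
                     "tn": c.tn, "fn": c.fn,
                     "ppv_pct": 100.0 * ppv_f, "npv_pct": 100.0 * npv_f})
    return pd.DataFrame(rows)
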