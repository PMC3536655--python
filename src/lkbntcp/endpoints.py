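"""Xerostomia endpoints from salivary-flow and quality-of-life measures.

Parotid function is measured by scintigraphy as the salivary excretion
factor (SEF); the endpoint is the follow-up flow relative to baseline.
The LENT-SOMA salivary-flow bands grade the loss (grade 1: 76-95% of the
pre-treatment flow, grade 2: 51-75%, grade 3: 26-50%, grade 4: 0-25%).
Two binary event definitions are exposed:

* ``sef_event`` - flow ratio <= 45% of baseline (the primary endpoint,
  reported as equivalent to grade 3+);
* the LENT-SOMA grade-3+ predicate via ``lentsoma_grade`` (ratio <= 50%).

The two differ on ratios in (0.45, 0.50]; both are kept rather than
reconciled.  Patient-reported xerostomia from the QLQ-H&N35 single item
is binarized at "quite a bit" (score >= 3 of 4) by ``qol_event``.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FlowMeasurement", "XerostomiaGrade", "flow_ratio",
           "lentsoma_grade", "sef_event", "qol_event"]

#: Primary-endpoint threshold on the follow-up/baseline flow ratio.
SEF_EVENT_THRESHOLD = 0.45

#: Upper ratio bounds of LENT-SOMA grades 4, 3, 2, 1 (grade 0 above).
_GRADE_BOUNDS = ((0.25, 4), (0.50, 3), (0.75, 2), (0.95, 1))


@dataclass(frozen=True)
class FlowMeasurement:
    """Baseline and follow-up salivary excretion factors (percent)."""

    baseline_sef: float
    followup_sef: float

    def __post_init__(self) -> None:
        if not self.baseline_sef > 0:
            raise ValueError("baseline SEF must be > 0")
        if self.followup_sef < 0:
            raise ValueError("follow-up SEF must be >= 0")

    @property
    def ratio(self) -> float:
        return flow_ratio(self.baseline_sef, self.followup_sef)


@dataclass(frozen=True)
class XerostomiaGrade:
    grade: int

    @property
    def grade3plus(self) -> bool:
        return self.grade >= 3


def flow_ratio(baseline: float, followup: float) -> float:
    """Follow-up flow as a fraction of the pre-treatment value."""
    if not baseline > 0:
        raise ValueError(f"baseline SEF must be > 0, got {baseline}")
    if followup < 0:
        raise ValueError(f"follow-up SEF must be >= 0, got {followup}")
    return followup / baseline


def lentsoma_grade(ratio: float) -> XerostomiaGrade:
    """LENT-SOMA salivary-flow grade for a follow-up/baseline ratio.

    Boundary ratios are assigned to the more severe grade (each band is
    ``ratio <= upper bound``), so 0.25 is grade 4 and 0.50 grade 3.
    """
    if ratio < 0:
        raise ValueError(f"flow ratio must be >= 0, got {ratio}")
    for bound, grade in _GRADE_BOUNDS:
        if ratio <= bound:
            return XerostomiaGrade(grade)
    return XerostomiaGrade(0)


def sef_event(ratio: float) -> bool:
    """Primary scintigraphy endpoint: flow <= 45% of baseline (inclusive)."""
    if ratio < 0:
        raise ValueError(f"flow ratio must be >= 0, got {ratio}")
    return ratio <= SEF_EVENT_THRESHOLD


def qol_event(xerostomia_item_score: int) -> bool:
    """Moderate-to-severe patient-reported xerostomia.

    The single QLQ-H&N35 dry-mouth item is scored 1-4 (not at all /
    a little / quite a bit / very much); the event is score >= 3.
    """
    score = xerostomia_item_score
    if score not in (1, 2, 3, 4):
        raise ValueError(f"QoL item score must be in 1..4, got {score}")
    return score >= 3
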