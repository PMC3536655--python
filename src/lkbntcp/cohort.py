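"""Cohort data model and delimited-text I/O.

A cohort is a set of patients, each contributing up to two parotid
glands.  Every gland row carries its mean dose and, optionally, baseline
and follow-up salivary excretion factors; the patient additionally
carries a single QoL xerostomia item score.  The *spared* gland is the
one with the lower mean dose - the dose axis used for per-patient
analyses and the QUANTEC guideline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .endpoints import FlowMeasurement, qol_event, sef_event

__all__ = ["GlandObservation", "PatientRecord", "CohortSchemaError",
           "read_cohort", "write_cohort", "analysis_units"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("patient_id", "laterality", "mean_dose_gy")
OPTIONAL_COLUMNS = ("baseline_sef", "followup_sef", "qol_score", "event")

_LATERALITY_ALIASES = {
    "ipsilateral": "ipsilateral", "ipsi": "ipsilateral",
    "contralateral": "contralateral", "contra": "contralateral",
}


class CohortSchemaError(ValueError):
    """Raised for cohort tables violating the expected schema."""


@dataclass(frozen=True)
class GlandObservation:
    """One gland's dose metric and endpoint measurements."""

    patient_id: str
    laterality: str  # ipsilateral | contralateral
    mean_dose: float  # Gy
    flow: FlowMeasurement | None = None
    event: bool | None = None  # supplied flag; derived from flow if absent

    def __post_init__(self) -> None:
        if self.laterality not in ("ipsilateral", "contralateral"):
            raise CohortSchemaError(
                f"laterality must be ipsilateral|contralateral, "
                f"got {self.laterality!r}")
        if not self.mean_dose >= 0 or not math.isfinite(self.mean_dose):
            raise CohortSchemaError(
                f"mean dose must be finite and >= 0 Gy, got {self.mean_dose}")

    @property
    def sef_event(self) -> bool | None:
        """Binary SEF endpoint: derived from flow when measured, else the
        supplied event flag, else None."""
        if self.flow is not None:
            return sef_event(self.flow.ratio)
        return self.event


@dataclass(frozen=True)
class PatientRecord:
    """A patient's gland pair plus the patient-level QoL item score."""

    patient_id: str
    glands: tuple[GlandObservation, ...]
    qol_score: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.glands) <= 2:
            raise CohortSchemaError(
                f"patient {self.patient_id}: needs 1-2 glands, "
                f"got {len(self.glands)}")
        sides = [g.laterality for g in self.glands]
        if len(set(sides)) != len(sides):
            raise CohortSchemaError(
                f"patient {self.patient_id}: duplicate laterality")
        if self.qol_score is not None and self.qol_score not in (1, 2, 3, 4):
            raise CohortSchemaError(
                f"patient {self.patient_id}: QoL score must be 1-4")

    @property
    def spared_dose(self) -> float:
        """Mean dose (Gy) to the lower-dose (spared) gland."""
        return min(g.mean_dose for g in self.glands)

    @property
    def spared_gland(self) -> GlandObservation:
        return min(self.glands, key=lambda g: g.mean_dose)

    @property
    def qol_event(self) -> bool | None:
        return None if self.qol_score is None else qol_event(self.qol_score)


def read_cohort(path) -> list[PatientRecord]:
    """Read a delimited cohort table into validated patient records.

    Requires columns patient_id, laterality, mean_dose_gy; optional
    baseline_sef, followup_sef, qol_score, event.  SEF events are derived
    from the flow measurements where present.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required columns: {missing}")
    records: list[PatientRecord] = []
    n_missing_flow = 0
    for pid, group in df.groupby("patient_id", sort=False):
        glands = []
        qol: int | None = None
        for _, row in group.iterrows():
            lat = _LATERALITY_ALIASES.get(str(row["laterality"]).lower())
            if lat is None:
                raise CohortSchemaError(
                    f"unknown laterality {row['laterality']!r}")
            flow = None
            if ("baseline_sef" in df.columns and "followup_sef" in df.columns
                    and pd.notna(row["baseline_sef"])
                    and pd.notna(row["followup_sef"])):
                flow = FlowMeasurement(float(row["baseline_sef"]),
                                       float(row["followup_sef"]))
            else:
                n_missing_flow += 1
            event = None
            if "event" in df.columns and pd.notna(row["event"]):
                event = bool(int(row["event"]))
            glands.append(GlandObservation(str(pid), lat,
                                           float(row["mean_dose_gy"]),
                                           flow=flow, event=event))
            if "qol_score" in df.columns and pd.notna(row["qol_score"]):
                qol = int(row["qol_score"])
        records.append(PatientRecord(str(pid), tuple(glands), qol_score=qol))
    if n_missing_flow:
        logger.info("%d gland rows lack flow measurements (excluded from "
                    "SEF-endpoint fitting)", n_missing_flow)
    return records


def write_cohort(records: list[PatientRecord], path) -> None:
    """Write records as a CSV (one row per gland) that round-trips exactly."""
    rows = []
    for rec in records:
        for g in rec.glands:
            rows.append({
                "patient_id": rec.patient_id,
                "laterality": g.laterality,
                "mean_dose_gy": g.mean_dose,
                "baseline_sef": g.flow.baseline_sef if g.flow else np.nan,
                "followup_sef": g.flow.followup_sef if g.flow else np.nan,
                "qol_score": rec.qol_score if rec.qol_score is not None
                             else np.nan,
                "event": int(g.event) if g.event is not None else np.nan,
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def analysis_units(records: list[PatientRecord], endpoint_source: str = "sef",
                   unit: str = "per_gland") -> tuple[np.ndarray, np.ndarray]:
    """Flatten a cohort into the (dose Gy, event) pairs used for fitting.

    ``per_gland`` emits one pair per gland (the SEF default, 2 per
    patient); ``per_patient_spared`` emits one pair per patient at the
    spared-gland dose (the QoL default).  Glands or patients without the
    requested endpoint are dropped with a logged count.
    """
    if endpoint_source not in ("sef", "qol"):
        raise ValueError(f"endpoint_source must be sef|qol, "
                         f"got {endpoint_source!r}")
    if unit not in ("per_gland", "per_patient_spared"):
        raise ValueError(f"unit must be per_gland|per_patient_spared, "
                         f"got {unit!r}")
    doses: list[float] = []
    events: list[bool] = []
    dropped = 0
    for rec in records:
        if unit == "per_patient_spared":
            ev = (rec.spared_gland.sef_event if endpoint_source == "sef"
                  else rec.qol_event)
            if ev is None:
                dropped += 1
                continue
            doses.append(rec.spared_dose)
            events.append(ev)
        else:
            for g in rec.glands:
                ev = g.sef_event if endpoint_source == "sef" else rec.qol_event
                if ev is None:
                    dropped += 1
                    continue
                doses.append(g.mean_dose)
                events.append(ev)
    if dropped:
        logger.info("dropped %d units lacking the %s endpoint",
                    dropped, endpoint_source)
    if not doses and dropped:
        raise ValueError(
            f"no units carry the {endpoint_source!r} endpoint")
    return np.asarray(doses, dtype=float), np.asarray(events, dtype=bool)
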