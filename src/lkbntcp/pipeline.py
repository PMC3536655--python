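"""End-to-end orchestration: simulate/load -> endpoints -> fit -> evaluate
-> QUANTEC validation, with a consolidated, reproducible report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import PatientRecord, analysis_units, read_cohort
from .fitting import FitResult, fit_lkb
from .lkb import ntcp_curve
from .metrics import PerformanceReport, pearson_chi2_2x2, performance_report
from .quantec import DEFAULT_CUTOFFS, predictive_values_at_cutoffs
from .simulate import CohortConfig, simulate_cohort

__all__ = ["RunReport", "run_pipeline"]

logger = logging.getLogger(__name__)

#: Default analysis unit per endpoint: the scintigraphy endpoint is
#: evaluated per gland, the patient-reported endpoint per patient at the
#: spared-gland dose.
DEFAULT_UNITS = {"sef": "per_gland", "qol": "per_patient_spared"}


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunReport:
    """All pipeline outputs: per-endpoint fits, performance, predictive
    values, endpoint agreement, and full provenance."""

    fits: dict[str, FitResult]
    performance: dict[str, PerformanceReport]
    predictive: dict[str, pd.DataFrame]
    endpoint_agreement: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        out: dict = {"fits": {}, "performance": {}, "predictive": {},
                     "endpoint_agreement": self.endpoint_agreement,
                     "provenance": self.provenance}
        for name, fit in self.fits.items():
            out["fits"][name] = {
                "n": fit.params.n, "m": fit.params.m, "td50": fit.params.td50,
                "ci": {k: list(v) for k, v in fit.ci.items()},
                "loglik": fit.loglik, "loglik_null": fit.loglik_null,
                "n_obs": fit.n_obs, "converged": fit.converged,
            }
        for name, perf in self.performance.items():
            out["performance"][name] = dataclasses.asdict(perf)
        for name, table in self.predictive.items():
            out["predictive"][name] = table.to_dict(orient="records")
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, allow_nan=True, **kwargs)


def _config_hash(config: CohortConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _endpoint_agreement(records: list[PatientRecord]) -> dict | None:
    """2x2 association between the per-patient SEF (spared-gland) and QoL
    endpoints, where both are available."""
    pairs = [(r.spared_gland.sef_event, r.qol_event) for r in records
             if r.spared_gland.sef_event is not None
             and r.qol_event is not None]
    if not pairs:
        return None
    sef = np.array([p[0] for p in pairs])
    qol = np.array([p[1] for p in pairs])
    table = [[int(np.sum(sef & qol)), int(np.sum(sef & ~qol))],
             [int(np.sum(~sef & qol)), int(np.sum(~sef & ~qol))]]
    try:
        chi2, p = pearson_chi2_2x2(table)
    except ValueError as exc:
        return {"table": table, "chi2": None, "p": None, "note": str(exc)}
    return {"table": table, "chi2": chi2, "p": p}


def run_pipeline(config: CohortConfig | dict | None = None,
                 cohort_path=None, seed: int | None = None,
                 endpoints: tuple[str, ...] = ("sef", "qol"),
                 cutoffs=DEFAULT_CUTOFFS, hl_groups: int = 10,
                 out_dir=None) -> RunReport:
    """Run all stages and return (and optionally write) the report.

    Provide either a simulation ``config`` (dict or CohortConfig) or a
    ``cohort_path`` to a cohort table.  ``seed`` overrides the config
    seed.  With ``out_dir`` set, the JSON report, the cohort table and
    per-endpoint NTCP-curve tables are written there.
    """
    for ep in endpoints:
        if ep not in DEFAULT_UNITS:
            raise PipelineError("config", f"unknown endpoint {ep!r}")
    if (config is None) == (cohort_path is None):
        raise PipelineError(
            "config", "provide exactly one of config or cohort_path")

    if cohort_path is not None:
        records = read_cohort(cohort_path)
        source = {"cohort_path": str(cohort_path)}
        logger.info("read %d patients (%d glands) from %s", len(records),
                    sum(len(r.glands) for r in records), cohort_path)
    else:
        if isinstance(config, dict):
            config = CohortConfig.from_dict(config)
        if seed is not None:
            config = config.with_seed(seed)
        records = simulate_cohort(config)
        source = {"config": config.to_dict(),
                  "config_hash": _config_hash(config)}
        logger.info("simulated %d patients (%d glands), seed %d",
                    len(records), sum(len(r.glands) for r in records),
                    config.seed)

    fits: dict[str, FitResult] = {}
    performance: dict[str, PerformanceReport] = {}
    predictive: dict[str, pd.DataFrame] = {}
    for ep in endpoints:
        unit = DEFAULT_UNITS[ep]
        try:
            doses, events = analysis_units(records, endpoint_source=ep,
                                           unit=unit)
        except ValueError as exc:
            raise PipelineError("endpoints", str(exc)) from exc
        logger.info("%s endpoint: %d units, %d events", ep, doses.size,
                    int(events.sum()))
        try:
            fit = fit_lkb(doses, events)
        except ValueError as exc:
            raise PipelineError("fit", f"{ep}: {exc}") from exc
        fits[ep] = fit
        groups = hl_groups
        if doses.size < 2 * groups:
            groups = max(3, doses.size // 2)
            logger.warning("%s: reducing Hosmer-Lemeshow groups to %d "
                           "(n=%d)", ep, groups, doses.size)
        try:
            performance[ep] = performance_report(fit, doses, events,
                                                 groups=groups)
        except ValueError as exc:
            raise PipelineError("evaluate", f"{ep}: {exc}") from exc
        predictive[ep] = predictive_values_at_cutoffs(doses, events,
                                                      cutoffs=cutoffs)

    report = RunReport(
        fits=fits, performance=performance, predictive=predictive,
        endpoint_agreement=_endpoint_agreement(records),
        provenance={
            **source,
            "seed": seed if seed is not None else
                    (config.seed if config is not None else None),
            "endpoints": list(endpoints),
            "analysis_units": DEFAULT_UNITS,
            "cutoffs_gy": list(cutoffs),
            "package_version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(report.to_json())
        from .cohort import write_cohort
        write_cohort(records, out_dir / "cohort.csv")
        for ep in endpoints:
            curve = ntcp_curve(fits[ep].params)
            pd.DataFrame(curve, columns=["dose_gy", "ntcp"]).to_csv(
                out_dir / f"ntcp_curve_{ep}.csv", index=False)
    return report
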