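"""Synthetic cohorts with the statistical structure of a parotid-sparing
head-and-neck radiotherapy study.

Each simulated patient has an ipsilateral and a contralateral parotid
gland.  Mean doses are drawn from truncated normals matching the study
cohort (ipsilateral mean 51.7 Gy on 26.9-74.8; contralateral 36.7 Gy on
7.6-57.6); baseline salivary excretion factors from Normal(48.1%, 18.2%)
truncated to the observed 19.2-72.8% range.  Per-gland grade-3+ events
are Bernoulli draws from the LKB dose-response at the gland's mean dose;
the follow-up SEF is then drawn conditionally so that the flow-ratio
endpoint (<= 45% of baseline) reproduces the event flag exactly.
Patient-level QoL events are Bernoulli draws from a second LKB curve
evaluated at the spared-gland dose, mapped to a 1-4 item score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr
from scipy.stats import truncnorm

from .cohort import GlandObservation, PatientRecord
from .dvh import DVHCurve
from .endpoints import FlowMeasurement
from .lkb import LKBParameters, ntcp

__all__ = ["TruncatedNormalSpec", "CohortConfig", "simulate_cohort",
           "simulate_dvh"]


@dataclass(frozen=True)
class TruncatedNormalSpec:
    """A truncated-normal marginal: Normal(mean, sd) restricted to [low, high]."""

    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("sd must be > 0")
        if not self.low <= self.mean <= self.high:
            raise ValueError(
                f"range [{self.low}, {self.high}] must contain the mean "
                f"{self.mean}")
        if self.high < self.mean - 6 * self.sd or \
                self.low > self.mean + 6 * self.sd:
            raise ValueError("truncation range excludes mean +/- 6 sd; "
                             "sampling would be degenerate")

    def _frozen(self):
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return truncnorm(a, b, loc=self.mean, scale=self.sd)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return self._frozen().rvs(size=size, random_state=rng)

    def from_uniform(self, u: np.ndarray) -> np.ndarray:
        """Inverse-CDF transform (used for Gaussian-copula correlation)."""
        return self._frozen().ppf(u)


def _default_ipsi() -> TruncatedNormalSpec:
    # sd defaults to range/4 where only mean and range are known
    return TruncatedNormalSpec(51.7, (74.8 - 26.9) / 4, 26.9, 74.8)


def _default_contra() -> TruncatedNormalSpec:
    return TruncatedNormalSpec(36.7, (57.6 - 7.6) / 4, 7.6, 57.6)


def _default_sef() -> TruncatedNormalSpec:
    return TruncatedNormalSpec(48.1, 18.2, 19.2, 72.8)


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for one synthetic cohort.

    Defaults reproduce the study conditions: 31 patients (62 glands),
    the Table-1 dose and baseline-SEF marginals, a true SEF dose-response
    of (n=1, m=0.18, TD50=43.6 Gy) and a true QoL dose-response of
    (n=1, m=0.11, TD50=44.1 Gy).  Ipsilateral and contralateral doses are
    independent unless ``dose_correlation`` sets a Gaussian-copula
    correlation between them.
    """

    n_patients: int = 31
    ipsi_dose: TruncatedNormalSpec = field(default_factory=_default_ipsi)
    contra_dose: TruncatedNormalSpec = field(default_factory=_default_contra)
    baseline_sef: TruncatedNormalSpec = field(default_factory=_default_sef)
    true_params_sef: LKBParameters = LKBParameters(n=1.0, m=0.18, td50=43.6)
    true_params_qol: LKBParameters = LKBParameters(n=1.0, m=0.11, td50=44.1)
    dose_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not -1.0 < self.dose_correlation < 1.0:
            raise ValueError("dose_correlation must lie in (-1, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        kwargs = dict(d)
        for key in ("ipsi_dose", "contra_dose", "baseline_sef"):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = TruncatedNormalSpec(**kwargs[key])
        for key in ("true_params_sef", "true_params_qol"):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = LKBParameters(**kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "ipsi_dose": vars(self.ipsi_dose).copy(),
            "contra_dose": vars(self.contra_dose).copy(),
            "baseline_sef": vars(self.baseline_sef).copy(),
            "true_params_sef": vars(self.true_params_sef).copy(),
            "true_params_qol": vars(self.true_params_qol).copy(),
            "dose_correlation": self.dose_correlation,
            "seed": self.seed,
        }

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


def _sample_doses(config: CohortConfig, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    n = config.n_patients
    rho = config.dose_correlation
    if rho == 0.0:
        return (config.ipsi_dose.sample(n, rng),
                config.contra_dose.sample(n, rng))
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n)
    u = ndtr(z)
    return (config.ipsi_dose.from_uniform(u[:, 0]),
            config.contra_dose.from_uniform(u[:, 1]))


def simulate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw one cohort; bit-for-bit reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    ipsi, contra = _sample_doses(config, rng)
    records: list[PatientRecord] = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        glands = []
        for lat, dose in (("ipsilateral", ipsi[i]),
                          ("contralateral", contra[i])):
            p_event = ntcp(dose, config.true_params_sef)
            event = bool(rng.random() < p_event)
            baseline = float(config.baseline_sef.sample(1, rng)[0])
            if event:
                ratio = rng.uniform(np.nextafter(0.0, 1.0), 0.45)
            else:
                ratio = rng.uniform(np.nextafter(0.45, 1.0), 1.1)
            flow = FlowMeasurement(baseline, baseline * ratio)
            glands.append(GlandObservation(pid, lat, float(dose),
                                           flow=flow, event=event))
        spared = min(g.mean_dose for g in glands)
        p_qol = ntcp(spared, config.true_params_qol)
        qol_is_event = bool(rng.random() < p_qol)
        score = int(rng.integers(3, 5)) if qol_is_event \
            else int(rng.integers(1, 3))
        records.append(PatientRecord(pid, tuple(glands), qol_score=score))
    return records


def simulate_dvh(target_mean: float, spread: float, bins: int = 100,
                 seed: int | np.random.Generator = 0,
                 gland_id: str = "sim") -> DVHCurve:
    """A random differential DVH whose mean dose equals ``target_mean``.

    Bin doses are positive normal draws around the target with the given
    spread (Gy), volume fractions a flat Dirichlet draw; doses are then
    rescaled so the volume-weighted mean matches ``target_mean`` to 1e-6.
    ``spread = 0`` collapses to a single bin.
    """
    if not target_mean > 0:
        raise ValueError("target mean dose must be > 0")
    if spread < 0:
        raise ValueError("spread must be >= 0")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if spread == 0 or bins == 1:
        return DVHCurve.differential(gland_id, [target_mean], [1.0])
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    doses = np.abs(rng.normal(target_mean, spread, size=bins))
    doses = np.unique(doses[doses > 0])
    if doses.size == 1:
        return DVHCurve.differential(gland_id, [target_mean], [1.0])
    volumes = rng.dirichlet(np.ones(doses.size))
    doses = doses * (target_mean / float(np.dot(volumes, doses)))
    return DVHCurve.differential(gland_id, doses, volumes)
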