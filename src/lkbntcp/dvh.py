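"""Dose-volume histograms and their EUD / mean-dose reduction.

A DVH summarizes the dose distribution over an organ.  The differential
form lists (dose bin, volume fraction) point masses; the cumulative form
lists the volume fraction receiving at least each dose.  The equivalent
uniform dose (EUD) reduces a differential DVH to a single dose via the
generalized (power) mean

    EUD = ( sum_i v_i * D_i^(1/n) )^n ,

which equals the volume-weighted mean dose when n = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DVHCurve", "MalformedDVHError", "read_dvh", "eud", "mean_dose"]

logger = logging.getLogger(__name__)

_SUM_TOL = 1e-9


class MalformedDVHError(ValueError):
    """Raised for DVH input violating monotonicity / volume constraints."""


def _normalize_percent(volumes: np.ndarray, cumulative: bool) -> np.ndarray:
    # Percent-scale columns (e.g. planning-system exports) are detected by
    # values > 1.5: a differential curve sums to ~100, a cumulative one
    # starts at ~100.
    if volumes.size and volumes.max() > 1.5:
        total = volumes[0] if cumulative else volumes.sum()
        if abs(total - 100.0) <= 0.5:
            logger.warning("DVH volumes look like percentages; dividing by 100")
            return volumes / 100.0
    return volumes


@dataclass(frozen=True)
class DVHCurve:
    """A per-gland differential DVH: point masses (dose Gy, volume fraction).

    Construct with :meth:`differential` or :meth:`cumulative`; the stored
    representation is always differential.  Doses are strictly increasing
    and non-negative; volume fractions are non-negative and sum to 1.
    """

    gland_id: str
    doses: np.ndarray = field(repr=False)
    volumes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        volumes = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "volumes", volumes)
        if doses.ndim != 1 or doses.shape != volumes.shape:
            raise MalformedDVHError("doses and volumes must be equal-length 1-D")
        if doses.size == 0:
            raise MalformedDVHError("empty DVH")
        if np.any(doses < 0) or np.any(np.diff(doses) <= 0):
            raise MalformedDVHError("doses must be strictly increasing and >= 0")
        if np.any(volumes < 0):
            raise MalformedDVHError("volume fractions must be >= 0")
        if abs(volumes.sum() - 1.0) > _SUM_TOL:
            raise MalformedDVHError(
                f"differential volumes must sum to 1 (got {volumes.sum()!r})")

    @classmethod
    def differential(cls, gland_id: str, doses, volumes) -> "DVHCurve":
        volumes = _normalize_percent(np.asarray(volumes, dtype=float),
                                     cumulative=False)
        return cls(gland_id, np.asarray(doses, dtype=float), volumes)

    @classmethod
    def cumulative(cls, gland_id: str, doses, volumes) -> "DVHCurve":
        """Build from a cumulative curve (volume receiving >= dose).

        The curve must start at 1 (within 1e-9), be non-increasing and end
        >= 0.  The volume drop between consecutive points is assigned to
        the higher dose of the pair (right-edge convention); any residual
        volume beyond the last point stays at the last dose.
        """
        doses = np.asarray(doses, dtype=float)
        cumvol = _normalize_percent(np.asarray(volumes, dtype=float),
                                    cumulative=True)
        if doses.size == 0:
            raise MalformedDVHError("empty DVH")
        if np.any(doses < 0) or np.any(np.diff(doses) <= 0):
            raise MalformedDVHError("doses must be strictly increasing and >= 0")
        if np.any(np.diff(cumvol) > _SUM_TOL):
            raise MalformedDVHError("cumulative volumes must be non-increasing")
        if abs(cumvol[0] - 1.0) > _SUM_TOL:
            raise MalformedDVHError("cumulative curve must start at 1")
        if cumvol[-1] < -_SUM_TOL:
            raise MalformedDVHError("cumulative volumes must be >= 0")
        if doses.size == 1:
            return cls(gland_id, doses, np.array([cumvol[0]]))
        diff = np.clip(-np.diff(cumvol), 0.0, None)
        diff[-1] += max(cumvol[-1], 0.0)
        return cls(gland_id, doses[1:], diff)

    def to_cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        """Export as a cumulative curve (doses, volume receiving >= dose).

        A leading (0 Gy, 1.0) point is prepended when the first bin dose is
        positive so that :meth:`cumulative` reconstructs this curve exactly.
        """
        tail = np.concatenate([np.cumsum(self.volumes[::-1])[::-1][1:], [0.0]])
        if self.doses[0] > 0:
            return (np.concatenate([[0.0], self.doses]),
                    np.concatenate([[1.0], tail]))
        return self.doses.copy(), np.concatenate([[1.0], tail[1:]])


def read_dvh(path, form: str = "differential",
             gland_id: str | None = None) -> DVHCurve:
    """Read a two-column delimited DVH file (dose Gy, volume).

    The delimiter (comma or tab) is sniffed; an optional single header row
    is skipped.  ``form`` selects ``differential`` or ``cumulative`` input;
    cumulative curves are converted on read.
    """
    if form not in ("differential", "cumulative"):
        raise ValueError(f"form must be differential|cumulative, got {form!r}")
    try:
        df = pd.read_csv(path, sep=None, engine="python", header=None,
                         comment="#")
    except Exception as exc:  # noqa: BLE001 - surface as domain error
        raise MalformedDVHError(f"cannot parse DVH file {path}: {exc}") from exc
    # Drop a header row if the first row is not numeric.
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    if df.shape[1] != 2:
        raise MalformedDVHError(
            f"DVH file must have exactly 2 columns, found {df.shape[1]}")
    try:
        data = df.astype(float).to_numpy()
    except ValueError as exc:
        raise MalformedDVHError(f"non-numeric DVH entries: {exc}") from exc
    gid = gland_id if gland_id is not None else str(path)
    factory = (DVHCurve.differential if form == "differential"
               else DVHCurve.cumulative)
    return factory(gid, data[:, 0], data[:, 1])


def eud(curve: DVHCurve, n: float) -> float:
    """Equivalent uniform dose (Gy) with volume exponent ``n`` > 0."""
    if not n > 0:
        raise ValueError(f"volume exponent n must be > 0, got {n}")
    return float(np.dot(curve.volumes, curve.doses ** (1.0 / n)) ** n)


def mean_dose(curve: DVHCurve) -> float:
    """Volume-weighted mean dose (Gy); identical to ``eud(curve, 1)``."""
    return float(np.dot(curve.volumes, curve.doses))
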