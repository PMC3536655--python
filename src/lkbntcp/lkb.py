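"""Lyman-Kutcher-Burman (LKB) probit dose-response model.

The LKB model expresses the probability of a normal-tissue complication
(NTCP) as the standard-normal CDF of a standardized dose deviate,

    NTCP(EUD) = Phi(t),    t = (EUD - TD50) / (m * TD50),

where TD50 is the uniform dose giving a 50% complication probability and
m controls the steepness of the sigmoid (smaller m, steeper curve).  The
volume exponent n enters only through the EUD reduction of the
dose-volume histogram (see :mod:`lkbntcp.dvh`); with n = 1 the EUD is the
mean organ dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = ["LKBParameters", "lkb_t", "ntcp", "inverse_ntcp", "ntcp_curve"]

#: Lower bound on the slope parameter; below this the dose-response curve
#: degenerates into a numerical step function.
M_MIN = 1e-4


@dataclass(frozen=True)
class LKBParameters:
    """The LKB model triple (n, m, TD50).

    Parameters
    ----------
    n : float
        Volume-effect exponent (dimensionless), > 0.  n near 1 describes a
        parallel organ (mean dose drives response); n << 1 a serial one.
    m : float
        Slope parameter (dimensionless), >= 1e-4.
    td50 : float
        Dose in Gy producing a 50% complication probability, > 0.
    """

    n: float = 1.0
    m: float = 0.18
    td50: float = 43.6

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise ValueError(f"volume exponent n must be > 0, got {self.n}")
        if not self.m >= M_MIN:
            raise ValueError(f"slope m must be >= {M_MIN}, got {self.m}")
        if not self.td50 > 0:
            raise ValueError(f"td50 must be > 0 Gy, got {self.td50}")


def lkb_t(eud, params: LKBParameters):
    """Standardized dose deviate t = (EUD - TD50) / (m * TD50).

    Accepts a scalar or array EUD in Gy; returns the same shape.
    """
    eud = np.asarray(eud, dtype=float)
    t = (eud - params.td50) / (params.m * params.td50)
    return float(t) if t.ndim == 0 else t


def ntcp(eud, params: LKBParameters):
    """Complication probability Phi(t) at the given EUD (Gy).

    The standard-normal CDF is evaluated with :func:`scipy.special.ndtr`
    (erf-based, |error| < 1e-15), not by literal quadrature.
    """
    p = ndtr(np.asarray(lkb_t(eud, params)))
    return float(p) if p.ndim == 0 else p


def inverse_ntcp(p, params: LKBParameters):
    """The unique EUD (Gy) at which the model attains probability ``p``.

    Inverts the probit: EUD = TD50 * (1 + m * Phi^{-1}(p)).  Requires
    0 < p < 1.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probability must lie strictly inside (0, 1)")
    eud = params.td50 * (1.0 + params.m * ndtri(p))
    return float(eud) if eud.ndim == 0 else eud


def ntcp_curve(params: LKBParameters, dose_max: float = 80.0,
               step: float = 0.5) -> np.ndarray:
    """Tabulate (dose, NTCP) on a regular grid from 0 to ``dose_max`` Gy.

    Returns an array of shape (k, 2); convenient for plotting fitted
    dose-response curves.
    """
    doses = np.arange(0.0, dose_max + step / 2, step)
    return np.column_stack([doses, ntcp(doses, params)])
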