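"""Maximum-likelihood estimation of LKB parameters from binary dose-response data.

Each analysis unit is a (dose, event) pair; events are Bernoulli with
success probability NTCP(dose; n, m, TD50).  With the volume exponent n
fixed at 1 (the mean-dose model) the free parameters are (TD50, m),
estimated by minimizing the negative Bernoulli log-likelihood on a log
scale inside box bounds, from a fixed multi-start grid for determinism.
Confidence intervals are profile-likelihood intervals: the bounds where
the log-likelihood drops by chi2_1(level)/2 from its maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from .lkb import LKBParameters, ntcp

__all__ = ["FitResult", "NonIdentifiableError", "neg_loglik", "fit_lkb",
           "profile_ci"]

_P_CLAMP = 1e-12
DEFAULT_BOUNDS = {"td50": (5.0, 100.0), "m": (0.01, 1.0), "n": (0.05, 5.0)}
#: Quantiles of the log-scale box at which the deterministic multi-start
#: grid is placed.
_START_QUANTILES = (0.15, 0.5, 0.85)


class NonIdentifiableError(ValueError):
    """Raised when the data cannot identify the LKB parameters."""


@dataclass
class FitResult:
    """ML estimates with profile CIs and log-likelihoods for one cohort fit."""

    params: LKBParameters
    loglik: float
    loglik_null: float
    n_obs: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    converged: bool = True
    fit_meta: dict = field(default_factory=dict)


def neg_loglik(params: LKBParameters, doses, events) -> float:
    """Negative Bernoulli log-likelihood of (dose, event) units.

    Probabilities are clamped to [1e-12, 1 - 1e-12] so fully separated
    data stay finite.
    """
    doses = np.asarray(doses, dtype=float)
    events = np.asarray(events, dtype=bool)
    if doses.size == 0:
        raise ValueError("units must be non-empty")
    p = np.clip(ntcp(doses, params), _P_CLAMP, 1.0 - _P_CLAMP)
    return float(-np.sum(np.where(events, np.log(p), np.log1p(-p))))


def _null_loglik(events: np.ndarray) -> float:
    """Log-likelihood of the intercept-only Bernoulli model."""
    n = events.size
    k = int(events.sum())
    ll = 0.0
    if 0 < k:
        ll += k * np.log(k / n)
    if k < n:
        ll += (n - k) * np.log((n - k) / n)
    return float(ll)


def _check_units(doses: np.ndarray, events: np.ndarray) -> None:
    if doses.size < 2:
        raise NonIdentifiableError("need at least 2 observations")
    if events.all() or not events.any():
        raise NonIdentifiableError(
            "both outcome classes must be present to fit the dose-response")
    if np.unique(doses).size < 2:
        raise NonIdentifiableError(
            "all observations share one dose level; TD50 is not identifiable")


def fit_lkb(doses, events, fix_n: float | None = 1.0, init=None, bounds=None,
            compute_ci: bool = True, ci_level: float = 0.95) -> FitResult:
    """Fit (TD50, m) - and optionally n - by maximum likelihood.

    Parameters
    ----------
    doses, events : array-like
        Analysis units; doses in Gy, events boolean.
    fix_n : float or None
        Volume exponent held fixed (default 1, the mean-dose model).
        ``None`` frees n as a third parameter; this is experimental, the
        scalar doses must then already be EUDs for candidate n values to
        differ, so identifiability is weak.
    init : LKBParameters, optional
        Extra starting point prepended to the deterministic 3x3 grid.
    bounds : dict, optional
        Box bounds per parameter name, e.g. ``{"td50": (5, 100)}``;
        unspecified parameters keep :data:`DEFAULT_BOUNDS`.  Pass rescaled
        td50 bounds when doses are in other units (e.g. cGy).
    compute_ci : bool
        Compute profile-likelihood CIs for td50 and m (skip for speed in
        simulation loops).

    Returns
    -------
    FitResult
        ``converged`` reflects optimizer status; an estimate of m on its
        lower box bound triggers a separation warning.
    """
    doses = np.asarray(doses, dtype=float)
    events = np.asarray(events, dtype=bool)
    _check_units(doses, events)
    box = dict(DEFAULT_BOUNDS)
    if bounds:
        box.update(bounds)
    free = ["td50", "m"] + ([] if fix_n is not None else ["n"])
    log_bounds = [np.log(box[name]) for name in free]

    def build_params(theta: np.ndarray) -> LKBParameters:
        vals = dict(zip(free, np.exp(theta)))
        return LKBParameters(n=fix_n if fix_n is not None else vals["n"],
                             m=vals["m"], td50=vals["td50"])

    def objective(theta: np.ndarray) -> float:
        return neg_loglik(build_params(theta), doses, events)

    starts = []
    if init is not None:
        theta0 = [np.log(getattr(init, name)) for name in free]
        starts.append(np.array(theta0))
    grid_1d = [[lo + q * (hi - lo) for q in _START_QUANTILES]
               for lo, hi in log_bounds]
    mesh = np.meshgrid(*grid_1d, indexing="ij")
    starts.extend(np.column_stack([m.ravel() for m in mesh]))

    best = None
    for theta0 in starts:
        res = optimize.minimize(objective, theta0, method="L-BFGS-B",
                                bounds=log_bounds)
        if best is None or res.fun < best.fun:
            best = res
    params = build_params(best.x)
    separated = doses[events].min() > doses[~events].max()
    if separated or params.m <= box["m"][0] * 1.0001:
        warnings.warn(
            "outcomes are perfectly separated by dose (or m sits on its "
            "lower bound): the slope is a boundary estimate and the fit "
            "is not identifiable",
            RuntimeWarning, stacklevel=2)
    result = FitResult(
        params=params,
        loglik=-float(best.fun),
        loglik_null=_null_loglik(events),
        n_obs=int(doses.size),
        converged=bool(best.success),
        fit_meta={"n_starts": len(starts), "nit": int(best.nit),
                  "message": str(best.message), "bounds": box,
                  "fix_n": fix_n},
    )
    if compute_ci:
        for name in ("td50", "m"):
            result.ci[name] = profile_ci(result, doses, events, param=name,
                                         level=ci_level)
    return result


def _profile_loglik(value: float, param: str, fit: FitResult,
                    doses: np.ndarray, events: np.ndarray) -> float:
    """Max log-likelihood over the nuisance parameter at a fixed value."""
    other = "m" if param == "td50" else "td50"
    box = fit.fit_meta.get("bounds", DEFAULT_BOUNDS)
    fix_n = fit.fit_meta.get("fix_n", fit.params.n)
    n_val = fit.params.n if fix_n is None else fix_n

    def nll_of(log_other: float) -> float:
        vals = {param: value, other: float(np.exp(log_other))}
        p = LKBParameters(n=n_val, m=vals["m"], td50=vals["td50"])
        return neg_loglik(p, doses, events)

    lo, hi = np.log(box[other])
    res = optimize.minimize_scalar(nll_of, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    return -float(res.fun)


def profile_ci(fit: FitResult, doses, events, param: str = "td50",
               level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood confidence interval for td50 or m.

    Each bound solves 2*(loglik_max - loglik_profile(value)) = chi2_1
    quantile at ``level`` by bisection (1e-4 relative tolerance).  If the
    profile has not dropped below the threshold at the box edge the
    interval is open on that side: the edge is returned with a warning.
    """
    if param not in ("td50", "m"):
        raise ValueError(f"param must be td50|m, got {param!r}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if not fit.converged:
        raise ValueError("cannot profile a non-converged fit")
    doses = np.asarray(doses, dtype=float)
    events = np.asarray(events, dtype=bool)
    target = fit.loglik - chi2.ppf(level, df=1) / 2.0
    mle = getattr(fit.params, param)
    box = fit.fit_meta.get("bounds", DEFAULT_BOUNDS)[param]

    def excess(value: float) -> float:
        return _profile_loglik(value, param, fit, doses, events) - target

    bounds_out = []
    for edge in box:
        if excess(edge) > 0:
            warnings.warn(
                f"{param} profile interval open at {edge} (search box edge)",
                RuntimeWarning, stacklevel=2)
            bounds_out.append(float(edge))
            continue
        # Bisection on the log scale between the MLE (excess > 0) and the
        # box edge (excess < 0).
        inner, outer = mle, float(edge)
        for _ in range(100):
            mid = float(np.sqrt(inner * outer))
            if excess(mid) > 0:
                inner = mid
            else:
                outer = mid
            if abs(outer - inner) / max(abs(outer), 1e-12) < 1e-4:
                break
        bounds_out.append(float(np.sqrt(inner * outer)))
    lower, upper = sorted(bounds_out)
    return lower, upper
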