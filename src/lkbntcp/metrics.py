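"""Model performance and association statistics for binary dose-response fits.

Covers overall performance (Nagelkerke pseudo-R-squared), discrimination
(AUC), calibration (Hosmer-Lemeshow decile test), Pearson chi-squared
goodness of fit / association, and Spearman rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = ["PerformanceReport", "nagelkerke_r2", "auc", "hosmer_lemeshow",
           "pearson_chi2_gof", "pearson_chi2_2x2", "spearman",
           "performance_report"]


@dataclass(frozen=True)
class PerformanceReport:
    """The model-performance battery for one fitted endpoint."""

    nagelkerke_r2: float
    auc: float
    hl_chi2: float
    hl_df: int
    hl_p: float
    pearson_chi2: float
    pearson_p: float


def nagelkerke_r2(loglik_model: float, loglik_null: float, n_obs: int) -> float:
    """Nagelkerke's R-squared: Cox-Snell R2 normalized by its maximum.

    R2 = [1 - exp(2(ll0 - ll)/n)] / [1 - exp(2*ll0/n)].
    """
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    if loglik_model < loglik_null - 1e-9:
        raise ValueError("model log-likelihood must be >= null log-likelihood")
    denom = 1.0 - np.exp(2.0 * loglik_null / n_obs)
    if denom <= 0:
        raise ValueError("null model is saturated; R2 undefined")
    num = 1.0 - np.exp(2.0 * (loglik_null - max(loglik_model, loglik_null))
                       / n_obs)
    return float(num / denom)


def auc(scores, labels) -> float:
    """Area under the ROC curve, i.e. the Mann-Whitney concordance
    (#concordant + 0.5 * #ties) / (n1 * n0).  Both classes required."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUC needs both outcome classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def hosmer_lemeshow(pred, labels, groups: int = 10
                    ) -> tuple[float, int, float]:
    """Hosmer-Lemeshow calibration test on near-equal predicted-risk groups.

    Observations are sorted by predicted probability and split into
    ``groups`` near-equal bins; tied predictions stay together in the
    lower bin.  chi2 = sum_g (O1-E1)^2/E1 + (O0-E0)^2/E0 with df =
    groups - 2.  Bins with a zero expected count are merged into their
    neighbour (df reduced, warning issued).

    Returns (chi2, df, p).
    """
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n = pred.size
    if n != labels.size:
        raise ValueError("pred and labels must have equal length")
    if n < 2 * groups:
        raise ValueError(f"need at least {2 * groups} observations "
                         f"for {groups} groups")
    order = np.argsort(pred, kind="stable")
    pred_s, labels_s = pred[order], labels[order]
    edges = []
    for g in range(1, groups):
        b = round(n * g / groups)
        # keep tied predictions together in the lower bin
        while b < n and b > 0 and pred_s[b - 1] == pred_s[b]:
            b += 1
        edges.append(b)
    edges = sorted(set(e for e in edges if 0 < e < n))
    bounds = [0] + edges + [n]
    bins = [(pred_s[a:b], labels_s[a:b])
            for a, b in zip(bounds[:-1], bounds[1:])]
    # merge bins whose expected event or non-event count is exactly zero
    merged = []
    for p_g, y_g in bins:
        e1 = p_g.sum()
        e0 = (1 - p_g).sum()
        if merged and (e1 == 0 or e0 == 0):
            warnings.warn("merging Hosmer-Lemeshow bin with zero expected "
                          "count into its neighbour", RuntimeWarning,
                          stacklevel=2)
            pp, yy = merged[-1]
            merged[-1] = (np.concatenate([pp, p_g]), np.concatenate([yy, y_g]))
        else:
            merged.append((p_g, y_g))
    chi2_stat = 0.0
    for p_g, y_g in merged:
        e1, e0 = p_g.sum(), (1 - p_g).sum()
        o1 = y_g.sum()
        o0 = y_g.size - o1
        chi2_stat += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    df = len(merged) - 2
    if df < 1:
        raise ValueError("fewer than 3 usable groups after merging")
    p_value = float(stats.chi2.sf(chi2_stat, df))
    return float(chi2_stat), int(df), p_value


def pearson_chi2_gof(pred, labels, n_params: int = 2) -> tuple[float, float]:
    """Per-observation Pearson chi-squared goodness of fit for a binary model.

    X2 = sum_i (y_i - p_i)^2 / (p_i (1 - p_i)), df = n - n_params.
    """
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if np.any((pred <= 0) | (pred >= 1)):
        raise ValueError("predicted probabilities must lie in (0, 1)")
    x2 = float(np.sum((labels - pred) ** 2 / (pred * (1 - pred))))
    df = pred.size - n_params
    if df < 1:
        raise ValueError("non-positive degrees of freedom")
    return x2, float(stats.chi2.sf(x2, df))


def pearson_chi2_2x2(table) -> tuple[float, float]:
    """Uncorrected Pearson chi-squared test of association on a 2x2 table.

    No Yates continuity correction is applied.
    """
    table = np.asarray(table)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("table must be a 2x2 array of non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all table margins must be positive")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with the t-approximation p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length sequences with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("rank variance is zero; correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def performance_report(fit, doses, labels, groups: int = 10
                       ) -> PerformanceReport:
    """Assemble the full battery for a FitResult on its analysis units."""
    from .lkb import ntcp  # local import to avoid a cycle at module load

    doses = np.asarray(doses, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = np.clip(ntcp(doses, fit.params), 1e-12, 1 - 1e-12)
    ll_model = max(fit.loglik, fit.loglik_null)  # guard tiny numeric deficit
    r2 = nagelkerke_r2(ll_model, fit.loglik_null, fit.n_obs)
    hl_chi2, hl_df, hl_p = hosmer_lemeshow(pred, labels, groups=groups)
    gof_chi2, gof_p = pearson_chi2_gof(pred, labels, n_params=2)
    return PerformanceReport(
        nagelkerke_r2=r2,
        auc=auc(pred, labels),
        hl_chi2=hl_chi2, hl_df=hl_df, hl_p=hl_p,
        pearson_chi2=gof_chi2, pearson_p=gof_p,
    )
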