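"""Covariate-balance diagnostics: standardized mean differences and density overlap.

The SMD denominator is the pooled standard deviation computed on the
*unmatched* cohort (average of the two group variances; binary covariates use
p(1-p) variances), so pre- and post-matching SMDs share a denominator.  The
overlap coefficient (OVL) integrates the pointwise minimum of weighted
Gaussian kernel density estimates of the propensity score in the two matched
groups; 1 means identical distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "BalanceReport",
    "pooled_reference_sd",
    "smd",
    "asmd",
    "overlap_coefficient",
    "balance_report",
]

_OVL_GRID_POINTS = 512
_OVL_PAD_BANDWIDTHS = 3.0
_BANDWIDTH_FLOOR = 1e-3


@dataclass(frozen=True)
class BalanceReport:
    """Balance diagnostics of one matched sample."""

    smd_per_covariate: np.ndarray  # signed, one entry per covariate
    asmd: float
    ovl: float
    one_minus_ovl: float


def _is_binary(x: np.ndarray) -> bool:
    return np.isin(np.unique(x), (0.0, 1.0)).all()


def _group_var(x: np.ndarray, binary: bool) -> float:
    if binary:
        p = float(np.mean(x))
        return p * (1.0 - p)
    return float(np.var(x, ddof=1))


def pooled_reference_sd(x: np.ndarray, t: np.ndarray) -> float:
    """Pooled-groups SD ``sqrt((s_t^2 + s_c^2)/2)`` on the unmatched cohort.

    Binary covariates (values in {0,1}) use ``p(1-p)`` variances.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t).astype(bool)
    binary = _is_binary(x)
    return float(np.sqrt((_group_var(x[t], binary) + _group_var(x[~t], binary)) / 2.0))


def smd(
    x: np.ndarray,
    t: np.ndarray,
    w: np.ndarray | None = None,
    sd_reference: float | None = None,
) -> float:
    """Signed standardized mean difference (treated minus control).

    ``w`` are unit weights (matching weights on a matched sample; ``None``
    for the unweighted cohort).  ``sd_reference`` defaults to the pooled SD
    of ``x`` over the two groups of the data passed in; on matched samples
    pass the unmatched-cohort value so the denominator is shared.  Returns
    NaN when the reference SD is zero.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t).astype(bool)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    wt, wc = w[t], w[~t]
    if wt.sum() <= 0 or wc.sum() <= 0:
        raise ValueError("both groups need positive total weight")
    if sd_reference is None:
        sd_reference = pooled_reference_sd(x, t)
    if sd_reference == 0:
        return float("nan")
    mean_t = float(np.average(x[t], weights=wt))
    mean_c = float(np.average(x[~t], weights=wc))
    return (mean_t - mean_c) / sd_reference


def asmd(smds: np.ndarray) -> float:
    """Average absolute SMD across covariates."""
    smds = np.asarray(smds, dtype=float)
    if np.isnan(smds).any():
        raise ValueError("ASMD undefined with missing SMD entries")
    return float(np.abs(smds).mean())


def _weighted_kde(values: np.ndarray, weights: np.ndarray):
    """Weighted Gaussian KDE with Silverman bandwidth and a degeneracy floor."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    try:
        kde = gaussian_kde(values, bw_method="silverman", weights=weights)
        bw = float(np.sqrt(kde.covariance[0, 0]))
        if bw >= _BANDWIDTH_FLOOR:
            return kde.evaluate, bw
    except np.linalg.LinAlgError:
        pass
    # single distinct value (or near-degenerate spread): floor the bandwidth
    bw = _BANDWIDTH_FLOOR

    def evaluate(grid: np.ndarray) -> np.ndarray:
        z = (grid[:, None] - values[None, :]) / bw
        return (np.exp(-0.5 * z**2) / (bw * np.sqrt(2 * np.pi))) @ weights

    return evaluate, bw


def overlap_coefficient(
    ps_treated: np.ndarray,
    ps_control: np.ndarray,
    w_treated: np.ndarray | None = None,
    w_control: np.ndarray | None = None,
) -> float:
    """OVL: integral of the pointwise minimum of the two weighted PS densities.

    Densities are weighted Gaussian KDEs (Silverman bandwidth) evaluated on a
    512-point grid spanning the pooled range padded by three bandwidths.
    """
    ps_treated = np.asarray(ps_treated, dtype=float)
    ps_control = np.asarray(ps_control, dtype=float)
    if ps_treated.size == 0 or ps_control.size == 0:
        raise ValueError("both groups must be non-empty")
    w_treated = np.ones_like(ps_treated) if w_treated is None else np.asarray(w_treated, float)
    w_control = np.ones_like(ps_control) if w_control is None else np.asarray(w_control, float)
    f1, bw1 = _weighted_kde(ps_treated, w_treated)
    f0, bw0 = _weighted_kde(ps_control, w_control)
    pad = _OVL_PAD_BANDWIDTHS * max(bw1, bw0)
    lo = min(ps_treated.min(), ps_control.min()) - pad
    hi = max(ps_treated.max(), ps_control.max()) + pad
    grid = np.linspace(lo, hi, _OVL_GRID_POINTS)
    ovl = float(np.trapezoid(np.minimum(f1(grid), f0(grid)), grid))
    return min(ovl, 1.0)


def balance_report(
    X: np.ndarray,
    t: np.ndarray,
    ps: np.ndarray,
    weights: np.ndarray,
    reference_sds: np.ndarray,
) -> BalanceReport:
    """Balance diagnostics of a matched sample.

    ``weights`` are the aggregate matching weights (zero for unmatched
    units); ``reference_sds`` are the per-covariate pooled SDs of the
    unmatched cohort.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t).astype(bool)
    in_sample = np.asarray(weights, dtype=float) > 0
    smds = np.array(
        [
            smd(X[in_sample, j], t[in_sample], weights[in_sample], reference_sds[j])
            for j in range(X.shape[1])
        ]
    )
    ovl = overlap_coefficient(
        ps[in_sample & t], ps[in_sample & ~t], weights[in_sample & t], weights[in_sample & ~t]
    )
    return BalanceReport(
        smd_per_covariate=smds, asmd=asmd(smds), ovl=ovl, one_minus_ovl=1.0 - ovl
    )
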