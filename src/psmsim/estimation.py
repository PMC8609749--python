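"""ATT estimation on matched samples with two variance estimators.

The ATT is the mean over matched sets of the treated outcome minus the
average control outcome in the set (the weighted absolute risk reduction
under the 1/m control-weight convention).  Two standard errors are computed:

* ``standard``: the matched-set paired-difference SE, ``sd(d_i)/sqrt(n)``
  with sample SD over set-level differences — the classical matched-pairs
  form for 1:1 binary data;
* ``abadie_imbens``: adds the control-reuse correction driven by usage
  counts and locally estimated conditional outcome variances; only defined
  for matching with replacement.

Confidence intervals are normal-theory at the requested level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .matching import MatchedSample

__all__ = [
    "ATTEstimate",
    "estimate_att",
    "standard_se",
    "abadie_imbens_se",
    "nearest_same_group",
    "confidence_interval",
    "estimate_all",
]


@dataclass(frozen=True)
class ATTEstimate:
    """Point estimate, both standard errors and 95% CIs for one matched sample."""

    att: float
    se_standard: float
    se_ai: float | None  # None when matching was without replacement
    ci_standard: tuple[float, float]
    ci_ai: tuple[float, float] | None
    n_sets: int


def _set_differences(sample: MatchedSample, y: np.ndarray) -> np.ndarray:
    """Set-level differences d_i = y_treated - mean(y_controls), vectorized."""
    y = np.asarray(y, dtype=float)
    n_sets = len(sample.sets)
    t_idx = np.fromiter((s.treated_index for s in sample.sets), dtype=int, count=n_sets)
    counts = np.fromiter((s.m for s in sample.sets), dtype=int, count=n_sets)
    flat = np.fromiter(
        (c for s in sample.sets for c in s.control_indices), dtype=int, count=int(counts.sum())
    )
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    control_means = np.add.reduceat(y[flat], starts) / counts
    return y[t_idx] - control_means


def estimate_att(sample: MatchedSample, y: np.ndarray) -> float:
    """ATT point estimate: mean over sets of (treated outcome - mean control outcome)."""
    if sample.n_sets == 0:
        raise ValueError("ATT undefined on an empty matched sample")
    return float(_set_differences(sample, y).mean())


def standard_se(sample: MatchedSample, y: np.ndarray) -> float:
    """Matched-set paired-difference standard error, ``sd(d_i)/sqrt(n_sets)``."""
    if sample.n_sets < 2:
        raise ValueError("standard SE needs at least 2 matched sets")
    d = _set_differences(sample, y)
    return float(np.std(d, ddof=1) / np.sqrt(d.size))


def nearest_same_group(indices: np.ndarray, logit_ps: np.ndarray) -> dict[int, int]:
    """Nearest neighbour within a group by |logit PS| distance, ties to lower index.

    Used for the conditional-variance estimate of each control in the
    Abadie-Imbens variance.  Distinct logit-PS values take a vectorized
    sorted-neighbour path; exact ties fall back to exhaustive search.
    """
    indices = np.asarray(indices, dtype=int)
    lp = np.asarray(logit_ps, dtype=float)[indices]
    m = indices.size
    if m < 2:
        raise ValueError("need at least two units in the group")
    if np.unique(lp).size == m:
        order = np.argsort(lp)
        si, sl = indices[order], lp[order]
        dl = np.concatenate(([np.inf], np.diff(sl)))
        dr = np.concatenate((np.diff(sl), [np.inf]))
        left = np.roll(si, 1)
        right = np.roll(si, -1)
        pick_left = (dl < dr) | ((dl == dr) & (left < right))
        nn_sorted = np.where(pick_left, left, right)
        return {int(i): int(j) for i, j in zip(si, nn_sorted)}
    nn: dict[int, int] = {}
    for k in range(m):
        d = np.abs(lp - lp[k])
        d[k] = np.inf
        order = np.lexsort((indices, d))
        nn[int(indices[k])] = int(indices[order[0]])
    return nn


def abadie_imbens_se(
    sample: MatchedSample,
    y: np.ndarray,
    logit_ps: np.ndarray,
    nn_map: dict[int, int] | None = None,
) -> float:
    """Abadie-Imbens standard error for matching with replacement.

    ``V = n^-2 [ sum_i (d_i - att)^2 + sum_j (K_j^2 - K'_j) sigma2_j ]`` where
    for control ``j``: ``K_j = sum over sets containing j of 1/m_i``,
    ``K'_j = sum of 1/m_i^2``, and ``sigma2_j = (y_j - y_l(j))^2 / 2`` with
    ``l(j)`` the nearest other control on the logit-PS scale.  The second
    term is the control-reuse correction; it vanishes when no control is
    reused at ratio 1.

    ``nn_map`` optionally supplies a precomputed control nearest-neighbour
    map (from :func:`nearest_same_group`), shared across strategies on the
    same cohort.
    """
    if not sample.options.with_replacement:
        raise ValueError("the Abadie-Imbens SE applies to matching with replacement")
    if sample.n_sets < 2:
        raise ValueError("Abadie-Imbens SE needs at least 2 matched sets")
    y = np.asarray(y, dtype=float)
    logit_ps = np.asarray(logit_ps, dtype=float)
    d = _set_differences(sample, y)
    att = d.mean()
    n = d.size

    K: dict[int, float] = {}
    Kp: dict[int, float] = {}
    for s in sample.sets:
        inv_m = 1.0 / s.m
        for c in s.control_indices:
            K[c] = K.get(c, 0.0) + inv_m
            Kp[c] = Kp.get(c, 0.0) + inv_m**2

    # conditional outcome variance of each matched control from its nearest
    # same-group neighbour among all controls in the cohort; every treated
    # unit is either matched or discarded, so the complement is the controls
    correction = 0.0
    if nn_map is None:
        treated_set = {s.treated_index for s in sample.sets} | set(sample.discarded_treated)
        all_controls = np.array(sorted(set(range(len(y))) - treated_set), dtype=int)
        nn_map = nearest_same_group(all_controls, logit_ps) if all_controls.size >= 2 else None
    if nn_map is not None:
        for j, kj in K.items():
            sigma2 = 0.5 * (y[j] - y[nn_map[j]]) ** 2
            correction += (kj**2 - Kp[j]) * sigma2
    # fewer than 2 controls in the cohort: conditional variances set to 0

    var = (np.sum((d - att) ** 2) + correction) / n**2
    return float(np.sqrt(var))


def confidence_interval(att: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-theory CI ``att +/- z_{(1+level)/2} * se``."""
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    z = norm.ppf((1.0 + level) / 2.0)
    return (att - z * se, att + z * se)


def estimate_all(
    sample: MatchedSample,
    y: np.ndarray,
    logit_ps: np.ndarray,
    level: float = 0.95,
    nn_map: dict[int, int] | None = None,
) -> ATTEstimate:
    """Point estimate, both SEs and CIs for one matched sample."""
    att = estimate_att(sample, y)
    se_std = standard_se(sample, y)
    ci_std = confidence_interval(att, se_std, level)
    if sample.options.with_replacement:
        se_ai = abadie_imbens_se(sample, y, logit_ps, nn_map=nn_map)
        ci_ai = confidence_interval(att, se_ai, level)
    else:
        se_ai, ci_ai = None, None
    return ATTEstimate(
        att=att,
        se_standard=se_std,
        se_ai=se_ai,
        ci_standard=ci_std,
        ci_ai=ci_ai,
        n_sets=sample.n_sets,
    )
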