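"""Independent reference implementations used only to check the package."""

from __future__ import annotations

import numpy as np


def brute_force_match(
    logit_ps: np.ndarray,
    t: np.ndarray,
    caliper: float,
    K: int,
    with_replacement: bool,
    order_seed: int,
    partial_sets: bool = False,
):
    """Exhaustive greedy matcher replaying the package's order and tie-break rule.

    Returns (sets, discarded) where sets maps treated index -> list of
    control indices ordered by (distance, index).
    """
    logit_ps = np.asarray(logit_ps, dtype=float)
    t = np.asarray(t).astype(bool)
    treated = [i for i in range(len(t)) if t[i]]
    controls = [i for i in range(len(t)) if not t[i]]
    order = np.random.default_rng(order_seed).permutation(len(treated))
    available = set(controls)
    sets: dict[int, list[int]] = {}
    discarded: list[int] = []
    for pos in order:
        ti = treated[pos]
        pool = controls if with_replacement else sorted(available)
        cands = [c for c in pool if abs(logit_ps[c] - logit_ps[ti]) <= caliper]
        cands.sort(key=lambda c: (abs(logit_ps[c] - logit_ps[ti]), c))
        if len(cands) < K and not (partial_sets and cands):
            discarded.append(ti)
            continue
        chosen = cands[:K]
        sets[ti] = chosen
        if not with_replacement:
            available -= set(chosen)
    return sets, discarded


def paired_binary_variance(d: np.ndarray) -> float:
    """Variance of the mean paired difference from the 2x2 discordance table.

    For 1:1 matched pairs with binary outcomes the set-level differences are
    in {-1, 0, 1}; with b pairs at +1 and c at -1 out of n, the sample
    variance of the mean difference is (b + c - (b-c)^2/n) / ((n-1) n).
    """
    d = np.asarray(d)
    n = d.size
    b = int((d == 1).sum())
    c = int((d == -1).sum())
    return (b + c - (b - c) ** 2 / n) / ((n - 1) * n)


def normal_overlap(mu1: float, mu2: float, sigma: float) -> float:
    """Closed-form overlap of two equal-variance normal densities."""
    from scipy.stats import norm

    return 2.0 * norm.cdf(-abs(mu1 - mu2) / (2.0 * sigma))
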