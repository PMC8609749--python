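"""Propensity-score estimation and greedy nearest-neighbour caliper matching.

The propensity score is fit by maximum-likelihood logistic regression of the
treatment on all six covariates as main effects.  Matching operates on the
logit of the propensity score with a caliper of 0.2 standard deviations of
that logit.  Ten strategies are supported: with or without replacement,
matching ratio K = 1..5.  Treated units are processed in a seeded random
order; a treated unit that cannot obtain K distinct in-caliper controls is
discarded entirely.  Ties in distance are broken by the lower control index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .synthetic import Cohort

__all__ = [
    "PropensityFit",
    "MatchOptions",
    "MatchedSet",
    "MatchedSample",
    "fit_propensity",
    "fit_propensity_xy",
    "compute_caliper",
    "match",
    "match_with_replacement_family",
    "proportion_matched_treated",
    "proportion_resampled_controls",
]

CALIPER_MULTIPLIER = 0.2


@dataclass(frozen=True)
class PropensityFit:
    """Fitted propensity model for one cohort."""

    ps: np.ndarray
    logit_ps: np.ndarray
    coefficients: np.ndarray  # intercept followed by 6 slopes, log-odds
    converged: bool
    caliper_width: float


@dataclass(frozen=True)
class MatchOptions:
    """One matching strategy: replacement flag, ratio, and processing-order seed.

    ``partial_sets`` controls what happens to a treated unit with fewer than
    K admissible controls: under the strict policy (default) it is discarded
    entirely; under the partial policy it keeps the controls it found (at
    least one) and only zero-candidate treated units are discarded.  The
    simulation engine uses the partial policy, mirroring the behaviour of
    the reference matching software in which the caliper drops pairs rather
    than whole treated units; the proportion of matched treated then counts
    only the treated units that received the full prespecified K.
    """

    with_replacement: bool
    ratio_K: int
    order_seed: int = 0
    caliper_multiplier: float = CALIPER_MULTIPLIER
    partial_sets: bool = False

    def __post_init__(self) -> None:
        if self.ratio_K not in (1, 2, 3, 4, 5):
            raise ValueError("ratio_K must be in 1..5")


@dataclass(frozen=True)
class MatchedSet:
    """One treated unit with its matched controls, ordered by distance."""

    treated_index: int
    control_indices: tuple[int, ...]

    @property
    def m(self) -> int:
        return len(self.control_indices)

    @property
    def control_weight(self) -> float:
        # each of the m controls carries weight 1/m; the treated unit weight 1
        return 1.0 / self.m


@dataclass
class MatchedSample:
    """Result of one matching strategy on one cohort."""

    sets: list[MatchedSet]
    usage_count: dict[int, int]
    n_treated_total: int
    n_treated_matched: int
    discarded_treated: list[int]
    options: MatchOptions
    caliper_width: float
    n_treated_full: int = 0  # sets that received the full prespecified K

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    def unit_weights(self, n: int, t: np.ndarray) -> np.ndarray:
        """Aggregate matching weights for all ``n`` units.

        Matched treated units get weight 1; each control accumulates 1/m for
        every set it belongs to; unmatched units get weight 0.
        """
        w = np.zeros(n)
        for s in self.sets:
            w[s.treated_index] = 1.0
            for c in s.control_indices:
                w[c] += s.control_weight
        return w

    def to_frame(self):
        """Tidy long-format table of the matched sample (one row per unit per set)."""
        import pandas as pd

        rows = []
        for set_id, s in enumerate(self.sets):
            rows.append((set_id, "treated", s.treated_index, 1.0))
            for c in s.control_indices:
                rows.append((set_id, "control", c, s.control_weight))
        return pd.DataFrame(rows, columns=["set_id", "role", "unit_index", "weight"])


def fit_propensity(cohort: Cohort) -> PropensityFit:
    """Fit the main-effects logistic propensity model for a cohort.

    Non-convergence or perfect separation is flagged (``converged=False``)
    rather than raised, so a simulation replication can be marked invalid
    downstream.
    """
    return fit_propensity_xy(cohort.X, cohort.T)


def fit_propensity_xy(X: np.ndarray, T: np.ndarray) -> PropensityFit:
    """Propensity fit from raw covariate matrix and treatment vector.

    Same contract as :func:`fit_propensity`; accepts any number of
    covariate columns (used by the applied-analysis path).
    """
    T = np.asarray(T, dtype=float)
    n_coef = np.asarray(X).shape[1] + 1
    if T.min() == T.max():
        return PropensityFit(
            ps=np.full_like(T, np.nan),
            logit_ps=np.full_like(T, np.nan),
            coefficients=np.full(n_coef, np.nan),
            converged=False,
            caliper_width=np.nan,
        )
    design = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    try:
        with warnings.catch_warnings():
            # non-convergence is reported through the flag, not a warning
            warnings.simplefilter("ignore")
            res = sm.Logit(T, design).fit(disp=0, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", False))
        coef = np.asarray(res.params, dtype=float)
    except Exception:
        converged = False
        coef = np.full(n_coef, np.nan)
    if not converged or not np.all(np.isfinite(coef)):
        return PropensityFit(
            ps=np.full_like(T, np.nan),
            logit_ps=np.full_like(T, np.nan),
            coefficients=coef,
            converged=False,
            caliper_width=np.nan,
        )
    logit_ps = design @ coef
    ps = 1.0 / (1.0 + np.exp(-logit_ps))
    return PropensityFit(
        ps=ps,
        logit_ps=logit_ps,
        coefficients=coef,
        converged=True,
        caliper_width=compute_caliper(logit_ps),
    )


def compute_caliper(logit_ps: np.ndarray, multiplier: float = CALIPER_MULTIPLIER) -> float:
    """Caliper width: ``multiplier`` times the sample SD (ddof=1) of the logit PS."""
    logit_ps = np.asarray(logit_ps, dtype=float)
    if logit_ps.size < 2:
        raise ValueError("need at least 2 units to compute a caliper")
    return float(multiplier * np.std(logit_ps, ddof=1))


def match(fit: PropensityFit, t: np.ndarray, options: MatchOptions) -> MatchedSample:
    """Greedy nearest-neighbour caliper matching on the logit propensity score.

    Treated units are visited in a random order drawn from
    ``options.order_seed``.  Each treated unit takes its K nearest distinct
    in-caliper controls by absolute logit-PS difference (ties broken by lower
    control index); without replacement those controls leave the pool.  A
    treated unit with fewer than K admissible controls is discarded under the
    strict policy, or keeps the admissible ones under the partial policy
    (see :class:`MatchOptions`).
    """
    t = np.asarray(t).astype(bool)
    treated_idx = np.flatnonzero(t)
    control_idx = np.flatnonzero(~t)
    caliper = fit.caliper_width
    if treated_idx.size == 0 or control_idx.size == 0:
        return MatchedSample(
            sets=[],
            usage_count={},
            n_treated_total=int(treated_idx.size),
            n_treated_matched=0,
            discarded_treated=list(map(int, treated_idx)),
            options=options,
            caliper_width=caliper,
        )
    if not fit.converged or not np.isfinite(caliper) or caliper <= 0:
        raise ValueError("matching requires a converged fit with a positive caliper")

    lp = np.asarray(fit.logit_ps, dtype=float)
    # controls sorted by logit PS (ties by index) for windowed candidate lookup
    order = np.lexsort((control_idx, lp[control_idx]))
    c_sorted = control_idx[order]
    c_lp = lp[c_sorted]
    available = np.ones(c_sorted.size, dtype=bool)

    rng = np.random.default_rng(options.order_seed)
    processing_order = rng.permutation(treated_idx.size)

    lp_treated = lp[treated_idx]
    lo_all = np.searchsorted(c_lp, lp_treated - caliper, side="left")
    hi_all = np.searchsorted(c_lp, lp_treated + caliper, side="right")

    K = options.ratio_K
    sets: list[MatchedSet] = []
    usage: dict[int, int] = {}
    discarded: list[int] = []
    for pos in processing_order:
        ti = int(treated_idx[pos])
        lp_t = lp_treated[pos]
        window = np.arange(lo_all[pos], hi_all[pos])
        if not options.with_replacement:
            window = window[available[window]]
        if window.size < K and not (options.partial_sets and window.size > 0):
            discarded.append(ti)
            continue
        cand = c_sorted[window]
        dist = np.abs(c_lp[window] - lp_t)
        pick = np.lexsort((cand, dist))[:K]
        chosen = cand[pick]
        sets.append(MatchedSet(treated_index=ti, control_indices=tuple(map(int, chosen))))
        for c in chosen:
            usage[int(c)] = usage.get(int(c), 0) + 1
        if not options.with_replacement:
            available[window[pick]] = False
    sets.sort(key=lambda s: s.treated_index)
    return MatchedSample(
        sets=sets,
        usage_count=usage,
        n_treated_total=int(treated_idx.size),
        n_treated_matched=len(sets),
        discarded_treated=sorted(discarded),
        options=options,
        caliper_width=caliper,
        n_treated_full=sum(1 for s in sets if s.m == K),
    )


def match_with_replacement_family(
    fit: PropensityFit,
    t: np.ndarray,
    ratios: list[int],
    order_seed: int = 0,
    partial_sets: bool = False,
) -> dict[int, "MatchedSample"]:
    """All with-replacement matched samples for several ratios in one pass.

    With replacement the pool never shrinks, so each treated unit's ordered
    in-caliper candidate list is computed once; the K-ratio sample takes its
    first K entries.  Produces exactly what :func:`match` would for each
    ratio under the requested partial-set policy — the greedy processing
    order is irrelevant with replacement.
    """
    kmax = max(ratios)
    base = match(
        fit,
        t,
        MatchOptions(
            with_replacement=True, ratio_K=kmax, order_seed=order_seed, partial_sets=True
        ),
    )
    out: dict[int, MatchedSample] = {}
    for K in ratios:
        sets, usage, discarded = [], {}, list(base.discarded_treated)
        for s in base.sets:
            if s.m < K and not partial_sets:
                discarded.append(s.treated_index)
                continue
            chosen = s.control_indices[:K]
            sets.append(MatchedSet(treated_index=s.treated_index, control_indices=chosen))
            for c in chosen:
                usage[c] = usage.get(c, 0) + 1
        out[K] = MatchedSample(
            sets=sets,
            usage_count=usage,
            n_treated_total=base.n_treated_total,
            n_treated_matched=len(sets),
            discarded_treated=sorted(discarded),
            options=MatchOptions(
                with_replacement=True,
                ratio_K=K,
                order_seed=order_seed,
                partial_sets=partial_sets,
            ),
            caliper_width=base.caliper_width,
            n_treated_full=sum(1 for s in sets if s.m >= K),
        )
    return out


def proportion_matched_treated(sample: MatchedSample) -> float:
    """PMT: fraction of treated units that received the full prespecified K.

    Under the strict discard policy every retained set is full, so this is
    simply the fraction of treated units retained in the matched sample;
    under the partial policy treated units with partial sets stay in the
    sample but do not count toward the PMT.
    """
    if sample.n_treated_total == 0:
        raise ValueError("PMT undefined with no treated units")
    return sample.n_treated_full / sample.n_treated_total


def proportion_resampled_controls(sample: MatchedSample) -> float:
    """PRC: among distinct matched controls, the fraction used in two or more sets.

    Returns NaN when no control was matched.
    """
    if not sample.usage_count:
        return float("nan")
    counts = np.array(list(sample.usage_count.values()))
    return float((counts >= 2).mean())
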