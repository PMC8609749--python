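"""Simulation engine: scenario/strategy grids, replications, ADEMP aggregation.

The study is a full factorial of assignment strength (weak/strong), treated
proportion (0.3/0.5/0.7) and sample size (100/250/500/1000) — 24 scenarios
per outcome family — crossed with 10 matching strategies ({with, without
replacement} x ratio 1..5).  Each replication draws one cohort, fits a single
propensity model shared by all strategies, and produces one record per
strategy.  Performance per cell is summarized as relative bias, RMSE and
nominal coverage of both CI methods, plus mean balance diagnostics.

Seeding is hierarchical (study seed -> scenario code -> replication index ->
strategy), so any single replication is reproducible in isolation and results
do not depend on the number of parallel workers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import balance as bal
from .estimation import estimate_all, nearest_same_group
from .matching import (
    MatchOptions,
    fit_propensity,
    fit_propensity_xy,
    match,
    match_with_replacement_family,
    proportion_matched_treated,
    proportion_resampled_controls,
)
from .synthetic import (
    ScenarioConfig,
    calibrate_parameters,
    generate_cohort,
    load_calibration,
    save_calibration,
)

__all__ = [
    "StrategySpec",
    "scenario_grid",
    "strategy_grid",
    "calibrate_grid",
    "run_replication",
    "summarize_performance",
    "run_study",
    "applied_analysis",
]

logger = logging.getLogger("psmsim")

_STRENGTH_CODE = {"weak": 0, "strong": 1}
_PROP_CODE = {0.3: 0, 0.5: 1, 0.7: 2}
_SIZE_CODE = {100: 0, 250: 1, 500: 2, 1000: 3}
_FAMILY_CODE = {"logistic": 0, "linear_probability": 1}

RECORD_COLUMNS = [
    "scenario_id",
    "strategy_id",
    "replication",
    "seed",
    "att_hat",
    "se_standard",
    "se_ai",
    "cover_standard",
    "cover_ai",
    "asmd",
    "one_minus_ovl",
    "pmt",
    "prc",
    "valid",
    "failure_reason",
]


@dataclass(frozen=True)
class StrategySpec:
    """One matching strategy of the 10-cell grid."""

    with_replacement: bool
    ratio_K: int

    @property
    def strategy_id(self) -> str:
        return f"{'wr' if self.with_replacement else 'nr'}_K{self.ratio_K}"


def scenario_grid(outcome_family: str = "logistic") -> list[ScenarioConfig]:
    """Full factorial of strength x treated proportion x sample size (24 cells)."""
    return [
        ScenarioConfig(
            assignment_strength=s,
            treated_proportion_target=p,
            sample_size=n,
            outcome_family=outcome_family,
        )
        for s in ("weak", "strong")
        for p in (0.3, 0.5, 0.7)
        for n in (100, 250, 500, 1000)
    ]


def strategy_grid() -> list[StrategySpec]:
    """All 10 strategies: {without, with} replacement x K in 1..5."""
    return [
        StrategySpec(with_replacement=wr, ratio_K=k)
        for wr in (False, True)
        for k in (1, 2, 3, 4, 5)
    ]


def scenario_code(config: ScenarioConfig) -> int:
    """Stable small integer identifying a scenario, used in seed derivation."""
    return (
        _FAMILY_CODE[config.outcome_family] * 1000
        + _STRENGTH_CODE[config.assignment_strength] * 100
        + _PROP_CODE[config.treated_proportion_target] * 10
        + _SIZE_CODE[config.sample_size]
    )


def calibrate_grid(
    configs: list[ScenarioConfig],
    n_cal: int = 1_000_000,
    cache_path: str | Path | None = None,
) -> list[ScenarioConfig]:
    """Calibrate every scenario, reusing coefficients across sample sizes.

    Calibrated coefficients depend only on (family, strength, treated
    proportion), so each unique combination is calibrated once.  If
    ``cache_path`` exists it is loaded instead; otherwise results are
    written there.
    """
    if cache_path is not None and Path(cache_path).exists():
        return load_calibration(cache_path, configs)
    cache: dict[tuple, ScenarioConfig] = {}
    out = []
    for cfg in configs:
        key = (cfg.outcome_family, cfg.assignment_strength, cfg.treated_proportion_target)
        if key not in cache:
            logger.info("calibrating %s", cfg.scenario_id)
            cache[key] = calibrate_parameters(cfg, n_cal=n_cal)
        ref = cache[key]
        out.append(
            calibrated_copy(cfg, ref)
        )
    if cache_path is not None:
        save_calibration(out, cache_path)
    return out


def calibrated_copy(cfg: ScenarioConfig, ref: ScenarioConfig) -> ScenarioConfig:
    """Copy calibrated coefficients from ``ref`` onto ``cfg`` (same DGP cell)."""
    import dataclasses

    return dataclasses.replace(
        cfg,
        beta0=ref.beta0,
        gamma0=ref.gamma0,
        gamma_T=ref.gamma_T,
        att_true=ref.att_true,
        clamp_fraction=ref.clamp_fraction,
    )


def _invalid_records(
    config: ScenarioConfig,
    strategies: list[StrategySpec],
    rep_index: int,
    seed_repr: int,
    reason: str,
) -> list[dict]:
    base = dict(
        scenario_id=config.scenario_id,
        replication=rep_index,
        seed=seed_repr,
        att_hat=np.nan,
        se_standard=np.nan,
        se_ai=np.nan,
        cover_standard=np.nan,
        cover_ai=np.nan,
        asmd=np.nan,
        one_minus_ovl=np.nan,
        pmt=np.nan,
        prc=np.nan,
        valid=False,
        failure_reason=reason,
    )
    return [dict(base, strategy_id=s.strategy_id) for s in strategies]


def run_replication(
    config: ScenarioConfig,
    strategies: list[StrategySpec],
    rep_index: int,
    base_seed: int,
    compute_balance: bool = True,
) -> list[dict]:
    """Run all strategies on one simulated cohort; one record per strategy.

    A single propensity fit is shared by all strategies.  Propensity
    non-convergence or fewer than two matched sets mark the affected records
    invalid with a reason instead of raising.
    """
    config.require_calibrated()
    code = scenario_code(config)
    ss = np.random.SeedSequence([base_seed, code, rep_index])
    seed_repr = int(ss.generate_state(1)[0] % (2**31))
    cohort = generate_cohort(config, ss)

    fit = fit_propensity(cohort)
    if not fit.converged:
        return _invalid_records(config, strategies, rep_index, seed_repr, "ps_not_converged")
    if not np.isfinite(fit.caliper_width) or fit.caliper_width <= 0:
        return _invalid_records(config, strategies, rep_index, seed_repr, "degenerate_caliper")

    t_bool = cohort.T.astype(bool)
    control_idx = np.flatnonzero(~t_bool)
    nn_map = (
        nearest_same_group(control_idx, fit.logit_ps) if control_idx.size >= 2 else None
    )
    if compute_balance:
        reference_sds = np.array(
            [bal.pooled_reference_sd(cohort.X[:, j], t_bool) for j in range(cohort.X.shape[1])]
        )

    # with replacement the greedy order is irrelevant and the candidate lists
    # are shared across ratios, so those samples are built in one pass; the
    # study pipeline keeps partial sets (see MatchOptions)
    wr_ratios = [s.ratio_K for s in strategies if s.with_replacement]
    wr_samples = (
        match_with_replacement_family(
            fit, cohort.T, wr_ratios, order_seed=0, partial_sets=True
        )
        if wr_ratios
        else {}
    )

    records = []
    for s_index, strat in enumerate(strategies):
        if strat.with_replacement:
            sample = wr_samples[strat.ratio_K]
        else:
            order_seed = int(
                np.random.SeedSequence(
                    [base_seed, code, rep_index, s_index]
                ).generate_state(1)[0]
            )
            opts = MatchOptions(
                with_replacement=False,
                ratio_K=strat.ratio_K,
                order_seed=order_seed,
                partial_sets=True,
            )
            sample = match(fit, cohort.T, opts)
        rec = dict(
            scenario_id=config.scenario_id,
            strategy_id=strat.strategy_id,
            replication=rep_index,
            seed=seed_repr,
            att_hat=np.nan,
            se_standard=np.nan,
            se_ai=np.nan,
            cover_standard=np.nan,
            cover_ai=np.nan,
            asmd=np.nan,
            one_minus_ovl=np.nan,
            pmt=proportion_matched_treated(sample) if sample.n_treated_total else np.nan,
            prc=proportion_resampled_controls(sample),
            valid=False,
            failure_reason="",
        )
        if sample.n_sets < 2:
            rec["failure_reason"] = "too_few_sets"
            records.append(rec)
            continue
        est = estimate_all(sample, cohort.Y, fit.logit_ps, nn_map=nn_map)
        rec["att_hat"] = est.att
        rec["se_standard"] = est.se_standard
        rec["cover_standard"] = bool(
            est.ci_standard[0] <= config.att_true <= est.ci_standard[1]
        )
        if est.se_ai is not None:
            rec["se_ai"] = est.se_ai
            rec["cover_ai"] = bool(est.ci_ai[0] <= config.att_true <= est.ci_ai[1])
        if compute_balance:
            weights = sample.unit_weights(cohort.n, t_bool)
            report = bal.balance_report(cohort.X, t_bool, fit.ps, weights, reference_sds)
            rec["asmd"] = report.asmd
            rec["one_minus_ovl"] = report.one_minus_ovl
        rec["valid"] = True
        records.append(rec)
    return records


def summarize_performance(
    records: pd.DataFrame, att_true: float | dict[str, float]
) -> pd.DataFrame:
    """ADEMP performance summary per scenario x strategy cell.

    ``relative_bias = |mean(att_hat) - att_true| / att_true * 100``;
    ``rmse = sqrt(var(att_hat) + bias^2)`` with population variance over the
    valid replications; nominal coverage is the fraction of valid
    replications whose CI covers the oracle ATT.  Invalid records are
    excluded from the statistics but counted in ``n_total``.
    """
    records = pd.DataFrame(records)
    if isinstance(att_true, dict):
        truth = records["scenario_id"].map(att_true)
    else:
        truth = pd.Series(att_true, index=records.index)
    records = records.assign(_att_true=truth)

    rows = []
    for (scen, strat), g in records.groupby(["scenario_id", "strategy_id"], sort=True):
        valid = g[g["valid"].astype(bool)]
        n_valid, n_total = len(valid), len(g)
        row = dict(
            scenario_id=scen,
            strategy_id=strat,
            relative_bias=np.nan,
            rmse=np.nan,
            nc_standard=np.nan,
            nc_ai=np.nan,
            mean_asmd=np.nan,
            mean_one_minus_ovl=np.nan,
            mean_pmt=np.nan,
            mean_prc=np.nan,
            att_true=float(g["_att_true"].iloc[0]),
            n_valid=n_valid,
            n_total=n_total,
        )
        if n_valid > 0:
            att_hat = valid["att_hat"].to_numpy(dtype=float)
            truth_val = float(valid["_att_true"].iloc[0])
            bias = att_hat.mean() - truth_val
            row["relative_bias"] = abs(bias / truth_val) * 100.0
            row["rmse"] = float(np.sqrt(att_hat.var() + bias**2))
            row["nc_standard"] = float(valid["cover_standard"].mean())
            ai = valid["cover_ai"].dropna()
            row["nc_ai"] = float(ai.mean()) if len(ai) else np.nan
            for col in ("asmd", "one_minus_ovl", "pmt", "prc"):
                vals = valid[col].dropna()
                row[f"mean_{col}"] = float(vals.mean()) if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(
    out_dir: str | Path,
    outcome_family: str = "logistic",
    scenarios: list[ScenarioConfig] | None = None,
    strategies: list[StrategySpec] | None = None,
    replications: int = 10_000,
    seed: int = 0,
    workers: int = 1,
    n_cal: int = 1_000_000,
    compute_balance: bool = True,
    calibration_cache: str | Path | None = None,
) -> dict[str, Path]:
    """Run the full simulation study and write tidy output tables.

    Writes ``replications.csv`` (one row per scenario x strategy x
    replication), ``summary.csv`` (performance per cell), ``calibration.csv``
    (coefficients) and ``manifest.json`` (seeds and settings) into
    ``out_dir``.  Results are independent of ``workers``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if scenarios is None:
        scenarios = scenario_grid(outcome_family)
    if strategies is None:
        strategies = strategy_grid()
    scenarios = calibrate_grid(scenarios, n_cal=n_cal, cache_path=calibration_cache)

    all_records: list[dict] = []
    for cfg in scenarios:
        logger.info("simulating %s (%d replications)", cfg.scenario_id, replications)
        if workers == 1:
            chunks = [
                run_replication(cfg, strategies, r, seed, compute_balance)
                for r in range(replications)
            ]
        else:
            chunks = Parallel(n_jobs=workers)(
                delayed(run_replication)(cfg, strategies, r, seed, compute_balance)
                for r in range(replications)
            )
        for chunk in chunks:
            all_records.extend(chunk)

    records = pd.DataFrame(all_records, columns=RECORD_COLUMNS)
    truth = {cfg.scenario_id: cfg.att_true for cfg in scenarios}
    summary = summarize_performance(records, truth)

    paths = {
        "replications": out_dir / "replications.csv",
        "summary": out_dir / "summary.csv",
        "calibration": out_dir / "calibration.csv",
        "manifest": out_dir / "manifest.json",
    }
    records.to_csv(paths["replications"], index=False)
    summary.to_csv(paths["summary"], index=False)
    save_calibration(scenarios, paths["calibration"])
    manifest = {
        "seed": seed,
        "replications": replications,
        "outcome_family": outcome_family,
        "n_cal": n_cal,
        "scenarios": [cfg.scenario_id for cfg in scenarios],
        "strategies": [s.strategy_id for s in strategies],
        "compute_balance": compute_balance,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths


def applied_analysis(
    data: pd.DataFrame,
    treatment: str,
    outcome: str,
    covariates: list[str],
    order_seed: int = 0,
) -> dict:
    """Analyse a user cohort with all 10 matching strategies.

    Complete-case analysis: rows with missing values in the used columns are
    dropped and counted.  Returns a dict with a balance table (ASMD /
    1-OVL / PMT / PRC per strategy), an estimates table (ATT with both 95%
    CIs per strategy) and the per-unit propensity scores by group.
    """
    cols = [treatment, outcome, *covariates]
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValueError(f"columns not found in data: {missing_cols}")
    complete = data[cols].dropna()
    n_dropped = len(data) - len(complete)
    T = complete[treatment].to_numpy()
    Y = complete[outcome].to_numpy()
    for name, v in ((treatment, T), (outcome, Y)):
        if not np.isin(np.unique(v), (0, 1)).all():
            raise ValueError(f"column {name!r} must be binary 0/1")
    if T.min() == T.max():
        raise ValueError("cohort needs both treated and control units")
    X = complete[covariates].to_numpy(dtype=float)

    fit = fit_propensity_xy(X, T)
    if not fit.converged:
        raise RuntimeError("propensity model did not converge on the supplied cohort")
    t_bool = T.astype(bool)
    reference_sds = np.array(
        [bal.pooled_reference_sd(X[:, j], t_bool) for j in range(X.shape[1])]
    )
    control_idx = np.flatnonzero(~t_bool)
    nn_map = nearest_same_group(control_idx, fit.logit_ps) if control_idx.size >= 2 else None

    balance_rows, estimate_rows = [], []
    for s_index, strat in enumerate(strategy_grid()):
        opts = MatchOptions(
            with_replacement=strat.with_replacement,
            ratio_K=strat.ratio_K,
            order_seed=order_seed + s_index,
            partial_sets=True,
        )
        sample = match(fit, T, opts)
        row = dict(
            strategy_id=strat.strategy_id,
            with_replacement=strat.with_replacement,
            ratio_K=strat.ratio_K,
            n_sets=sample.n_sets,
            pmt=proportion_matched_treated(sample),
            prc=0.0 if not strat.with_replacement else proportion_resampled_controls(sample),
        )
        if sample.n_sets >= 2:
            weights = sample.unit_weights(len(T), t_bool)
            report = bal.balance_report(X, t_bool, fit.ps, weights, reference_sds)
            row["asmd"] = report.asmd
            row["one_minus_ovl"] = report.one_minus_ovl
            est = estimate_all(sample, Y, fit.logit_ps, nn_map=nn_map)
            estimate_rows.append(
                dict(
                    strategy_id=strat.strategy_id,
                    with_replacement=strat.with_replacement,
                    ratio_K=strat.ratio_K,
                    att=est.att,
                    se_standard=est.se_standard,
                    ci_standard_low=est.ci_standard[0],
                    ci_standard_high=est.ci_standard[1],
                    se_ai=est.se_ai if est.se_ai is not None else np.nan,
                    ci_ai_low=est.ci_ai[0] if est.ci_ai else np.nan,
                    ci_ai_high=est.ci_ai[1] if est.ci_ai else np.nan,
                )
            )
        else:
            row["asmd"] = np.nan
            row["one_minus_ovl"] = np.nan
            estimate_rows.append(
                dict(
                    strategy_id=strat.strategy_id,
                    with_replacement=strat.with_replacement,
                    ratio_K=strat.ratio_K,
                    att=np.nan,
                    se_standard=np.nan,
                    ci_standard_low=np.nan,
                    ci_standard_high=np.nan,
                    se_ai=np.nan,
                    ci_ai_low=np.nan,
                    ci_ai_high=np.nan,
                )
            )
        balance_rows.append(row)

    propensity = pd.DataFrame(
        dict(
            group=np.where(t_bool, "treated", "control"),
            ps=fit.ps,
            logit_ps=fit.logit_ps,
        )
    )
    return dict(
        balance=pd.DataFrame(balance_rows),
        estimates=pd.DataFrame(estimate_rows),
        propensity=propensity,
        n_dropped=n_dropped,
    )
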