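"""Monte-Carlo evaluation of the correlation-estimation strategies.

``run_study`` simulates a scenario many times, applies the requested
strategies and scores each against its own target: the across-regions
strategies (1.1, 1.2) estimate the *conditional* correlation (the noise-level
association that survives averaging out participants), while the
across-participants strategies (2, 3) estimate the *marginal* correlation.
Reported metrics per (scenario, strategy, n): mean estimate, relative bias in
percent, 95%-CI coverage and rejection rate at p < 0.05 — type-1 error when
the target is zero, power otherwise — each with a Monte-Carlo standard error.

``subsample_stability`` resamples an observed cohort at sizes k to show how
the single-cohort (1.1) and split-cohort (1.2) across-regions estimates
behave as the cohort shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datagen import GenerativeSpec, RegionalTable, simulate_dataset
from .mixedmodel import fit_mixed_model
from .strategies import (
    CorrelationEstimate,
    across_regions_from_cohorts,
    aggregate_regional,
    strategy_across_regions,
    strategy_per_region,
)

__all__ = [
    "STRATEGIES",
    "SimulationSummary",
    "SubsampleSummary",
    "truth_for_strategy",
    "run_replicate",
    "run_study",
    "subsample_stability",
]

STRATEGIES = ("1.1", "1.2", "2", "3")
_ACROSS_REGIONS = ("1.1", "1.2")


@dataclass(frozen=True)
class SimulationSummary:
    """One scenario x strategy x n cell of the simulation study."""

    scenario: str
    strategy: str
    n: int
    reps: int
    truth: float
    mean_estimate: float
    bias_pct: float | None          # 100*(mean_estimate - truth)/truth; None when truth == 0
    coverage: float
    rejection_rate: float           # type-1 error when truth == 0, power otherwise
    mean_ci_width: float
    mc_se_estimate: float
    mc_se_coverage: float
    mc_se_rejection: float
    n_excluded: int = 0             # non-converged mixed-model replicates


@dataclass(frozen=True)
class SubsampleSummary:
    """Quantiles of an across-regions estimate over resampled sub-cohorts."""

    k: int
    strategy: str
    reps: int
    median: float
    q05: float
    q95: float
    median_p: float
    q05_p: float
    q95_p: float


def truth_for_strategy(spec: GenerativeSpec, strategy: str) -> float:
    """Target correlation a strategy is scored against: conditional for the
    across-regions strategies, marginal for the across-participants ones."""
    if strategy in _ACROSS_REGIONS:
        return float(spec.conditional_correlation)
    if strategy in ("2", "3"):
        return float(spec.marginal_correlation)
    raise ValueError(f"unknown strategy {strategy!r}; known: {STRATEGIES}")


def run_replicate(spec: GenerativeSpec, n: int, seed,
                  strategies=STRATEGIES,
                  variance_structure: str = "by_modality",
                  ) -> dict[str, CorrelationEstimate | None]:
    """One simulation replicate.

    A single dataset serves strategies 1.1, 2 and 3; strategy 1.2 gets an
    independent second dataset (same n) and correlates the first dataset's
    first-modality mean map with the second dataset's second-modality map.
    A non-converged mixed-model fit yields ``None`` for strategy 3.
    """
    unknown = set(strategies) - set(STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies {sorted(unknown)}; known: {STRATEGIES}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_main, child_second = ss.spawn(2)
    data = simulate_dataset(spec, n, np.random.default_rng(child_main))
    out: dict[str, CorrelationEstimate | None] = {}
    if "1.1" in strategies:
        out["1.1"] = strategy_across_regions(data)
    if "1.2" in strategies:
        second = simulate_dataset(spec, n, np.random.default_rng(child_second))
        out["1.2"] = across_regions_from_cohorts(data, second)
    if "2" in strategies:
        out["2"] = aggregate_regional(strategy_per_region(data), data)
    if "3" in strategies:
        fit = fit_mixed_model(data, variance_structure=variance_structure)
        out["3"] = fit.marginal if fit.converged else None
    return out


def run_study(spec: GenerativeSpec, n: int, reps: int, master_seed,
              strategies=STRATEGIES,
              variance_structure: str = "by_modality",
              return_replicates: bool = False):
    """Simulate ``reps`` replicates and score every requested strategy.

    Replicate k runs on an independent substream spawned from ``master_seed``,
    so any replicate is reproducible in isolation and results do not depend on
    the strategy subset.  Returns a list of :class:`SimulationSummary`
    (and the replicate-level DataFrame when ``return_replicates``).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    master = (master_seed if isinstance(master_seed, np.random.SeedSequence)
              else np.random.SeedSequence(master_seed))
    rep_seeds = master.spawn(reps)
    records = []
    for k in range(reps):
        ests = run_replicate(spec, n, rep_seeds[k], strategies, variance_structure)
        for strat, est in ests.items():
            if est is None:
                records.append({"replicate": k, "strategy": strat, "estimate": np.nan,
                                "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                                "converged": False})
            else:
                records.append({"replicate": k, "strategy": strat,
                                "estimate": est.estimate, "ci_low": est.ci_low,
                                "ci_high": est.ci_high, "p": est.p_value,
                                "converged": True})
    df = pd.DataFrame.from_records(records)

    summaries = []
    for strat in [s for s in STRATEGIES if s in strategies]:
        sub = df[df["strategy"] == strat]
        ok = sub[sub["converged"]]
        m = len(ok)
        truth = truth_for_strategy(spec, strat)
        est = ok["estimate"].to_numpy()
        cover = ((ok["ci_low"] <= truth) & (truth <= ok["ci_high"])).to_numpy()
        reject = (ok["p"] < 0.05).to_numpy()
        width = (ok["ci_high"] - ok["ci_low"]).to_numpy()
        cov = float(cover.mean())
        rej = float(reject.mean())
        summaries.append(SimulationSummary(
            scenario=spec.label or "custom",
            strategy=strat,
            n=n,
            reps=m,
            truth=truth,
            mean_estimate=float(est.mean()),
            bias_pct=None if truth == 0 else float(100.0 * (est.mean() - truth) / truth),
            coverage=cov,
            rejection_rate=rej,
            mean_ci_width=float(width.mean()),
            mc_se_estimate=float(est.std(ddof=1) / np.sqrt(m)) if m > 1 else np.nan,
            mc_se_coverage=float(np.sqrt(cov * (1 - cov) / m)),
            mc_se_rejection=float(np.sqrt(rej * (1 - rej) / m)),
            n_excluded=len(sub) - m,
        ))
    if return_replicates:
        return summaries, df
    return summaries


def subsample_stability(data: RegionalTable, k_range, reps: int, master_seed,
                        strategies=("1.1", "1.2")) -> list[SubsampleSummary]:
    """Resampling experiment: how stable are the across-regions estimates as
    the cohort shrinks?

    For each k in ``k_range``: strategy 1.1 draws one k-participant subset
    (both modalities); strategy 1.2 draws two disjoint k-participant subsets,
    one per modality.  Reports 5%/50%/95% quantiles of the estimate and the
    p-value over ``reps`` resamples.
    """
    n = data.n_participants
    k_range = list(k_range)
    for k in k_range:
        if not 2 <= k <= n:
            raise ValueError(f"subsample size {k} outside [2, {n}]")
        if "1.2" in strategies and 2 * k > n:
            raise ValueError(f"strategy 1.2 needs 2k <= n, got k={k}, n={n}")
    master = (master_seed if isinstance(master_seed, np.random.SeedSequence)
              else np.random.SeedSequence(master_seed))
    rng = np.random.default_rng(master)
    out = []
    for k in k_range:
        by_strat = {s: {"est": [], "p": []} for s in strategies}
        for _ in range(reps):
            if "1.1" in strategies:
                idx = rng.choice(n, size=k, replace=False)
                est = strategy_across_regions(data.subset_participants(np.sort(idx)))
                by_strat["1.1"]["est"].append(est.estimate)
                by_strat["1.1"]["p"].append(est.p_value)
            if "1.2" in strategies:
                idx = rng.choice(n, size=2 * k, replace=False)
                a = data.subset_participants(np.sort(idx[:k])).subset_modality(data.modalities[0])
                b = data.subset_participants(np.sort(idx[k:])).subset_modality(data.modalities[1])
                est = across_regions_from_cohorts(a, b)
                by_strat["1.2"]["est"].append(est.estimate)
                by_strat["1.2"]["p"].append(est.p_value)
        for s in strategies:
            e = np.array(by_strat[s]["est"])
            p = np.array(by_strat[s]["p"])
            out.append(SubsampleSummary(
                k=k, strategy=s, reps=reps,
                median=float(np.median(e)),
                q05=float(np.quantile(e, 0.05)),
                q95=float(np.quantile(e, 0.95)),
                median_p=float(np.median(p)),
                q05_p=float(np.quantile(p, 0.05)),
                q95_p=float(np.quantile(p, 0.95)),
            ))
    return out
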