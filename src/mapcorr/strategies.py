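"""Correlation-estimation strategies for paired regional measurements.

Four strategies estimate the correlation between two modalities measured in R
regions of n participants:

* ``strategy_across_regions`` (1.1) — average each modality's map over
  participants and correlate the two mean maps across regions ("spatial"
  correlation; what studies with two independent cohorts compute).
* ``strategy_across_regions_split`` (1.2) — as 1.1, but each modality's mean
  map comes from a disjoint half of the cohort, mimicking truly separate
  cohorts.
* ``strategy_per_region`` (2) — one across-participants correlation per
  region; ``aggregate_regional`` averages them with inference that accounts
  for the between-region dependence of the regional estimates.
* strategy 3 (structured-covariance mixed model) lives in
  :mod:`mapcorr.mixedmodel`.

Pearson inference follows the standard implementation: a t test with n-2
degrees of freedom for the p-value and a Fisher-z interval with variance
1/(n-3) for the CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datagen import RegionalTable

__all__ = [
    "CorrelationEstimate",
    "pearson_inference",
    "strategy_across_regions",
    "across_regions_from_cohorts",
    "split_cohort",
    "strategy_across_regions_split",
    "strategy_per_region",
    "influence_values",
    "aggregate_regional",
]

Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class CorrelationEstimate:
    """Point estimate with 95% CI and two-sided p-value.

    ``n_units`` is the number of independent units the inference pretends it
    has: regions for the across-regions strategies, participants otherwise.
    """

    estimate: float
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    n_units: int
    method: str
    region: str | None = None

    @property
    def ci_width(self) -> float | None:
        if self.ci_low is None or self.ci_high is None:
            return None
        return self.ci_high - self.ci_low

    def covers(self, truth: float) -> bool | None:
        if self.ci_low is None or self.ci_high is None:
            return None
        return bool(self.ci_low <= truth <= self.ci_high)


def pearson_inference(x, y, method: str = "pearson",
                      region: str | None = None) -> CorrelationEstimate:
    """Pearson r with t-test p-value and Fisher-z 95% CI.

    p is two-sided from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 df; the CI is
    tanh(atanh(r) +/- z_{0.975}/sqrt(n-3)).  Requires n >= 4 and non-zero
    variance in both inputs.  A degenerate r of +/-1 reports p = 0 with the CI
    clamped to [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 paired observations for inference, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) >= 1.0 - 1e-12:
        r = float(np.sign(r))
        return CorrelationEstimate(r, min(r, -1.0 if r < 0 else r),
                                   max(r, 1.0 if r > 0 else r),
                                   0.0, n, method, region)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    half = Z975 / np.sqrt(n - 3)
    z = np.arctanh(r)
    return CorrelationEstimate(
        r, float(np.tanh(z - half)), float(np.tanh(z + half)),
        float(p), n, method, region,
    )


def strategy_across_regions(data: RegionalTable) -> CorrelationEstimate:
    """Strategy 1.1: correlate the two participant-averaged maps across regions."""
    if len(data.modalities) != 2:
        raise ValueError("across-regions strategy needs exactly two modalities")
    means = data.regional_means()
    est = pearson_inference(means[0], means[1], method="across_regions_single")
    return est


def across_regions_from_cohorts(cohort_a: RegionalTable,
                                cohort_b: RegionalTable) -> CorrelationEstimate:
    """Across-regions correlation with each modality's mean map from its own cohort.

    ``cohort_a`` supplies the first modality, ``cohort_b`` the second; the two
    tables must share the region set.
    """
    if cohort_a.regions != cohort_b.regions:
        raise ValueError("cohorts must share the same region set")
    a = cohort_a.values[:, 0, :].mean(axis=0)
    b = cohort_b.values[:, -1, :].mean(axis=0)
    return pearson_inference(a, b, method="across_regions_split")


def split_cohort(data: RegionalTable, seed) -> tuple[RegionalTable, RegionalTable]:
    """Random disjoint halves: the first floor(n/2) participants of a seeded
    permutation keep only the first modality, the rest only the second."""
    n = data.n_participants
    if n < 2:
        raise ValueError("need at least 2 participants to split")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = n // 2
    first = data.subset_participants(np.sort(perm[:half]))
    second = data.subset_participants(np.sort(perm[half:]))
    return (first.subset_modality(data.modalities[0]),
            second.subset_modality(data.modalities[1]))


def strategy_across_regions_split(data: RegionalTable, seed) -> CorrelationEstimate:
    """Strategy 1.2 on a single cohort: split in half, one modality per half."""
    cohort_a, cohort_b = split_cohort(data, seed)
    return across_regions_from_cohorts(cohort_a, cohort_b)


def strategy_per_region(data: RegionalTable) -> list[CorrelationEstimate]:
    """Strategy 2: across-participants Pearson correlation in each region."""
    if len(data.modalities) != 2:
        raise ValueError("per-region strategy needs exactly two modalities")
    out = []
    for j, region in enumerate(data.regions):
        out.append(pearson_inference(
            data.values[:, 0, j], data.values[:, 1, j],
            method="per_region", region=region,
        ))
    return out


def influence_values(x, y) -> np.ndarray:
    """Per-observation influence contributions for the Pearson estimate.

    With x, y standardized by their sample mean and sd, observation i
    contributes ``psi_i = x_i*y_i - (r/2)*(x_i^2 + y_i^2)``; the psi have
    exactly zero mean and ``var(psi)/n`` approximates ``var(r_hat)`` (equal to
    (1-r^2)^2/n for bivariate normal data).  Covariances of psi across two
    estimates computed on the same participants approximate the covariance of
    the estimates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 4:
        raise ValueError("x and y must be equal-length vectors with n >= 4")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("influence values undefined: zero variance in input")
    xt = (x - x.mean()) / sx
    yt = (y - y.mean()) / sy
    r = float(xt @ yt) / (x.size - 1)
    return xt * yt - 0.5 * r * (xt * xt + yt * yt)


def aggregate_regional(estimates: list[CorrelationEstimate],
                       data: RegionalTable) -> CorrelationEstimate:
    """Strategy-2 summary: mean of regional correlations with dependence-aware
    inference.

    The point estimate is the arithmetic mean of the regional r values.  For
    inference, the Fisher-z transforms of the regional estimates are treated
    as jointly normal with variance 1/(n-3) each and a correlation matrix
    estimated from the influence values (the regional estimates share
    participants, so they are far from independent).  The Wald test and CI are
    formed on the z scale; the CI is mapped back through tanh.
    """
    R = len(estimates)
    if R < 1:
        raise ValueError("need at least one regional estimate")
    ns = {e.n_units for e in estimates}
    if len(ns) != 1 or ns != {data.n_participants}:
        raise ValueError("regional estimates must come from the common cohort")
    n = data.n_participants
    rvals = np.array([e.estimate for e in estimates])
    point = float(rvals.mean())

    # correlation of the regional estimates via influence functions
    psi = np.column_stack([
        influence_values(data.values[:, 0, j], data.values[:, 1, j])
        for j in range(R)
    ])
    psi_corr = np.corrcoef(psi, rowvar=False) if R > 1 else np.ones((1, 1))
    cov_z = psi_corr / (n - 3)
    var_mean_z = float(cov_z.sum()) / R ** 2
    se = np.sqrt(var_mean_z)
    zbar = float(np.arctanh(rvals).mean())
    p = 2.0 * stats.norm.sf(abs(zbar) / se)
    return CorrelationEstimate(
        point,
        float(np.tanh(zbar - Z975 * se)),
        float(np.tanh(zbar + Z975 * se)),
        float(p), n, "regional_average",
    )
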