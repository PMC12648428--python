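"""Structured-covariance ("covariance pattern") mixed model for paired maps.

Each participant contributes a 2R-vector (R regions x 2 modalities) modelled
as multivariate normal with a mean per (region, modality), standard deviations
either per modality (``by_modality``) or per (region, modality)
(``by_region_modality``), and the four-parameter correlation structure of the
generator: within-modality exchangeable correlations, a cross-modality
same-region correlation (the marginal correlation of interest) and a
cross-modality different-region correlation.

Fitting is by maximum likelihood.  For a balanced design the ML means are the
sample mean vector whatever the covariance, so the likelihood is concentrated:
with S the (1/n-denominator) sample covariance,

    -2 log L / n = 2R log(2 pi) + log|Sigma| + tr(Sigma^{-1} S)

and only the covariance parameters are optimized — on the log scale for
standard deviations and the atanh scale for correlations, with non-positive-
definite proposals rejected by a penalty.  Wald inference for the marginal
correlation is read off the atanh-scale parameter; the conditional correlation
gets a delta-method interval, also built on the atanh scale so the CI stays
inside (-1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .datagen import RegionalTable
from .strategies import Z975, CorrelationEstimate

__all__ = ["MixedModelFit", "fit_mixed_model"]

_PENALTY = 1e10


@dataclass
class MixedModelFit:
    """ML parameter set with inference for the marginal/conditional correlations."""

    mean: np.ndarray                 # (2, R) fitted means
    sd: np.ndarray                   # (2,) or (2, R) fitted standard deviations
    rho_within: tuple[float, float]
    rho_cross_same: float
    rho_cross_diff: float
    log_likelihood: float
    vcov: np.ndarray                 # covariance of the transformed parameters
    marginal: CorrelationEstimate
    conditional: CorrelationEstimate
    converged: bool
    variance_structure: str
    n_participants: int

    @property
    def conditional_correlation(self) -> float:
        denom = np.sqrt((1 - self.rho_within[0]) * (1 - self.rho_within[1]))
        return (self.rho_cross_same - self.rho_cross_diff) / denom


def _theta_to_sigma(theta: np.ndarray, R: int, by_region: bool):
    """Unpack transformed parameters into (sd array, 4 correlations, Sigma)."""
    k = 2 * R if by_region else 2
    sd = np.exp(theta[:k])
    rw0, rw1, rcs, rcd = np.tanh(theta[k:])
    C = np.empty((2 * R, 2 * R))
    for m, rw in enumerate((rw0, rw1)):
        blk = np.full((R, R), rw)
        np.fill_diagonal(blk, 1.0)
        C[m * R:(m + 1) * R, m * R:(m + 1) * R] = blk
    cross = np.full((R, R), rcd) + (rcs - rcd) * np.eye(R)
    C[:R, R:] = cross
    C[R:, :R] = cross.T
    s = np.repeat(sd, R) if not by_region else sd
    return sd, (rw0, rw1, rcs, rcd), C * np.outer(s, s)


def _neg_loglik_factory(S: np.ndarray, n: int, R: int, by_region: bool):
    const = 2 * R * np.log(2 * np.pi)

    def nll(theta: np.ndarray) -> float:
        _, _, Sigma = _theta_to_sigma(theta, R, by_region)
        try:
            L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return _PENALTY + float(np.sum(theta ** 2))
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        tr = float(np.trace(np.linalg.solve(Sigma, S)))
        return 0.5 * n * (const + logdet + tr)

    return nll


def _moment_start(S: np.ndarray, R: int, by_region: bool) -> np.ndarray:
    d = np.sqrt(np.diag(S))
    Corr = S / np.outer(d, d)
    off = ~np.eye(R, dtype=bool)
    rw = [float(np.mean(Corr[m * R:(m + 1) * R, m * R:(m + 1) * R][off])) for m in (0, 1)]
    cross = Corr[:R, R:]
    rcs = float(np.mean(np.diag(cross)))
    rcd = float(np.mean(cross[off]))
    if by_region:
        sd = d
    else:
        sd = np.array([np.sqrt(np.mean(d[:R] ** 2)), np.sqrt(np.mean(d[R:] ** 2))])
    corrs = np.clip([rw[0], rw[1], rcs, rcd], -0.95, 0.95)
    return np.concatenate([np.log(sd), np.arctanh(corrs)])


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = x.size
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return H


def fit_mixed_model(data: RegionalTable,
                    variance_structure: str = "by_modality") -> MixedModelFit:
    """ML fit of the structured multivariate normal (strategy 3).

    ``variance_structure`` is ``"by_modality"`` (two sd parameters; the
    simulation-study default, cheap and robust) or ``"by_region_modality"``
    (one sd per region and modality).  Starts from moment estimates with a
    zero-correlation fallback start; reports ``converged=False`` instead of
    raising when the optimizer fails.
    """
    if variance_structure not in ("by_modality", "by_region_modality"):
        raise ValueError("variance_structure must be by_modality or by_region_modality")
    if len(data.modalities) != 2:
        raise ValueError("mixed model needs exactly two modalities")
    by_region = variance_structure == "by_region_modality"
    n, _, R = data.values.shape
    if n <= 4:
        raise ValueError("need more participants than correlation parameters")
    Y = data.values.reshape(n, 2 * R)
    ybar = Y.mean(axis=0)
    res = Y - ybar
    S = res.T @ res / n
    nll = _neg_loglik_factory(S, n, R, by_region)

    starts = [_moment_start(S, R, by_region)]
    null_start = starts[0].copy()
    null_start[-4:] = 0.0
    starts.append(null_start)

    best = None
    for x0 in starts:
        opt = optimize.minimize(nll, x0, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8})
        if best is None or opt.fun < best.fun:
            best = opt
    if not best.success:  # line-search failures: polish with a simplex pass
        polish = optimize.minimize(nll, best.x, method="Nelder-Mead",
                                   options={"maxiter": 5000, "fatol": 1e-10,
                                            "xatol": 1e-8})
        if polish.fun <= best.fun:
            best = polish
    theta = best.x
    converged = bool(best.success) and nll(theta) < _PENALTY / 2

    sd, (rw0, rw1, rcs, rcd), _ = _theta_to_sigma(theta, R, by_region)
    ll = -nll(theta)

    k = theta.size
    H = _numeric_hessian(nll, theta)
    try:
        vcov = np.linalg.inv(H)
        if np.any(np.diag(vcov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        vcov = np.full((k, k), np.nan)
        converged = False

    # marginal correlation: atanh-scale parameter is theta[-2]
    se_zcs = float(np.sqrt(vcov[-2, -2])) if np.isfinite(vcov[-2, -2]) else np.nan
    z_cs = theta[-2]
    if np.isfinite(se_zcs) and se_zcs > 0:
        marginal = CorrelationEstimate(
            float(rcs),
            float(np.tanh(z_cs - Z975 * se_zcs)),
            float(np.tanh(z_cs + Z975 * se_zcs)),
            float(2 * stats.norm.sf(abs(z_cs) / se_zcs)),
            n, "mixed_marginal",
        )
    else:
        marginal = CorrelationEstimate(float(rcs), None, None, None, n, "mixed_marginal")

    # conditional correlation: delta method on the atanh scale
    def cond_z(th):
        _, (a, b, c, d_), _ = _theta_to_sigma(th, R, by_region)
        val = (c - d_) / np.sqrt((1 - a) * (1 - b))
        return np.arctanh(np.clip(val, -1 + 1e-12, 1 - 1e-12))

    cond = float(np.tanh(cond_z(theta)))
    grad = optimize.approx_fprime(theta, cond_z, 1e-6)
    var_zc = float(grad @ vcov @ grad) if np.all(np.isfinite(vcov)) else np.nan
    if np.isfinite(var_zc) and var_zc > 0:
        se_zc = np.sqrt(var_zc)
        zc = cond_z(theta)
        conditional = CorrelationEstimate(
            cond,
            float(np.tanh(zc - Z975 * se_zc)),
            float(np.tanh(zc + Z975 * se_zc)),
            float(2 * stats.norm.sf(abs(zc) / se_zc)),
            n, "mixed_conditional",
        )
    else:
        conditional = CorrelationEstimate(cond, None, None, None, n, "mixed_conditional")

    return MixedModelFit(
        mean=ybar.reshape(2, R),
        sd=sd if not by_region else sd.reshape(2, R),
        rho_within=(float(rw0), float(rw1)),
        rho_cross_same=float(rcs),
        rho_cross_diff=float(rcd),
        log_likelihood=float(ll),
        vcov=vcov,
        marginal=marginal,
        conditional=conditional,
        converged=converged,
        variance_structure=variance_structure,
        n_participants=n,
    )
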