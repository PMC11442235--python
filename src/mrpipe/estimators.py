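"""Causal-effect estimators for harmonized instrument sets.

Implements the Wald ratio, fixed- and multiplicative-random-effects IVW,
Egger regression (slope + intercept pleiotropy test), the weighted median,
and the weighted mode, together with odds-scale conversion of any estimate.

Conventions
-----------
* IVW uses first-order weights ``w_j = beta_exp_j^2 / se_out_j^2``, which is
  identical to zero-intercept weighted least squares of ``beta_out`` on
  ``beta_exp`` with weights ``1 / se_out^2``.
* The multiplicative random-effects SE inflates the fixed-effect SE by
  ``sqrt(max(1, Q / (k - 1)))``.
* 95% intervals use the normal quantile 1.959964.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .harmonize import HarmonizedPair, InstrumentSet

Z95 = 1.959964


class InsufficientInstrumentsError(ValueError):
    """Raised when an estimator receives fewer SNPs than its minimum."""


class UndefinedRatioError(ZeroDivisionError):
    """Raised for a Wald ratio with a zero exposure effect."""


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log-odds (or SD) scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    or_: Optional[float] = None
    or_ci_low: Optional[float] = None
    or_ci_high: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_p: Optional[float] = None
    heterogeneity_q: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "method": self.method, "n_snps": self.n_snps, "beta": self.beta,
            "se": self.se, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pval": self.pval, "or": self.or_, "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high, "egger_intercept": self.egger_intercept,
            "egger_intercept_p": self.egger_intercept_p,
        }


def _finish(method: str, beta: float, se: float, n_snps: int, pval=None, **extra) -> MREstimate:
    if pval is None:
        pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    est = MREstimate(
        method=method, beta=beta, se=se,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        pval=float(pval), n_snps=n_snps, **extra,
    )
    return to_odds_scale(est)


def to_odds_scale(estimate: MREstimate) -> MREstimate:
    """Populate the odds-ratio fields by exponentiating beta and its CI."""
    return replace(
        estimate,
        or_=math.exp(estimate.beta),
        or_ci_low=math.exp(estimate.ci_low),
        or_ci_high=math.exp(estimate.ci_high),
    )


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-SNP causal estimate ``beta_out / beta_exp`` with first-order SE."""
    if pair.beta_exp == 0:
        raise UndefinedRatioError(f"{pair.snp_id}: exposure beta is zero")
    beta = pair.beta_out / pair.beta_exp
    se = abs(pair.se_out / pair.beta_exp)
    return _finish("wald", beta, se, 1)


def _ivw_weights(instruments: InstrumentSet):
    beta_exp, _, beta_out, se_out = instruments.arrays()
    if np.any(beta_exp == 0):
        raise UndefinedRatioError("zero exposure beta in instrument set")
    ratios = beta_out / beta_exp
    weights = beta_exp**2 / se_out**2
    return ratios, weights


def ivw(instruments: InstrumentSet, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted meta-analysis of per-SNP Wald ratios."""
    k = len(instruments)
    if k < 2:
        raise InsufficientInstrumentsError(f"IVW needs >= 2 SNPs, got {k}")
    ratios, weights = _ivw_weights(instruments)
    beta = float(np.sum(weights * ratios) / np.sum(weights))
    se_fe = float(1.0 / math.sqrt(np.sum(weights)))
    q = float(np.sum(weights * (ratios - beta) ** 2))
    se = se_fe
    method = "ivw_fe"
    if random_effects:
        se = se_fe * math.sqrt(max(1.0, q / (k - 1)))
        method = "ivw_mre"
    return _finish(method, beta, se, k, heterogeneity_q=q)


def egger(instruments: InstrumentSet) -> MREstimate:
    """MR-Egger regression: weighted fit with intercept after orienting all
    exposure effects non-negative; the intercept is the directional-pleiotropy
    test. SEs use the multiplicative random-effects inflation with a floor of
    1 and t-distribution p-values on k - 2 df.
    """
    k = len(instruments)
    if k < 3:
        raise InsufficientInstrumentsError(f"Egger needs >= 3 SNPs, got {k}")
    beta_exp, _, beta_out, se_out = instruments.arrays()
    sign = np.where(beta_exp < 0, -1.0, 1.0)
    x = beta_exp * sign
    y = beta_out * sign
    w = 1.0 / se_out**2

    design = np.column_stack([np.ones(k), x])
    xtwx = design.T @ (design * w[:, None])
    cov_unscaled = np.linalg.inv(xtwx)
    coef = cov_unscaled @ design.T @ (w * y)
    resid = y - design @ coef
    q = float(np.sum(w * resid**2))
    scale = max(1.0, q / (k - 2)) if k > 2 else 1.0
    se_coef = np.sqrt(np.diag(cov_unscaled) * scale)

    slope, slope_se = float(coef[1]), float(se_coef[1])
    intercept, intercept_se = float(coef[0]), float(se_coef[0])
    df = k - 2
    slope_p = 2.0 * stats.t.sf(abs(slope) / slope_se, df)
    intercept_p = 2.0 * stats.t.sf(abs(intercept) / intercept_se, df) if intercept_se > 0 else 1.0
    return _finish(
        "egger", slope, slope_se, k, pval=slope_p,
        egger_intercept=intercept, egger_intercept_se=intercept_se,
        egger_intercept_p=float(intercept_p), heterogeneity_q=q,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    cum = np.cumsum(weights[order]) / np.sum(weights)
    # first SNP whose cumulative weight passes 0.5; interpolate on an exact tie
    idx = int(np.searchsorted(cum, 0.5))
    if idx < r.size - 1 and math.isclose(cum[idx], 0.5, rel_tol=0, abs_tol=1e-12):
        return float(0.5 * (r[idx] + r[idx + 1]))
    return float(r[min(idx, r.size - 1)])


def _bootstrap_se(
    point_fn, instruments: InstrumentSet, n_boot: int, seed: int
) -> float:
    beta_exp, se_exp, beta_out, se_out = instruments.arrays()
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_boot)
    weights = beta_exp**2 / se_out**2
    for b in range(n_boot):
        bx = rng.normal(beta_exp, se_exp)
        by = rng.normal(beta_out, se_out)
        with np.errstate(divide="ignore", invalid="ignore"):
            estimates[b] = point_fn(by / bx, weights)
    return float(np.std(estimates, ddof=1))


def weighted_median(
    instruments: InstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of the per-SNP ratios (50% breakdown estimator).

    The SE comes from a parametric bootstrap resampling both betas from
    their sampling distributions with the original IVW weights.
    """
    k = len(instruments)
    if k < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 SNPs, got {k}")
    ratios, weights = _ivw_weights(instruments)
    beta = _weighted_median_point(ratios, weights)
    se = _bootstrap_se(_weighted_median_point, instruments, n_boot, seed)
    return _finish("weighted_median", beta, se, k)


def _mode_bandwidth(ratios: np.ndarray, weights: np.ndarray, factor: float) -> float:
    med = _weighted_median_point(ratios, weights)
    mad = _weighted_median_point(np.abs(ratios - med), weights)
    scale = 1.4826 * mad
    if scale <= 0:
        scale = np.std(ratios, ddof=1) if ratios.size > 1 else 1.0
    if scale <= 0:
        scale = 1.0
    return factor * 0.9 * scale * ratios.size ** (-1 / 5)


def _weighted_mode_point(
    ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float = 1.0
) -> float:
    h = _mode_bandwidth(ratios, weights, bandwidth_factor)
    w = weights / np.sum(weights)

    def density(x):
        z = (np.atleast_1d(x)[:, None] - ratios[None, :]) / h
        return np.exp(-0.5 * z * z) @ w  # unnormalized; argmax unaffected

    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    vals = density(grid)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    opt = minimize_scalar(lambda x: -density(x)[0], bounds=(lo, hi), method="bounded")
    return float(opt.x)


def weighted_mode(
    instruments: InstrumentSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode of the weighted normal-kernel density of the per-SNP ratios.

    Bandwidth is ``bandwidth_factor * 0.9 * (1.4826 * weighted MAD) *
    k^(-1/5)``; the SE is a parametric bootstrap as in the weighted median.
    """
    k = len(instruments)
    if k < 3:
        raise InsufficientInstrumentsError(f"weighted mode needs >= 3 SNPs, got {k}")
    ratios, weights = _ivw_weights(instruments)
    beta = _weighted_mode_point(ratios, weights, bandwidth_factor)
    se = _bootstrap_se(
        lambda r, w: _weighted_mode_point(r, w, bandwidth_factor),
        instruments, n_boot, seed,
    )
    return _finish("weighted_mode", beta, se, k)


ALL_METHODS = ("ivw", "egger", "weighted_median", "weighted_mode")


def estimate_all(
    instruments: InstrumentSet,
    methods=ALL_METHODS,
    n_boot: int = 1000,
    seed: int = 0,
    bandwidth_factor: float = 1.0,
) -> dict[str, MREstimate]:
    """Run the requested estimators, skipping any with too few instruments."""
    out: dict[str, MREstimate] = {}
    for method in methods:
        try:
            if method == "ivw":
                out[method] = ivw(instruments, random_effects=True)
            elif method == "ivw_fe":
                out[method] = ivw(instruments, random_effects=False)
            elif method == "egger":
                out[method] = egger(instruments)
            elif method == "weighted_median":
                out[method] = weighted_median(instruments, n_boot=n_boot, seed=seed)
            elif method == "weighted_mode":
                out[method] = weighted_mode(
                    instruments, bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed
                )
            else:
                raise ValueError(f"unknown method {method!r}")
        except InsufficientInstrumentsError:
            continue
    return out
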