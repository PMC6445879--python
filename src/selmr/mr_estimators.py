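"""Causal-effect estimators for two-sample Mendelian randomization.

Given instruments harmonized to a common effect allele, each estimator
combines per-variant Wald ratios (outcome effect over exposure effect) into a
single causal estimate on the log-odds scale:

* inverse-variance weighting (IVW), algebraically the slope of a no-intercept
  weighted regression of outcome on exposure effects with weights 1/se_out^2;
* MR-Egger, the same regression with a free intercept that absorbs average
  directional pleiotropy, at the price of needing the InSIDE assumption and
  more instruments;
* the weighted median, the interpolated 50th weighted percentile of the Wald
  ratios, consistent while less than half the total weight is invalid.

Random-effects handling follows mainstream two-sample MR practice: IVW and
Egger standard errors are inflated by a multiplicative overdispersion factor
floored at 1; an additive DerSimonian-Laird variant is selectable for IVW.
Confidence intervals use the 1.96 normal multiplier throughout so intervals
stay symmetric and comparable across methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .summary_data import HarmonizedInstrument

Z_95 = 1.959963984540054  # standard-normal 97.5% point


class EstimatorError(ValueError):
    """An estimator precondition is violated."""


class UndefinedRatioError(EstimatorError):
    """Wald ratio undefined because the exposure effect is zero."""


@dataclass(frozen=True)
class WaldRatio:
    """Per-variant causal estimate with its inverse-variance weight."""

    rsid: str
    ratio: float
    se: float
    weight: float


@dataclass(frozen=True)
class MrEstimate:
    """One causal-effect estimate on the log-odds scale, with an OR view."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    residual_scale: float = 1.0
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None


def to_odds_ratio(estimate: MrEstimate) -> MrEstimate:
    """Populate the exponentiated (odds-ratio) view of a log-odds estimate."""
    return replace(
        estimate,
        odds_ratio=math.exp(estimate.beta),
        or_ci_low=math.exp(estimate.ci_low),
        or_ci_high=math.exp(estimate.ci_high),
    )


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope (causal) and intercept (average pleiotropy) estimates."""

    slope: MrEstimate
    intercept: MrEstimate

    @property
    def exponentiated_intercept(self) -> float:
        return math.exp(self.intercept.beta)

    @property
    def exponentiated_intercept_ci(self) -> tuple[float, float]:
        return math.exp(self.intercept.ci_low), math.exp(self.intercept.ci_high)


def wald_ratio(inst: HarmonizedInstrument, se_order: str = "first") -> WaldRatio:
    """Per-variant causal estimate beta_out / beta_exp.

    ``first`` uses the leading-order delta-method SE se_out/|beta_exp| (the
    convention behind IVW weights); ``second`` adds the exposure-uncertainty
    term.
    """
    if inst.beta_exp == 0:
        raise UndefinedRatioError(f"{inst.rsid}: exposure effect is zero, Wald ratio undefined")
    ratio = inst.beta_out / inst.beta_exp
    if se_order == "first":
        se = inst.se_out / abs(inst.beta_exp)
    elif se_order == "second":
        bx2 = inst.beta_exp * inst.beta_exp
        se = math.sqrt(
            inst.se_out**2 / bx2 + inst.beta_out**2 * inst.se_exp**2 / (bx2 * bx2)
        )
    else:
        raise EstimatorError(f"unknown se_order {se_order!r}")
    return WaldRatio(rsid=inst.rsid, ratio=ratio, se=se, weight=1.0 / (se * se))


def _normal_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _estimate(method: str, beta: float, se: float, pval: float, n_snps: int,
              residual_scale: float = 1.0) -> MrEstimate:
    return to_odds_ratio(MrEstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z_95 * se),
        ci_high=float(beta + Z_95 * se),
        pval=float(pval),
        n_snps=n_snps,
        residual_scale=float(residual_scale),
    ))


def cochran_q_components(ratios: Sequence[WaldRatio]) -> tuple[float, float]:
    """Fixed-effect pooled estimate and Cochran's Q of a set of Wald ratios."""
    w = np.array([r.weight for r in ratios])
    r = np.array([r.ratio for r in ratios])
    b = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - b) ** 2))
    return b, q


def ivw(
    instruments: Sequence[HarmonizedInstrument],
    effects_model: str = "multiplicative_re",
    se_order: str = "first",
) -> MrEstimate:
    """Inverse-variance-weighted pooling of per-variant Wald ratios.

    ``fixed`` is the classical meta-analysis; ``multiplicative_re`` keeps the
    same point estimate and inflates the SE by max(1, sqrt(Q/(L-1)));
    ``additive_dl`` re-weights with the DerSimonian-Laird tau^2.
    """
    if not instruments:
        raise EstimatorError("IVW needs at least one instrument")
    ratios = [wald_ratio(inst, se_order=se_order) for inst in instruments]
    L = len(ratios)
    if L < 2 and effects_model != "fixed":
        raise EstimatorError(f"{effects_model} IVW needs at least two instruments")
    w = np.array([r.weight for r in ratios])
    r = np.array([r.ratio for r in ratios])
    beta, q = cochran_q_components(ratios)
    se_fixed = float(1.0 / math.sqrt(np.sum(w)))

    if effects_model == "fixed":
        beta_hat, se, scale, method = beta, se_fixed, 1.0, "ivw_fe"
    elif effects_model == "multiplicative_re":
        scale = max(1.0, math.sqrt(q / (L - 1)))
        beta_hat, se, method = beta, se_fixed * scale, "ivw_mre"
    elif effects_model == "additive_dl":
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (L - 1)) / c) if c > 0 else 0.0
        w_star = 1.0 / (1.0 / w + tau2)
        beta_hat = float(np.sum(w_star * r) / np.sum(w_star))
        se = float(1.0 / math.sqrt(np.sum(w_star)))
        scale, method = 1.0, "ivw_dl"
    else:
        raise EstimatorError(f"unknown effects model {effects_model!r}")
    return _estimate(method, beta_hat, se, _normal_p(beta_hat, se), L, scale)


def _oriented_arrays(instruments: Sequence[HarmonizedInstrument]):
    """Exposure/outcome effects with every exposure effect made positive."""
    bx = np.array([i.beta_exp for i in instruments], dtype=float)
    by = np.array([i.beta_out for i in instruments], dtype=float)
    sy = np.array([i.se_out for i in instruments], dtype=float)
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign, sy


def mr_egger(
    instruments: Sequence[HarmonizedInstrument],
    pval_dist: str = "t",
) -> EggerResult:
    """Weighted regression of outcome on exposure effects with a free intercept.

    Instruments are internally oriented to positive exposure effects; weights
    are 1/se_out^2.  Standard errors carry a multiplicative overdispersion
    factor floored at 1 (random effects); slope/intercept p-values come from
    a t distribution with L-2 df (``t``) or the standard normal (``normal``).
    """
    if len(instruments) < 3:
        raise EstimatorError("MR-Egger needs at least three instruments")
    if pval_dist not in ("t", "normal"):
        raise EstimatorError(f"unknown pval_dist {pval_dist!r}")
    bx, by, sy = _oriented_arrays(instruments)
    if np.ptp(bx) == 0:
        raise EstimatorError("exposure effects are all equal: Egger design matrix is rank-deficient")
    w = 1.0 / (sy * sy)
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    L = len(instruments)
    phi = float(np.sum(w * resid**2) / (L - 2))
    scale = max(1.0, math.sqrt(phi))
    cov_unscaled = np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov_unscaled)) * scale

    def pv(b: float, s: float) -> float:
        if pval_dist == "t":
            return float(2.0 * stats.t.sf(abs(b) / s, df=L - 2))
        return _normal_p(b, s)

    intercept = _estimate("egger_intercept", coef[0], se[0], pv(coef[0], se[0]), L, scale)
    slope = _estimate("egger_slope", coef[1], se[1], pv(coef[1], se[1]), L, scale)
    return EggerResult(slope=slope, intercept=intercept)


def weighted_median_estimate(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50th weighted percentile of a set of ratio estimates.

    Ratios are sorted; cumulative weight fractions p_j = (cumsum(w) - w_j/2)
    / sum(w); the estimate is the ratio linearly interpolated at p = 0.5.
    """
    ratios = np.asarray(ratios, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    cum = np.cumsum(w)
    p = (cum - 0.5 * w) / cum[-1]
    return float(np.interp(0.5, p, r))


def _weighted_median_rows(samples: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted-median interpolation for a bootstrap sample matrix."""
    order = np.argsort(samples, axis=1)
    r = np.take_along_axis(samples, order, axis=1)
    w = weights[order]
    cum = np.cumsum(w, axis=1)
    p = (cum - 0.5 * w) / cum[:, -1:]
    n_rows, L = samples.shape
    k = np.sum(p < 0.5, axis=1)  # first index with p >= 0.5
    k = np.clip(k, 0, L - 1)
    rows = np.arange(n_rows)
    lo = np.clip(k - 1, 0, L - 1)
    p_lo, p_hi = p[rows, lo], p[rows, k]
    r_lo, r_hi = r[rows, lo], r[rows, k]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(p_hi > p_lo, (0.5 - p_lo) / (p_hi - p_lo), 0.0)
    est = r_lo + frac * (r_hi - r_lo)
    return np.where(k == 0, r[:, 0], est)


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
    se_order: str = "first",
) -> MrEstimate:
    """Weighted-median causal estimate with a parametric-bootstrap SE.

    Each bootstrap replicate redraws every Wald ratio from Normal(ratio, se)
    and recomputes the weighted median with the original inverse-variance
    weights; the SE is the standard deviation over ``n_boot`` replicates.
    """
    if n_boot < 1:
        raise EstimatorError("n_boot must be a positive integer")
    if len(instruments) < 3:
        raise EstimatorError("weighted median needs at least three instruments")
    ratios = [wald_ratio(inst, se_order=se_order) for inst in instruments]
    r = np.array([x.ratio for x in ratios])
    s = np.array([x.se for x in ratios])
    w = np.array([x.weight for x in ratios])
    beta = weighted_median_estimate(r, w)
    rng = np.random.default_rng(seed)
    samples = rng.normal(loc=r, scale=s, size=(n_boot, len(r)))
    boot = _weighted_median_rows(samples, w)
    se = float(np.std(boot, ddof=1))
    return _estimate("weighted_median", beta, se, _normal_p(beta, se), len(r))
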