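"""Causal-effect estimators for harmonized two-sample MR instruments.

All estimators combine per-SNP Wald ratios theta_j = beta_out_j / beta_exp_j
with inverse-variance weights w_j = beta_exp_j^2 / se_out_j^2 (the
first-order variance of a Wald ratio):

* IVW — the precision-weighted mean of the ratios, identical to weighted
  least squares of the outcome effects on the exposure effects through the
  origin. The default multiplicative random-effects model inflates the
  fixed-effect SE by sqrt(max(1, Q/(J-1))) with Q Cochran's heterogeneity
  statistic.
* MR-Egger — the same regression with a free intercept; the slope is the
  causal estimate and a non-zero intercept measures directional
  horizontal pleiotropy. Instruments are oriented so every exposure
  effect is non-negative before fitting.
* Weighted median — the weighted 50th percentile of the ratio
  distribution, consistent when at least half the weight lies on valid
  instruments; its SE comes from a seeded parametric bootstrap.

Estimates are reported on the ln(OR) scale together with the odds ratio
exp(beta) and a 95% Wald confidence interval exp(beta -/+ 1.96 se).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import DomainError, InsufficientInstrumentsError, ZeroInstrumentError
from .instruments import HarmonizedInstrument

CI_Z = 1.96  # 95% Wald interval multiplier


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate, on both the ln(OR) and OR scales."""

    method: str  # wald | ivw | egger | weighted_median
    beta: float
    se: float
    pvalue: float
    n_snp: int
    or_: float
    ci_low: float
    ci_high: float
    model_detail: dict = field(default_factory=dict)


@dataclass(frozen=True)
class InterceptRecord:
    """MR-Egger intercept: the average directional pleiotropy estimate."""

    estimate: float
    se: float
    pvalue: float
    df: int


def to_or_scale(beta: float, se: float) -> tuple[float, float, float]:
    """Odds ratio and 95% CI bounds from a ln(OR)-scale estimate."""
    if se <= 0:
        raise DomainError("standard error must be positive")
    return math.exp(beta), math.exp(beta - CI_Z * se), math.exp(beta + CI_Z * se)


def _estimate(method: str, beta: float, se: float, pvalue: float, n_snp: int, **detail) -> MREstimate:
    or_, lo, hi = to_or_scale(beta, se)
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        pvalue=float(pvalue),
        n_snp=n_snp,
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        model_detail=detail,
    )


def _arrays(instruments: Sequence[HarmonizedInstrument]) -> tuple[np.ndarray, ...]:
    bx = np.array([i.beta_exp for i in instruments], dtype=float)
    sx = np.array([i.se_exp for i in instruments], dtype=float)
    by = np.array([i.beta_out for i in instruments], dtype=float)
    sy = np.array([i.se_out for i in instruments], dtype=float)
    return bx, sx, by, sy


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-SNP causal estimate beta_out/beta_exp with first-order SE."""
    if inst.beta_exp == 0:
        raise DomainError(f"{inst.snp_id}: zero exposure effect, Wald ratio undefined")
    beta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    p = 2 * stats.norm.sf(abs(beta / se))
    return _estimate("wald", beta, se, p, 1, snp_id=inst.snp_id)


def ivw(
    instruments: Sequence[HarmonizedInstrument],
    effects_model: str = "multiplicative_random",
) -> MREstimate:
    """Inverse-variance-weighted estimate; the primary MR method.

    ``effects_model`` is ``"fixed"`` or ``"multiplicative_random"`` (the
    default): random effects multiply the fixed SE by
    sqrt(max(1, Q/(J-1))), leaving the point estimate unchanged.
    """
    if len(instruments) == 0:
        raise ZeroInstrumentError("IVW requires at least one instrument")
    if effects_model not in ("fixed", "multiplicative_random"):
        raise DomainError(f"unknown effects model {effects_model!r}")
    bx, _, by, sy = _arrays(instruments)
    theta = by / bx
    w = bx**2 / sy**2
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w)) ** -0.5
    q = float(np.sum(w * (theta - beta) ** 2))
    j = len(instruments)
    scale = 1.0
    if effects_model == "multiplicative_random" and j > 1:
        scale = math.sqrt(max(1.0, q / (j - 1)))
    se = se_fixed * scale
    p = 2 * stats.norm.sf(abs(beta / se))
    return _estimate(
        "ivw", beta, se, p, j, effects_model=effects_model, cochran_q=q, se_scale=scale
    )


def _oriented(bx: np.ndarray, by: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip instruments so every exposure effect is non-negative."""
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign


def egger(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[MREstimate, InterceptRecord]:
    """MR-Egger regression: slope (causal effect) and intercept (pleiotropy).

    Weighted least squares of oriented outcome effects on oriented
    exposure effects with weights 1/se_out^2 and a free intercept, solved
    in closed form. SEs carry a multiplicative random-effects floor
    max(1, sqrt(RSS_w/(J-2))); p-values use the t distribution with J-2
    degrees of freedom.
    """
    j = len(instruments)
    if j < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires >= 3 instruments, got {j}")
    bx, _, by, sy = _arrays(instruments)
    x, y = _oriented(bx, by)
    w = 1.0 / sy**2

    sw = w.sum()
    sx = (w * x).sum()
    sy_ = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    denom = sw * sxx - sx**2
    if denom <= 0:
        raise DomainError("degenerate design: exposure effects have no weighted spread")
    slope = (sw * sxy - sx * sy_) / denom
    intercept = (sy_ - slope * sx) / sw

    resid = y - intercept - slope * x
    rss_w = float((w * resid**2).sum())
    sigma = math.sqrt(rss_w / (j - 2))
    scale = max(1.0, sigma)
    se_slope = math.sqrt(sw / denom) * scale
    se_intercept = math.sqrt(sxx / denom) * scale

    df = j - 2
    p_slope = 2 * stats.t.sf(abs(slope / se_slope), df)
    p_intercept = 2 * stats.t.sf(abs(intercept / se_intercept), df)
    est = _estimate(
        "egger",
        float(slope),
        float(se_slope),
        p_slope,
        j,
        intercept=float(intercept),
        intercept_se=float(se_intercept),
        intercept_p=float(p_intercept),
        se_scale=scale,
    )
    rec = InterceptRecord(float(intercept), float(se_intercept), float(p_intercept), df)
    return est, rec


def weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    """Weighted 50th percentile with linear interpolation.

    Ratios are sorted; the cumulative weight percentile of the j-th order
    statistic is (sum of weights up to j) minus half its own weight, and
    the estimate interpolates the sorted ratios at percentile 0.5.
    """
    order = np.argsort(theta)
    t = theta[order]
    wn = w[order] / w.sum()
    s = np.cumsum(wn) - wn / 2
    return float(np.interp(0.5, s, t))


def _weighted_median_rows(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median for (M, J) matrices (bootstrap fast path)."""
    order = np.argsort(theta, axis=1)
    t = np.take_along_axis(theta, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)
    wn = ws / ws.sum(axis=1, keepdims=True)
    s = np.cumsum(wn, axis=1) - wn / 2
    # linear interpolation of t at s = 0.5, clamped to the end ratios
    idx = np.argmax(s >= 0.5, axis=1)
    no_cross = s[:, -1] < 0.5
    idx[no_cross] = s.shape[1] - 1
    rows = np.arange(s.shape[0])
    hi_s, hi_t = s[rows, idx], t[rows, idx]
    lo = np.maximum(idx - 1, 0)
    lo_s, lo_t = s[rows, lo], t[rows, lo]
    frac = np.where(hi_s > lo_s, (0.5 - lo_s) / np.where(hi_s > lo_s, hi_s - lo_s, 1.0), 0.0)
    out = lo_t + frac * (hi_t - lo_t)
    out[idx == 0] = t[idx == 0, 0]  # 0.5 at/below the first percentile
    out[no_cross] = t[no_cross, -1]
    return out


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 5000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap standard error.

    The bootstrap redraws exposure and outcome effects from normal laws
    centred on the observed values with their reported SEs, recomputes the
    weighted median ``n_boot`` times, and takes the replicate standard
    deviation as the SE. ``seed`` is mandatory: there is no hidden global
    RNG.
    """
    j = len(instruments)
    if j < 3:
        raise InsufficientInstrumentsError(
            f"weighted median requires >= 3 instruments, got {j}"
        )
    if seed is None:
        raise DomainError("weighted_median requires an explicit seed")
    bx, sx, by, sy = _arrays(instruments)
    theta = by / bx
    w = bx**2 / sy**2
    beta = weighted_median_point(theta, w)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, j))
    by_star = rng.normal(by, sy, size=(n_boot, j))
    theta_star = by_star / bx_star
    w_star = bx_star**2 / sy**2
    reps = _weighted_median_rows(theta_star, w_star)
    se = float(np.std(reps, ddof=1))
    if se == 0:  # all replicates identical (zero-noise instruments)
        se = float(np.finfo(float).tiny)
    p = 2 * stats.norm.sf(abs(beta / se))
    return _estimate(
        "weighted_median", beta, se, p, j, n_boot=n_boot, seed=seed
    )
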