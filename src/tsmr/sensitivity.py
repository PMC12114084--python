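"""Pleiotropy, heterogeneity, outlier and influence diagnostics.

Four complementary checks on an instrument set:

* the MR-Egger intercept test — a non-zero intercept indicates
  directional horizontal pleiotropy;
* Cochran's Q — weighted heterogeneity of the per-SNP ratios about the
  IVW or Egger fit, chi-square distributed under homogeneity with J-1
  (IVW) or J-2 (Egger) degrees of freedom;
* MR-PRESSO — a parametric-resampling test of the leave-one-out residual
  sum of squares that detects globally inflated heterogeneity, flags
  individual outlier instruments, and measures how much removing them
  distorts the IVW estimate;
* leave-one-out — refits IVW excluding each SNP in turn to expose
  estimates driven by a single instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import InterceptRecord, egger, ivw, wald_ratio
from .exceptions import InsufficientInstrumentsError
from .instruments import HarmonizedInstrument

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class QRecord:
    """Cochran's Q heterogeneity statistic with its reference distribution."""

    q: float
    df: int
    pvalue: float
    about: str  # "ivw" | "egger"


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss: float
    global_pvalue: float
    outlier_indices: tuple[int, ...]
    outlier_snps: tuple[str, ...]
    outlier_pvalues: tuple[float, ...]  # Bonferroni-adjusted, one per instrument
    distortion_pvalue: float | None  # None when no outliers were found
    n_sim: int
    seed: int


@dataclass
class SensitivityReport:
    """The full diagnostic battery for one instrument set."""

    egger_intercept: InterceptRecord
    q_ivw: QRecord
    q_egger: QRecord | None
    presso: PressoResult | None
    loo: pd.DataFrame
    pleiotropy_detected: bool
    heterogeneity_detected: bool
    influential_snps: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        """JSON-serializable diagnostics block."""
        return {
            "egger_intercept": {
                "estimate": self.egger_intercept.estimate,
                "se": self.egger_intercept.se,
                "pvalue": self.egger_intercept.pvalue,
                "df": self.egger_intercept.df,
            },
            "cochran_q_ivw": {"q": self.q_ivw.q, "df": self.q_ivw.df, "pvalue": self.q_ivw.pvalue},
            "cochran_q_egger": None
            if self.q_egger is None
            else {"q": self.q_egger.q, "df": self.q_egger.df, "pvalue": self.q_egger.pvalue},
            "mr_presso": None
            if self.presso is None
            else {
                "global_rss": self.presso.global_rss,
                "global_pvalue": self.presso.global_pvalue,
                "outlier_snps": list(self.presso.outlier_snps),
                "outlier_pvalues": list(self.presso.outlier_pvalues),
                "distortion_pvalue": self.presso.distortion_pvalue,
                "n_sim": self.presso.n_sim,
            },
            "leave_one_out": self.loo.to_dict(orient="records"),
            "verdicts": {
                "pleiotropy_detected": self.pleiotropy_detected,
                "heterogeneity_detected": self.heterogeneity_detected,
                "influential_snps": self.influential_snps,
            },
        }


def egger_intercept_test(
    instruments: Sequence[HarmonizedInstrument], alpha: float = DEFAULT_ALPHA
) -> tuple[InterceptRecord, bool]:
    """Egger intercept with a directional-pleiotropy verdict at ``alpha``."""
    _, record = egger(instruments)
    return record, record.pvalue < alpha


def cochran_q(instruments: Sequence[HarmonizedInstrument], about: str = "ivw") -> QRecord:
    """Heterogeneity Q = sum w_j (theta_j - fitted_j)^2 on the ratio scale.

    Weights are the first-order Wald-ratio precisions beta_exp^2/se_out^2.
    The fitted value is the fixed-effect IVW estimate (constant) or the
    Egger line expressed per-SNP on the ratio scale; the reference
    distribution is chi-square with J-1 or J-2 degrees of freedom.
    """
    j = len(instruments)
    if about == "ivw":
        if j < 2:
            raise InsufficientInstrumentsError("Q about IVW requires >= 2 instruments")
        est = ivw(instruments, effects_model="fixed")
        q = est.model_detail["cochran_q"]
        df = j - 1
    elif about == "egger":
        if j < 3:
            raise InsufficientInstrumentsError("Q about Egger requires >= 3 instruments")
        est, rec = egger(instruments)
        bx = np.array([i.beta_exp for i in instruments])
        by = np.array([i.beta_out for i in instruments])
        sy = np.array([i.se_out for i in instruments])
        sign = np.where(bx < 0, -1.0, 1.0)
        x, y = bx * sign, by * sign
        q = float(np.sum((y - rec.estimate - est.beta * x) ** 2 / sy**2))
        df = j - 2
    else:
        raise ValueError(f"unknown Q reference fit {about!r}")
    p = float(stats.chi2.sf(q, df)) if q > 0 else 1.0
    return QRecord(q=float(q), df=df, pvalue=p, about=about)


def _loo_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slopes, vectorized over the left-out SNP.

    With weights w = 1/se_out^2, the IVW estimate is the origin-constrained
    WLS slope sum(w x y)/sum(w x^2); dropping SNP j subtracts its terms.
    """
    sxy = (w * x * y).sum()
    sxx = (w * x * x).sum()
    return (sxy - w * x * y) / (sxx - w * x * x)


def mr_presso(
    instruments: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = DEFAULT_ALPHA,
    n_distortion_draws: int = 500,
) -> PressoResult:
    """MR-PRESSO: global RSS test, per-SNP outlier test, distortion test.

    Each SNP's residual is its outcome effect minus the prediction of the
    leave-one-out IVW fit; the observed weighted RSS is compared with a
    null distribution built by redrawing outcome effects from
    N(beta_exp_j * theta_hat(-j), se_out_j) ``n_sim`` times, recomputing
    the leave-one-out fits within each simulated dataset. P-values use the
    add-one rule (1 + #{exceedances})/(n_sim + 1), so they are never zero.
    Per-SNP outlier p-values are Bonferroni-adjusted across instruments;
    the distortion test compares the outlier-corrected IVW estimate with
    the distribution obtained by deleting random instrument subsets of the
    same size.
    """
    j = len(instruments)
    if j < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO requires >= 4 instruments, got {j}")
    if n_sim < 1000:
        raise ValueError("MR-PRESSO needs n_sim >= 1000 for stable tail estimates")
    if seed is None:
        raise ValueError("mr_presso requires an explicit seed")

    bx = np.array([i.beta_exp for i in instruments], dtype=float)
    by = np.array([i.beta_out for i in instruments], dtype=float)
    sy = np.array([i.se_out for i in instruments], dtype=float)
    w = 1.0 / sy**2

    theta_loo = _loo_slopes(bx, by, w)
    resid = by - bx * theta_loo
    rss_obs = float(np.sum(w * resid**2))
    resid2_obs = resid**2

    rng = np.random.default_rng(seed)
    mu = bx * theta_loo
    y_star = rng.normal(mu, sy, size=(n_sim, j))
    # leave-one-out slopes inside each simulated dataset, vectorized
    sxy_star = (w * bx * y_star).sum(axis=1, keepdims=True)
    sxx = (w * bx * bx).sum()
    theta_star = (sxy_star - w * bx * y_star) / (sxx - w * bx * bx)
    resid_star = y_star - bx * theta_star
    rss_star = (w * resid_star**2).sum(axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))

    exceed = (resid_star**2 >= resid2_obs).sum(axis=0)
    p_raw = (1 + exceed) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * j)
    outlier_mask = p_adj < outlier_alpha
    outlier_idx = tuple(int(k) for k in np.flatnonzero(outlier_mask))
    outlier_ids = tuple(instruments[k].snp_id for k in outlier_idx)

    distortion_p: float | None = None
    n_out = len(outlier_idx)
    if 0 < n_out < j - 1:
        keep = [i for k, i in enumerate(instruments) if k not in outlier_idx]
        beta_all = ivw(instruments, effects_model="fixed").beta
        beta_corr = ivw(keep, effects_model="fixed").beta
        d_obs = abs((beta_corr - beta_all) / beta_corr) if beta_corr != 0 else math.inf
        draws = np.empty(n_distortion_draws)
        for i in range(n_distortion_draws):
            drop = rng.choice(j, size=n_out, replace=False)
            kept = [inst for k, inst in enumerate(instruments) if k not in set(drop.tolist())]
            b = ivw(kept, effects_model="fixed").beta
            draws[i] = abs((b - beta_all) / b) if b != 0 else math.inf
        distortion_p = float((1 + np.sum(draws >= d_obs)) / (n_distortion_draws + 1))

    return PressoResult(
        global_rss=rss_obs,
        global_pvalue=global_p,
        outlier_indices=outlier_idx,
        outlier_snps=outlier_ids,
        outlier_pvalues=tuple(float(p) for p in p_adj),
        distortion_pvalue=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
    alpha: float = DEFAULT_ALPHA,
    effects_model: str = "multiplicative_random",
) -> tuple[pd.DataFrame, bool, list[str]]:
    """IVW re-estimated with each instrument excluded in turn.

    Returns (table, influential_verdict, influential_snp_ids): the verdict
    is true when any single exclusion flips the sign of the estimate or
    moves its p-value across ``alpha`` relative to the full-set fit.
    """
    j = len(instruments)
    if j < 2:
        raise InsufficientInstrumentsError("leave-one-out requires >= 2 instruments")
    full = ivw(instruments, effects_model=effects_model)
    rows = []
    influential: list[str] = []
    for k, left_out in enumerate(instruments):
        rest = [inst for i, inst in enumerate(instruments) if i != k]
        est = ivw(rest, effects_model=effects_model) if len(rest) > 1 else wald_ratio(rest[0])
        rows.append(
            {"excluded_snp": left_out.snp_id, "beta": est.beta, "se": est.se, "pvalue": est.pvalue}
        )
        sign_flip = np.sign(est.beta) != np.sign(full.beta) and est.beta != 0 and full.beta != 0
        sig_flip = (est.pvalue < alpha) != (full.pvalue < alpha)
        if sign_flip or sig_flip:
            influential.append(left_out.snp_id)
    return pd.DataFrame(rows), bool(influential), influential


def sensitivity_report(
    instruments: Sequence[HarmonizedInstrument],
    alpha: float = DEFAULT_ALPHA,
    run_presso: bool = True,
    presso_nsim: int = 1000,
    seed: int | None = None,
) -> SensitivityReport:
    """Assemble the full diagnostic battery where instrument counts allow.

    Requires >= 3 instruments (the Egger minimum); the MR-PRESSO block is
    included only when >= 4 instruments are available and ``run_presso``.
    """
    intercept, pleio = egger_intercept_test(instruments, alpha=alpha)
    q_ivw = cochran_q(instruments, about="ivw")
    q_egger = cochran_q(instruments, about="egger") if len(instruments) >= 3 else None
    presso = None
    if run_presso and len(instruments) >= 4:
        presso = mr_presso(instruments, n_sim=presso_nsim, seed=seed, outlier_alpha=alpha)
    loo, _, influential = leave_one_out(instruments, alpha=alpha)
    return SensitivityReport(
        egger_intercept=intercept,
        q_ivw=q_ivw,
        q_egger=q_egger,
        presso=presso,
        loo=loo,
        pleiotropy_detected=pleio,
        heterogeneity_detected=q_ivw.pvalue < alpha,
        influential_snps=influential,
    )
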