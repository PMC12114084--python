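"""Replicated simulation experiments validating the estimators.

Each experiment generates many synthetic exposure/outcome pairs with a
known truth, runs a piece of the MR machinery on them, and summarizes its
behaviour: type-I error under the causal null, parameter recovery under a
true effect or directional pleiotropy, robustness of the weighted median
under contamination, and MR-PRESSO's calibration and outlier-detection
rate. The experiments feed the validation analysis scripts, the test
suite and the acceptance report, so their scenario parameters live here
in one place.

Harmonization (but not p-value pre-selection) is applied before
estimation: selecting on the exposure statistic would add winner's-curse
bias that these calibration checks deliberately do not model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .estimators import egger, ivw, weighted_median
from .sensitivity import mr_presso
from .simulate import SimScenario, harmonized_from_truth, simulate_outlier_spike, simulate_pair


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Independent per-replicate seeds below 2**31, derived from one seed."""
    return np.random.default_rng(seed).integers(1, 2**31 - 1, size=n)


@dataclass(frozen=True)
class CalibrationResult:
    rejection_rate: float
    n_replicates: int
    alpha: float

    @property
    def binomial_se(self) -> float:
        return float(np.sqrt(self.alpha * (1 - self.alpha) / self.n_replicates))


def ivw_null_calibration(
    n_replicates: int = 1000,
    seed: int = 0,
    n_snp: int = 10,
    alpha: float = 0.05,
) -> CalibrationResult:
    """IVW type-I error with no causal effect and no pleiotropy."""
    rejections = 0
    for s in _child_seeds(seed, n_replicates):
        scen = SimScenario(seed=int(s), n_snp=n_snp, beta_causal=0.0)
        instruments = harmonized_from_truth(*simulate_pair(scen)[:2])
        if ivw(instruments).pvalue < alpha:
            rejections += 1
    return CalibrationResult(rejections / n_replicates, n_replicates, alpha)


@dataclass(frozen=True)
class RecoveryResult:
    mean_estimate: float
    sd_estimate: float
    n_replicates: int
    truth: float

    @property
    def monte_carlo_se(self) -> float:
        return float(self.sd_estimate / np.sqrt(self.n_replicates))


def ivw_recovery(
    beta_causal: float = float(np.log(0.65)),
    n_replicates: int = 500,
    seed: int = 0,
    n_snp: int = 7,
) -> RecoveryResult:
    """Mean IVW estimate across replicates of the reference scenario."""
    betas = np.empty(n_replicates)
    for i, s in enumerate(_child_seeds(seed, n_replicates)):
        scen = SimScenario(seed=int(s), n_snp=n_snp, beta_causal=beta_causal)
        instruments = harmonized_from_truth(*simulate_pair(scen)[:2])
        betas[i] = ivw(instruments).beta
    return RecoveryResult(float(betas.mean()), float(betas.std(ddof=1)), n_replicates, beta_causal)


@dataclass(frozen=True)
class EggerRecoveryResult:
    mean_slope: float
    mean_intercept: float
    sd_slope: float
    sd_intercept: float
    n_replicates: int
    truth_slope: float
    truth_intercept: float


def egger_pleiotropy_recovery(
    beta_causal: float = float(np.log(0.65)),
    pleio_mean: float = 0.05,
    pleio_sd: float = 0.02,
    n_replicates: int = 500,
    seed: int = 0,
    n_snp: int = 20,
    n_exposure: int = 200_000,
) -> EggerRecoveryResult:
    """Egger slope/intercept recovery under InSiDE-respecting directional pleiotropy.

    Direct effects have non-zero mean but are independent of instrument
    strength, the regime in which the Egger intercept estimates the mean
    pleiotropic effect and the slope stays consistent for the causal one.
    Instrument effects are generated all-positive: the intercept's target
    is the mean direct effect relative to the oriented exposure allele,
    and sign-flipping an instrument would flip its direct effect too.

    Egger's consistency is an asymptotic property that additionally needs
    near-noiseless exposure effects (without an I2_GX attenuation
    correction, exposure-side noise shrinks the slope towards the
    pleiotropy-confounded value), so this experiment uses a large exposure
    GWAS; the attenuation under weaker instruments is a documented
    limitation, not a defect this check would catch.
    """
    slopes = np.empty(n_replicates)
    intercepts = np.empty(n_replicates)
    for i, s in enumerate(_child_seeds(seed, n_replicates)):
        scen = SimScenario(
            seed=int(s),
            n_snp=n_snp,
            beta_causal=beta_causal,
            pleio_mean=pleio_mean,
            pleio_sd=pleio_sd,
            gamma_range=(0.08, 0.3),
            gamma_positive=True,
            n_exposure=n_exposure,
        )
        instruments = harmonized_from_truth(*simulate_pair(scen)[:2])
        est, rec = egger(instruments)
        slopes[i] = est.beta
        intercepts[i] = rec.estimate
    return EggerRecoveryResult(
        float(slopes.mean()),
        float(intercepts.mean()),
        float(slopes.std(ddof=1)),
        float(intercepts.std(ddof=1)),
        n_replicates,
        beta_causal,
        pleio_mean,
    )


def presso_null_calibration(
    n_replicates: int = 200,
    seed: int = 0,
    n_snp: int = 10,
    n_sim: int = 1000,
    alpha: float = 0.05,
) -> CalibrationResult:
    """MR-PRESSO global-test rejection rate under the causal and pleiotropy null.

    The causal effect is zero here for the same reason the IVW calibration
    uses it: with a non-zero effect, exposure-side sampling noise enters
    the Wald ratios but not the first-order weights, producing genuine
    over-dispersion that is not a type-I error of the test.
    """
    rejections = 0
    for s in _child_seeds(seed, n_replicates):
        scen = SimScenario(seed=int(s), n_snp=n_snp, beta_causal=0.0)
        instruments = harmonized_from_truth(*simulate_pair(scen)[:2])
        res = mr_presso(instruments, n_sim=n_sim, seed=int(s) + 1)
        if res.global_pvalue < alpha:
            rejections += 1
    return CalibrationResult(rejections / n_replicates, n_replicates, alpha)


@dataclass(frozen=True)
class SpikeDetectionResult:
    detection_rate: float
    n_replicates: int
    spike_index: int
    spike_size_in_se: float


def presso_spike_detection(
    n_replicates: int = 200,
    seed: int = 0,
    n_snp: int = 7,
    spike_index: int = 2,
    spike_size_in_se: float = 10.0,
    n_sim: int = 1000,
) -> SpikeDetectionResult:
    """How often MR-PRESSO flags exactly the contaminated instrument."""
    hits = 0
    for s in _child_seeds(seed, n_replicates):
        scen = SimScenario(seed=int(s), n_snp=n_snp)
        exposure, outcome, _ = simulate_outlier_spike(scen, spike_index, spike_size_in_se)
        instruments = harmonized_from_truth(exposure, outcome)
        res = mr_presso(instruments, n_sim=n_sim, seed=int(s) + 1)
        if spike_index in res.outlier_indices:
            hits += 1
    return SpikeDetectionResult(hits / n_replicates, n_replicates, spike_index, spike_size_in_se)


@dataclass(frozen=True)
class ContaminationResult:
    """IVW vs weighted-median bias under minority-invalid instruments."""

    ivw_bias: float
    wmedian_bias: float
    truth: float
    invalid_weight_fraction: float
    n_replicates: int


def wmedian_contamination(
    beta_causal: float = 0.3,
    n_snp: int = 11,
    n_invalid: int = 3,
    pleio_shift: float = 0.08,
    n_replicates: int = 200,
    seed: int = 0,
    noise_scale: float = 0.2,
) -> ContaminationResult:
    """Breakdown contrast: < 50% of instruments carry a constant direct effect.

    The invalid minority biases IVW towards pleio_shift/gamma while the
    weighted median, anchored at the valid majority, stays near the truth
    — the sharper the SEs (small ``noise_scale``), the cleaner the contrast.
    """
    ivw_est = np.empty(n_replicates)
    wm_est = np.empty(n_replicates)
    frac = np.nan
    for i, s in enumerate(_child_seeds(seed, n_replicates)):
        scen = SimScenario(
            seed=int(s),
            n_snp=n_snp,
            beta_causal=beta_causal,
            noise_scale=noise_scale,
            gamma_positive=True,  # keeps the minority's bias directional
        )
        exposure, outcome, truth = simulate_pair(scen)
        # contaminate a fixed minority with a constant direct effect
        for k in range(n_invalid):
            rec = outcome.records[k]
            outcome.records[k] = replace(rec, beta=rec.beta + pleio_shift)
        instruments = harmonized_from_truth(exposure, outcome)
        w = np.array([inst.beta_exp**2 / inst.se_out**2 for inst in instruments])
        frac = float(w[:n_invalid].sum() / w.sum())
        ivw_est[i] = ivw(instruments).beta
        wm_est[i] = weighted_median(instruments, n_boot=200, seed=int(s) + 1).beta
    return ContaminationResult(
        float(ivw_est.mean() - beta_causal),
        float(wm_est.mean() - beta_causal),
        beta_causal,
        frac,
        n_replicates,
    )
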