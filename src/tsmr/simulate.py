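"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the data layout of a microbiota-exposure /
disease-outcome MR study: an exposure GWAS of modest size (a
microbiome-association scan of roughly fourteen thousand participants)
and a large binary-outcome GWAS (about 170,000 participants), observed
only through per-SNP summary statistics.

For SNP j with effect-allele frequency f_j and GWAS of N samples, the
sampling SE of a standardized-trait effect estimate is

    sigma_j = (2 N f_j (1 - f_j)) ** -0.5,

the usual quantitative-trait approximation with unit phenotypic variance.
True instrument effects gamma_j are drawn with uniform magnitude and
random sign; direct (pleiotropic) effects alpha_j have mean ``pleio_mean``
and sd ``pleio_sd`` and may correlate with instrument strength
(``inside_violation``) to break the InSiDE assumption on demand. The true
outcome effect is Gamma_j = beta_causal * gamma_j + alpha_j, and observed
effects add N(0, sigma) noise on each side. Every latent quantity is kept
in a truth record so estimators can be validated by parameter recovery.

Effects on the binary outcome are interpreted directly on the ln(OR)
scale; case/control imbalance is not modelled.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError
from .sumstats import SumstatRecord, TraitTable
from scipy import stats

# Non-palindromic allele pairs cycled across simulated SNPs.
_ALLELE_CYCLE = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T")]
_PALINDROMIC = [("A", "T"), ("C", "G")]

#: default sample sizes: a MiBioGen-scale taxon GWAS and a large
#: binary-outcome GWAS of 169,716 participants.
DEFAULT_N_EXPOSURE = 14_263
DEFAULT_N_OUTCOME = 169_716


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters for one synthetic exposure/outcome pair.

    Defaults describe the reference condition used throughout the test
    suite: seven independent strong instruments (effect magnitudes drawn
    uniformly from 0.12-0.25, comfortably past both the p < 5e-6 selection
    threshold and the F >= 10 strength rule at the default sample sizes),
    a protective causal effect ln(0.65), and no pleiotropy.
    """

    seed: int
    n_snp: int = 7
    beta_causal: float = float(np.log(0.65))
    gamma_range: tuple[float, float] = (0.12, 0.25)
    gamma_positive: bool = False  # force all instrument effects positive
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    inside_violation: float = 0.0  # corr(alpha, |gamma|); 0 keeps InSiDE
    n_exposure: int = DEFAULT_N_EXPOSURE
    n_outcome: int = DEFAULT_N_OUTCOME
    eaf_range: tuple[float, float] = (0.1, 0.9)
    palindromic_fraction: float = 0.0
    noise_scale: float = 1.0  # multiplies sampling noise; reported SEs stay analytic
    exposure_id: str = "sim_exposure"
    outcome_id: str = "sim_outcome"

    def validate(self) -> None:
        if self.n_snp < 1:
            raise ConfigurationError("n_snp must be >= 1")
        if self.n_exposure < 3 or self.n_outcome < 3:
            raise ConfigurationError("sample sizes must be >= 3")
        lo, hi = self.eaf_range
        if not (0 < lo <= hi < 1):
            raise ConfigurationError("eaf_range must lie within (0, 1)")
        if not (0 <= self.palindromic_fraction <= 1):
            raise ConfigurationError("palindromic_fraction must lie in [0, 1]")
        if not (-1 <= self.inside_violation <= 1):
            raise ConfigurationError("inside_violation is a correlation in [-1, 1]")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be >= 0")


@dataclass
class SimTruth:
    """Latent quantities behind one simulated pair."""

    beta_causal: float
    snp_ids: list[str]
    gamma: list[float]
    alpha: list[float]
    eaf: list[float]
    sigma_exposure: list[float]
    sigma_outcome: list[float]
    spike_index: int | None = None
    spike_size_in_se: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _se_standardized(n: int, eaf: np.ndarray) -> np.ndarray:
    return (2.0 * n * eaf * (1.0 - eaf)) ** -0.5


def simulate_pair(scenario: SimScenario) -> tuple[TraitTable, TraitTable, SimTruth]:
    """Generate one exposure table, one outcome table, and their truth record.

    The two tables cover the same SNPs (the instrument candidates), placed
    on distinct chromosomes or far apart so that distance-based clumping
    keeps them all. The same seed always reproduces the same tables, and
    scenarios differing only in ``beta_causal`` share identical exposure
    draws — convenient for building traits with shared instruments.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    j = scenario.n_snp

    eaf = rng.uniform(*scenario.eaf_range, size=j)
    magnitude = rng.uniform(*scenario.gamma_range, size=j)
    sign = rng.choice([-1.0, 1.0], size=j)  # drawn regardless, to keep the stream stable
    if scenario.gamma_positive:
        sign = np.ones(j)
    gamma = magnitude * sign

    z_indep = rng.normal(size=j)
    if scenario.pleio_sd > 0 and abs(scenario.inside_violation) > 0 and j > 1:
        m = magnitude
        z_gamma = (m - m.mean()) / (m.std() if m.std() > 0 else 1.0)
        rho = scenario.inside_violation
        z = rho * z_gamma + np.sqrt(1 - rho**2) * z_indep
    else:
        z = z_indep
    alpha = scenario.pleio_mean + scenario.pleio_sd * z

    sigma_x = _se_standardized(scenario.n_exposure, eaf)
    sigma_y = _se_standardized(scenario.n_outcome, eaf)
    noise_x = rng.normal(size=j) * sigma_x * scenario.noise_scale
    noise_y = rng.normal(size=j) * sigma_y * scenario.noise_scale
    beta_x = gamma + noise_x
    big_gamma = scenario.beta_causal * gamma + alpha
    beta_y = big_gamma + noise_y

    n_pal = int(round(scenario.palindromic_fraction * j))
    snp_ids = [f"rs{scenario.seed % 100_000}{k:03d}" for k in range(j)]
    exp_records, out_records = [], []
    for k in range(j):
        if k < n_pal:
            ea, oa = _PALINDROMIC[k % len(_PALINDROMIC)]
        else:
            ea, oa = _ALLELE_CYCLE[k % len(_ALLELE_CYCLE)]
        chrom = str(k % 22 + 1)
        pos = 1_000_000 + (k // 22) * 25_000_000
        common = dict(snp_id=snp_ids[k], chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa, eaf=float(eaf[k]))
        exp_records.append(
            SumstatRecord(
                beta=float(beta_x[k]),
                se=float(sigma_x[k]),
                pvalue=float(2 * stats.norm.sf(abs(beta_x[k] / sigma_x[k]))),
                n=scenario.n_exposure,
                **common,
            )
        )
        out_records.append(
            SumstatRecord(
                beta=float(beta_y[k]),
                se=float(sigma_y[k]),
                pvalue=float(2 * stats.norm.sf(abs(beta_y[k] / sigma_y[k]))),
                n=scenario.n_outcome,
                **common,
            )
        )

    exposure = TraitTable(
        trait_id=scenario.exposure_id, trait_type="quantitative", records=exp_records
    )
    outcome = TraitTable(
        trait_id=scenario.outcome_id, trait_type="binary", records=out_records
    )
    truth = SimTruth(
        beta_causal=scenario.beta_causal,
        snp_ids=snp_ids,
        gamma=gamma.tolist(),
        alpha=alpha.tolist(),
        eaf=eaf.tolist(),
        sigma_exposure=sigma_x.tolist(),
        sigma_outcome=sigma_y.tolist(),
    )
    return exposure, outcome, truth


def simulate_outlier_spike(
    scenario: SimScenario, spike_index: int, spike_size_in_se: float
) -> tuple[TraitTable, TraitTable, SimTruth]:
    """A simulated pair with one contaminated instrument.

    ``spike_size_in_se`` times the outcome sampling SE is added to the
    observed outcome effect of SNP ``spike_index``, emulating a single
    strongly pleiotropic outlier for the MR-PRESSO test to find.
    """
    if not (0 <= spike_index < scenario.n_snp):
        raise ConfigurationError(
            f"spike_index {spike_index} outside [0, {scenario.n_snp})"
        )
    exposure, outcome, truth = simulate_pair(scenario)
    rec = outcome.records[spike_index]
    shifted = rec.beta + spike_size_in_se * truth.sigma_outcome[spike_index]
    new_rec = SumstatRecord(
        snp_id=rec.snp_id,
        chrom=rec.chrom,
        pos=rec.pos,
        effect_allele=rec.effect_allele,
        other_allele=rec.other_allele,
        eaf=rec.eaf,
        beta=float(shifted),
        se=rec.se,
        pvalue=float(2 * stats.norm.sf(abs(shifted / rec.se))),
        n=rec.n,
    )
    outcome.records[spike_index] = new_rec
    truth.spike_index = spike_index
    truth.spike_size_in_se = spike_size_in_se
    return exposure, outcome, truth


def harmonized_from_truth(
    exposure: TraitTable, outcome: TraitTable
) -> "list":
    """Shortcut used by calibration experiments: harmonize a simulated pair.

    Simulated tables share orientation by construction, so this is a thin
    wrapper over :func:`tsmr.instruments.harmonize` followed by strength
    annotation.
    """
    from .instruments import annotate_strength, harmonize

    instruments = [i for i in harmonize(exposure, outcome) if i.kept]
    return annotate_strength(instruments)
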