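"""Builders shared across test modules (importable outside fixtures)."""

import numpy as np

from tsmr.instruments import HarmonizedInstrument
from tsmr.sumstats import SumstatRecord, TraitTable


def make_instruments(
    seed: int,
    j: int,
    beta: float = 0.5,
    intercept: float = 0.0,
    noise: float = 1.0,
    n_exp: int = 10_000,
) -> list[HarmonizedInstrument]:
    """Random harmonized instruments around beta_out = intercept + beta*beta_exp."""
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.1, 0.5, j) * rng.choice([-1, 1], j)
    sx = rng.uniform(0.005, 0.02, j)
    sy = rng.uniform(0.01, 0.05, j)
    sign = np.where(bx < 0, -1, 1)
    by = sign * (intercept + beta * np.abs(bx)) + noise * sy * rng.normal(size=j)
    return [
        HarmonizedInstrument(
            snp_id=f"rs{k}",
            beta_exp=float(bx[k]),
            se_exp=float(sx[k]),
            beta_out=float(by[k]),
            se_out=float(sy[k]),
            n_exp=n_exp,
            eaf_exp=0.3,
        )
        for k in range(j)
    ]


def make_record(**kwargs) -> SumstatRecord:
    defaults = dict(
        snp_id="rs1",
        chrom="1",
        pos=1_000_000,
        effect_allele="A",
        other_allele="G",
        eaf=0.3,
        beta=0.1,
        se=0.01,
        pvalue=1e-8,
        n=10_000,
    )
    defaults.update(kwargs)
    return SumstatRecord(**defaults)


def make_table(records, trait_id="trait", trait_type="quantitative") -> TraitTable:
    return TraitTable(trait_id=trait_id, trait_type=trait_type, records=list(records))
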