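"""Bidirectional MR orchestration over many traits.

``run_pair`` executes the full chain for one exposure/outcome pair —
p-value selection, LD clumping, harmonization, instrument-strength
filtering, estimation, sensitivity battery — with an attrition log of SNP
counts at every stage. Traits that lose all instruments produce a
structured "not analyzable" record instead of an exception, so batch runs
over dozens of taxa never abort on one of them.

``run_plan`` maps a plan (exposures x outcomes x direction) onto
``run_pair``; the reverse direction literally swaps the trait roles. The
assembled report has one row per (exposure, outcome, direction, method)
with p, OR, 95% CI and instrument count — the shape of a standard MR
result table — plus a raw-p significance flag and an optional
Benjamini-Hochberg column for readers who want multiplicity control
across taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .estimators import MREstimate, egger, ivw, wald_ratio, weighted_median
from .exceptions import ConfigurationError, ZeroInstrumentError
from .instruments import (
    ClumpConfig,
    HarmonizedInstrument,
    annotate_strength,
    clump,
    filter_weak,
    harmonize,
    select_by_pvalue,
)
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import TraitTable


@dataclass
class PipelineConfig:
    """Everything run_pair needs besides the two trait tables."""

    clump: ClumpConfig = field(default_factory=ClumpConfig)
    palindrome_eaf_limit: float = 0.42
    f_min: float = 10.0
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median")
    ivw_model: str = "multiplicative_random"
    n_boot: int = 5000
    run_presso: bool = True
    presso_nsim: int = 1000
    alpha: float = 0.05
    seed: int = 0


@dataclass
class AnalysisPlan:
    """A batch of exposures and outcomes to analyse in one or both directions."""

    exposures: list[TraitTable]
    outcomes: list[TraitTable]
    direction: str = "both"  # forward | reverse | both
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def __post_init__(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ConfigurationError("plan needs at least one exposure and one outcome")
        if self.direction not in ("forward", "reverse", "both"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")


@dataclass
class PairResult:
    """Outcome of one exposure -> outcome analysis."""

    exposure_id: str
    outcome_id: str
    direction: str
    estimates: list[MREstimate] = field(default_factory=list)
    sensitivity: SensitivityReport | None = None
    instruments: list[HarmonizedInstrument] = field(default_factory=list)
    attrition: dict[str, int] = field(default_factory=dict)
    not_analyzable: str | None = None

    @property
    def analyzable(self) -> bool:
        return self.not_analyzable is None


def run_pair(
    exposure: TraitTable,
    outcome: TraitTable,
    config: PipelineConfig | None = None,
    direction: str = "forward",
) -> PairResult:
    """Full single-pair MR analysis with stage-by-stage attrition.

    Stages: p-value selection -> clumping -> overlap with the outcome ->
    harmonization -> strength filter -> estimators -> sensitivity. A
    zero-instrument outcome at any stage short-circuits into a
    ``not_analyzable`` record carrying the reason and the attrition so far.
    """
    config = config or PipelineConfig()
    result = PairResult(
        exposure_id=exposure.trait_id, outcome_id=outcome.trait_id, direction=direction
    )
    att = result.attrition
    att["input"] = len(exposure)

    selected = select_by_pvalue(exposure, config.clump.p_threshold)
    att["p_selected"] = len(selected)
    if not selected.records:
        result.not_analyzable = f"no SNP at p < {config.clump.p_threshold:g}"
        return result

    clumped = clump(selected, config.clump)
    att["clumped"] = len(clumped)

    outcome_ids = set(outcome.snp_ids())
    overlap = [r.snp_id for r in clumped.records if r.snp_id in outcome_ids]
    att["in_outcome"] = len(overlap)
    if not overlap:
        result.not_analyzable = "no instrument present in the outcome GWAS"
        return result

    harmonized = harmonize(
        clumped.subset(overlap), outcome, config.palindrome_eaf_limit
    )
    kept = [i for i in harmonized if i.kept]
    att["harmonized"] = len(kept)
    if not kept:
        result.not_analyzable = "all instruments dropped during harmonization"
        result.instruments = harmonized
        return result

    annotate_strength(kept)
    try:
        strong, weak = filter_weak(kept, config.f_min)
    except ZeroInstrumentError:
        result.not_analyzable = f"all instruments weak (F < {config.f_min:g})"
        result.instruments = harmonized
        return result
    att["strong"] = len(strong)
    result.instruments = harmonized  # kept + dropped, for the attrition trail

    j = len(strong)
    for method in config.methods:
        if method == "ivw":
            est = (
                ivw(strong, effects_model=config.ivw_model)
                if j > 1
                else wald_ratio(strong[0])
            )
            result.estimates.append(est)
        elif method == "egger" and j >= 3:
            result.estimates.append(egger(strong)[0])
        elif method == "weighted_median" and j >= 3:
            result.estimates.append(
                weighted_median(strong, n_boot=config.n_boot, seed=config.seed)
            )
    if j >= 3:
        result.sensitivity = sensitivity_report(
            strong,
            alpha=config.alpha,
            run_presso=config.run_presso,
            presso_nsim=config.presso_nsim,
            seed=config.seed,
        )
    return result


def run_plan(plan: AnalysisPlan) -> tuple[pd.DataFrame, list[PairResult]]:
    """Run every (exposure, outcome) pair in the requested direction(s).

    Returns the assembled result table (one row per analysis and method,
    sorted by direction then p) and the underlying PairResult objects.
    Rows for non-analyzable pairs keep their reason in ``note``.
    """
    pair_results: list[PairResult] = []
    if plan.direction in ("forward", "both"):
        for exp in plan.exposures:
            for out in plan.outcomes:
                pair_results.append(run_pair(exp, out, plan.config, "forward"))
    if plan.direction in ("reverse", "both"):
        for out in plan.outcomes:
            for exp in plan.exposures:
                pair_results.append(run_pair(out, exp, plan.config, "reverse"))

    rows = []
    for pr in pair_results:
        if not pr.analyzable:
            rows.append(
                {
                    "direction": pr.direction,
                    "exposure": pr.exposure_id,
                    "outcome": pr.outcome_id,
                    "method": None,
                    "n_snp": 0,
                    "beta": np.nan,
                    "se": np.nan,
                    "p": np.nan,
                    "or": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "significant": False,
                    "note": pr.not_analyzable,
                }
            )
            continue
        for est in pr.estimates:
            rows.append(
                {
                    "direction": pr.direction,
                    "exposure": pr.exposure_id,
                    "outcome": pr.outcome_id,
                    "method": est.method,
                    "n_snp": est.n_snp,
                    "beta": est.beta,
                    "se": est.se,
                    "p": est.pvalue,
                    "or": est.or_,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "significant": est.pvalue < plan.config.alpha,
                    "note": "",
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["direction", "p"], na_position="last").reset_index(drop=True)
        df["p_bh"] = np.nan
        mask = df["p"].notna()
        for (_, _), idx in df[mask].groupby(["direction", "method"]).groups.items():
            df.loc[idx, "p_bh"] = multipletests(df.loc[idx, "p"], method="fdr_bh")[1]
    return df, pair_results


def shared_snp_report(instrument_sets: dict[str, Sequence[str]]) -> pd.DataFrame:
    """Pairwise instrument overlap between traits.

    ``instrument_sets`` maps trait id to its selected instrument SNP ids;
    the report lists, for every trait pair, the number and identity of
    shared SNPs (traits estimated from the same instruments cannot be
    interpreted as independent signals).
    """
    if len(instrument_sets) < 2:
        raise ConfigurationError("shared-SNP report needs at least two traits")
    names = sorted(instrument_sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            shared = sorted(set(instrument_sets[a]) & set(instrument_sets[b]))
            rows.append(
                {"trait_a": a, "trait_b": b, "n_shared": len(shared), "shared_snps": ",".join(shared)}
            )
    return pd.DataFrame(rows)


def scatter_data(result: PairResult) -> pd.DataFrame:
    """Per-SNP effect series with fitted IVW and Egger lines.

    Reconstructs the data behind the classic MR scatter plot: exposure
    effect vs outcome effect per instrument with both SEs, plus each
    fitted line's prediction at that SNP.
    """
    strong = [i for i in result.instruments if i.kept and "weak" not in i.flags]
    df = pd.DataFrame(
        {
            "snp_id": [i.snp_id for i in strong],
            "beta_exp": [i.beta_exp for i in strong],
            "se_exp": [i.se_exp for i in strong],
            "beta_out": [i.beta_out for i in strong],
            "se_out": [i.se_out for i in strong],
        }
    )
    for est in result.estimates:
        if est.method == "ivw":
            df["ivw_fit"] = est.beta * df["beta_exp"]
        elif est.method == "egger":
            a = est.model_detail["intercept"]
            sign = np.sign(df["beta_exp"]).replace(0, 1)
            # the Egger line lives on the oriented scale; map back per SNP
            df["egger_fit"] = sign * (a + est.beta * sign * df["beta_exp"])
    return df
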