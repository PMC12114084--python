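"""Instrument selection, LD clumping, allele harmonization and strength.

The instrument pipeline mirrors standard two-sample MR practice:

1. keep exposure SNPs with association p strictly below a threshold
   (default 5e-6);
2. greedily clump them to near-independence (LD r-squared < 0.001 within a
   10,000 kb window by default) keeping the lowest-p representative;
3. harmonize exposure and outcome effects onto the exposure's effect
   allele, resolving strand flips and palindromic (A/T, C/G) variants by
   allele frequency;
4. quantify instrument strength with the per-SNP variance explained

       R^2 = 2 b^2 f (1-f) / (2 b^2 f (1-f) + 2 se^2 N f (1-f))

   (the allele-frequency terms cancel algebraically, leaving
   b^2 / (b^2 + se^2 N); the formula is evaluated as written) and the
   F-statistic F = R^2 (N-2) / (1 - R^2), discarding weak instruments
   with F below 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import (
    DomainError,
    MissingEAFError,
    NoOverlapError,
    ZeroInstrumentError,
)
from .sumstats import SumstatRecord, TraitTable

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


@dataclass
class HarmonizedInstrument:
    """Exposure and outcome effects for one SNP on a shared effect allele.

    ``beta_out`` always refers to the exposure's effect allele. ``flags``
    records what harmonization did (``flipped``, ``strand_corrected``,
    ``palindromic``, ``weak``); ``dropped_reason`` is set when the SNP was
    excluded and explains why.
    """

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    n_exp: int
    eaf_exp: float | None = None
    eaf_out: float | None = None
    chrom: str = ""
    pos: int = 0
    r2: float | None = None
    f_stat: float | None = None
    flags: set[str] = field(default_factory=set)
    dropped_reason: str | None = None

    @property
    def kept(self) -> bool:
        return self.dropped_reason is None


@dataclass(frozen=True)
class ClumpConfig:
    """Greedy clumping parameters (p threshold, LD cutoff, window)."""

    p_threshold: float = 5e-6
    ld_r2_max: float = 0.001
    window_kb: float = 10_000.0
    ld_source: "LDSource | None" = None

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise DomainError("p_threshold must lie in (0, 1)")
        if not (0 <= self.ld_r2_max <= 1):
            raise DomainError("ld_r2_max must lie in [0, 1]")
        if self.window_kb <= 0:
            raise DomainError("window_kb must be positive")


class LDSource:
    """Symmetric pairwise LD r-squared lookup; unknown pairs count as 0."""

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        for (a, b), r2 in (pairs or {}).items():
            self._r2[frozenset((a, b))] = float(r2)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDSource":
        """Load a 3-column table: snp_id_a, snp_id_b, r2."""
        df = pd.read_csv(path, sep="\t")
        return cls({(a, b): r for a, b, r in df.itertuples(index=False)})

    def r2(self, snp_a: str, snp_b: str) -> float:
        return self._r2.get(frozenset((snp_a, snp_b)), 0.0)


def select_by_pvalue(table: TraitTable, threshold: float = 5e-6) -> TraitTable:
    """Keep records with association p strictly below ``threshold``.

    The comparison is strict, matching the convention "p < 5e-6". An empty
    selection is returned (not raised) so batch drivers can report a
    zero-instrument trait.
    """
    kept = [r for r in table.records if r.pvalue < threshold]
    if not kept:
        logger.info("trait %s: no SNP passed p < %g", table.trait_id, threshold)
    return table.subset([r.snp_id for r in kept])


def clump(table: TraitTable, config: ClumpConfig | None = None) -> TraitTable:
    """Greedy LD clumping: retain the lowest-p SNP of each correlated clump.

    Candidates are visited in ascending p (ties broken by chromosome and
    position for determinism). Accepting a SNP removes every remaining
    same-chromosome SNP within ``window_kb`` whose LD r-squared with it is
    at or above ``ld_r2_max``; with no LD source, all within-window
    same-chromosome neighbours are conservatively treated as correlated.
    The accepted set is returned in genomic order.
    """
    config = config or ClumpConfig()
    candidates = sorted(table.records, key=lambda r: (r.pvalue, r.chrom, r.pos))
    accepted: list[SumstatRecord] = []
    removed: set[str] = set()
    for rec in candidates:
        if rec.snp_id in removed:
            continue
        accepted.append(rec)
        for other in candidates:
            if other.snp_id == rec.snp_id or other.snp_id in removed:
                continue
            if other.chrom != rec.chrom:
                continue
            if abs(other.pos - rec.pos) > config.window_kb * 1000:
                continue
            if config.ld_source is None:
                removed.add(other.snp_id)
            elif config.ld_source.r2(rec.snp_id, other.snp_id) >= config.ld_r2_max:
                removed.add(other.snp_id)
    accepted.sort(key=lambda r: (r.chrom, r.pos))
    return table.subset([r.snp_id for r in accepted])


def _eaf_side_ok(eaf: float | None, limit: float) -> bool:
    """Frequency is informative for strand resolution: outside [limit, 1-limit]."""
    return eaf is not None and (eaf < limit or eaf > 1 - limit)


def harmonize(
    exposure: TraitTable,
    outcome: TraitTable,
    palindrome_eaf_limit: float = 0.42,
) -> list[HarmonizedInstrument]:
    """Place outcome effects on the exposure's effect-allele orientation.

    For each SNP present in both tables: matching allele pairs are copied
    or sign-flipped; strand-complement pairs (A/G vs T/C) are complemented
    first; palindromic pairs (A/T, C/G) are oriented by comparing which
    side of 0.5 the two allele frequencies fall on, and dropped as
    ambiguous when either frequency lies inside
    ``[palindrome_eaf_limit, 1 - palindrome_eaf_limit]`` or is missing.
    Incompatible allele pairs are dropped with a reason. Dropped SNPs are
    returned alongside kept ones, distinguished by ``dropped_reason``.
    """
    out_index = outcome._index()
    shared = [r for r in exposure.records if r.snp_id in out_index]
    if not shared:
        raise NoOverlapError(
            f"no shared SNPs between {exposure.trait_id!r} and {outcome.trait_id!r}"
        )

    instruments: list[HarmonizedInstrument] = []
    for e in shared:
        o = out_index[e.snp_id]
        inst = HarmonizedInstrument(
            snp_id=e.snp_id,
            beta_exp=e.beta,
            se_exp=e.se,
            beta_out=o.beta,
            se_out=o.se,
            n_exp=e.n,
            eaf_exp=e.eaf,
            eaf_out=o.eaf,
            chrom=e.chrom,
            pos=e.pos,
        )
        e_pair = (e.effect_allele, e.other_allele)
        o_pair = (o.effect_allele, o.other_allele)

        if _is_palindromic(*e_pair):
            if set(o_pair) != set(e_pair):
                inst.dropped_reason = "incompatible alleles"
                instruments.append(inst)
                continue
            inst.flags.add("palindromic")
            if o_pair != e_pair:  # textual swap before frequency check
                _flip_outcome(inst)
                inst.flags.add("flipped")
            if not (
                _eaf_side_ok(inst.eaf_exp, palindrome_eaf_limit)
                and _eaf_side_ok(inst.eaf_out, palindrome_eaf_limit)
            ):
                inst.dropped_reason = "ambiguous palindrome"
                instruments.append(inst)
                continue
            same_side = (inst.eaf_exp < 0.5) == (inst.eaf_out < 0.5)
            if not same_side:  # frequencies disagree: the outcome is strand-flipped
                _flip_outcome(inst)
                inst.flags.add("strand_corrected")
            instruments.append(inst)
            continue

        comp_pair = (COMPLEMENT[o_pair[0]], COMPLEMENT[o_pair[1]])
        if set(o_pair) == set(e_pair):
            aligned = o_pair
        elif set(comp_pair) == set(e_pair):
            aligned = comp_pair
            inst.flags.add("strand_corrected")
        else:
            inst.dropped_reason = "incompatible alleles"
            instruments.append(inst)
            continue
        if aligned != e_pair:
            _flip_outcome(inst)
            inst.flags.add("flipped")
        instruments.append(inst)
    return instruments


def _flip_outcome(inst: HarmonizedInstrument) -> None:
    inst.beta_out = -inst.beta_out
    if inst.eaf_out is not None:
        inst.eaf_out = 1 - inst.eaf_out


def variance_explained(record: SumstatRecord) -> float:
    """Per-SNP variance explained:

        R^2 = 2 b^2 f (1-f) / (2 b^2 f (1-f) + 2 se^2 N f (1-f)).

    The effect-allele-frequency terms cancel algebraically (the value
    equals b^2/(b^2 + se^2 N)), but the frequency is still required so
    that a record that could not legitimately enter this formula fails
    loudly instead of being silently imputed.
    """
    if record.eaf is None:
        raise MissingEAFError(
            f"{record.snp_id}: effect-allele frequency required for variance explained"
        )
    if record.n < 3:
        raise DomainError("sample size must be at least 3")
    f = record.eaf
    num = 2 * record.beta**2 * f * (1 - f)
    den = num + 2 * record.se**2 * record.n * f * (1 - f)
    return num / den


def f_statistic(r2: float, n: int) -> float:
    """Instrument-strength F-statistic: F = R^2 (N-2) / (1 - R^2)."""
    if not (0 <= r2 < 1):
        raise DomainError("r2 must lie in [0, 1)")
    if n < 3:
        raise DomainError("sample size must be at least 3")
    return r2 * (n - 2) / (1 - r2)


def annotate_strength(
    instruments: Iterable[HarmonizedInstrument],
) -> list[HarmonizedInstrument]:
    """Fill in each instrument's R^2 and F from its exposure association."""
    out = []
    for inst in instruments:
        rec = SumstatRecord(
            snp_id=inst.snp_id,
            chrom=inst.chrom or "NA",
            pos=inst.pos or 1,
            effect_allele="A",
            other_allele="G",
            eaf=inst.eaf_exp,
            beta=inst.beta_exp,
            se=inst.se_exp,
            pvalue=0.5,
            n=inst.n_exp,
        )
        inst.r2 = variance_explained(rec)
        inst.f_stat = f_statistic(inst.r2, inst.n_exp)
        out.append(inst)
    return out


def filter_weak(
    instruments: Sequence[HarmonizedInstrument], f_min: float = 10.0
) -> tuple[list[HarmonizedInstrument], list[HarmonizedInstrument]]:
    """Split instruments into (retained, weak) at the F >= ``f_min`` rule.

    Weak instruments are flagged and their removal logged. If nothing
    survives, a :class:`ZeroInstrumentError` is raised: an analysis with
    only weak instruments is not interpretable.
    """
    retained, weak = [], []
    for inst in instruments:
        if inst.f_stat is None:
            raise DomainError(f"{inst.snp_id}: f_stat not computed before weak filter")
        if inst.f_stat < f_min:
            inst.flags.add("weak")
            inst.dropped_reason = "weak"
            weak.append(inst)
            logger.info("removed weak instrument %s (F = %.3f)", inst.snp_id, inst.f_stat)
        else:
            retained.append(inst)
    if not retained:
        raise ZeroInstrumentError(f"all {len(weak)} instruments weak (F < {f_min})")
    return retained, weak
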