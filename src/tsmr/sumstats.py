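"""Reading, validating and writing GWAS summary-statistics and result tables.

Summary statistics arrive as tab-delimited text with arbitrary column
names; a column map translates them onto the canonical per-SNP fields
(variant id, chromosome, position, effect/other allele, effect-allele
frequency, beta or ln(OR), standard error, p-value, sample size).
Validation drops malformed rows and counts them; a duplicated variant id
within one trait is an error because every downstream join is keyed on it.

Result tables mirror the shape of a typical MR report: one row per
(trait, method) with p-value, odds ratio, 95% CI bounds and the number of
instruments. Numbers are written with six significant digits and survive a
read/write round trip at that precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import (
    ConfigurationError,
    DuplicateSNPError,
    EmptyInputError,
)

VALID_ALLELES = frozenset({"A", "C", "G", "T"})

#: canonical field -> (dtype caster, mandatory?)
CANONICAL_FIELDS: dict[str, bool] = {
    "snp_id": True,
    "chrom": True,
    "pos": True,
    "effect_allele": True,
    "other_allele": True,
    "eaf": False,  # some catalogues omit allele frequencies
    "beta": True,
    "se": True,
    "pvalue": True,
    "n": True,
}


@dataclass(frozen=True)
class SumstatRecord:
    """One SNP's association with one trait.

    ``beta`` is the additive effect per copy of ``effect_allele``; for a
    binary trait it is the log odds ratio. ``eaf`` may be ``None`` when the
    source catalogue does not report allele frequencies.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    n: int
    eaf: float | None = None

    def validation_failure(self) -> str | None:
        """Return a human-readable reason this record is invalid, or None."""
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "non-SNV allele"
        if self.effect_allele == self.other_allele:
            return "identical alleles"
        if not (math.isfinite(self.beta)):
            return "non-finite beta"
        if not (math.isfinite(self.se) and self.se > 0):
            return "se not positive"
        if not (0 < self.pvalue <= 1):
            return "p-value outside (0, 1]"
        if self.eaf is not None and not (0 < self.eaf < 1):
            return "eaf outside (0, 1)"
        if self.n < 1:
            return "non-positive sample size"
        if self.pos < 1:
            return "non-positive position"
        return None


@dataclass
class TraitTable:
    """An ordered collection of per-SNP records for one trait."""

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    records: list[SumstatRecord] = field(default_factory=list)
    taxonomic_level: str | None = None  # phylum/class/order/family/genus
    n_dropped: int = 0  # rows discarded during validation on read

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ConfigurationError(
                f"trait_type must be 'quantitative' or 'binary', got {self.trait_type!r}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def get(self, snp_id: str) -> SumstatRecord:
        return self._index()[snp_id]

    def _index(self) -> dict[str, SumstatRecord]:
        return {r.snp_id: r for r in self.records}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [r.snp_id for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "pos": [r.pos for r in self.records],
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "eaf": [r.eaf for r in self.records],
                "beta": [r.beta for r in self.records],
                "se": [r.se for r in self.records],
                "pvalue": [r.pvalue for r in self.records],
                "n": [r.n for r in self.records],
            }
        )

    def subset(self, keep_ids: Iterable[str]) -> "TraitTable":
        """New table restricted to ``keep_ids``, preserving record order."""
        keep = set(keep_ids)
        return replace(
            self, records=[r for r in self.records if r.snp_id in keep], n_dropped=0
        )


def _coerce_record(row: Mapping[str, object], has_eaf: bool) -> SumstatRecord | None:
    """Build a record from one raw row; None if fields cannot be parsed."""
    try:
        eaf_raw = row.get("eaf") if has_eaf else None
        eaf = None
        if eaf_raw is not None and not (isinstance(eaf_raw, float) and math.isnan(eaf_raw)):
            eaf = float(eaf_raw)
        return SumstatRecord(
            snp_id=str(row["snp_id"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=str(row["effect_allele"]).upper(),
            other_allele=str(row["other_allele"]).upper(),
            eaf=eaf,
            beta=float(row["beta"]),
            se=float(row["se"]),
            pvalue=float(row["pvalue"]),
            n=int(float(row["n"])),
        )
    except (KeyError, TypeError, ValueError):
        return None


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str = "",
    trait_type: str = "quantitative",
    taxonomic_level: str | None = None,
) -> TraitTable:
    """Read a tab-delimited summary-statistics table into a validated TraitTable.

    ``column_map`` maps canonical field names to the file's column names;
    identity mapping is assumed for absent keys. Rows failing validation
    (bad alleles, non-positive SE, p outside (0,1], ...) are dropped and
    counted in ``TraitTable.n_dropped``. A duplicated variant id among the
    surviving rows raises :class:`DuplicateSNPError`.
    """
    path = Path(path)
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep="\t", dtype=str)

    rename = {}
    for canonical, mandatory in CANONICAL_FIELDS.items():
        source = column_map.get(canonical, canonical)
        if source in df.columns:
            rename[source] = canonical
        elif mandatory:
            raise ConfigurationError(
                f"{path.name}: mandatory column {canonical!r} "
                f"(mapped from {source!r}) not found"
            )
    df = df.rename(columns=rename)
    has_eaf = "eaf" in df.columns

    records: list[SumstatRecord] = []
    n_dropped = 0
    for row in df.to_dict(orient="records"):
        rec = _coerce_record(row, has_eaf)
        if rec is None or rec.validation_failure() is not None:
            n_dropped += 1
            continue
        records.append(rec)

    if not records:
        raise EmptyInputError(f"{path.name}: no valid summary-statistics rows")

    seen: set[str] = set()
    for rec in records:
        if rec.snp_id in seen:
            raise DuplicateSNPError(rec.snp_id)
        seen.add(rec.snp_id)

    return TraitTable(
        trait_id=trait_id or path.stem,
        trait_type=trait_type,
        taxonomic_level=taxonomic_level,
        records=records,
        n_dropped=n_dropped,
    )


def write_sumstats(table: TraitTable, path: str | Path) -> None:
    """Write a TraitTable back to canonical tab-delimited text."""
    df = table.to_dataframe()
    df["beta"] = df["beta"].map(format_number)
    df["se"] = df["se"].map(format_number)
    df["pvalue"] = df["pvalue"].map(format_number)
    df["eaf"] = df["eaf"].map(lambda v: "" if v is None else format_number(v))
    df.to_csv(path, sep="\t", index=False)


def format_number(value: float) -> str:
    """Six-significant-digit text form; scientific notation below 1e-3."""
    if value == 0:
        return "0"
    if abs(value) < 1e-3:
        return f"{value:.5e}"
    return f"{value:.6g}"


RESULT_COLUMNS = ("id", "method", "p", "or", "ci_low", "ci_high", "n_snp")


def write_results(results: Sequence[tuple[str, "MREstimate"]], path: str | Path) -> None:
    """Write (trait id, estimate) pairs as a 7-column tab-delimited table.

    Columns: id, method, p, OR, 95% CI bounds, number of SNPs. An empty
    result set produces a header-only file and a warning rather than an
    error, so batch drivers can always emit their report.
    """
    rows = []
    for trait_id, est in results:
        rows.append(
            {
                "id": trait_id,
                "method": est.method,
                "p": format_number(est.pvalue),
                "or": format_number(est.or_),
                "ci_low": format_number(est.ci_low),
                "ci_high": format_number(est.ci_high),
                "n_snp": est.n_snp,
            }
        )
    if not rows:
        warnings.warn("writing empty result table (header only)", stacklevel=2)
    pd.DataFrame(rows, columns=list(RESULT_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a result table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
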