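"""Reading, validation, and writing of GWAS summary-statistics tables.

The on-disk format is tab-separated UTF-8 text with one header line and the
canonical columns ``snp, chr, pos, ea, oa, eaf, beta, se, pval, n, n_case,
n_control``.  Missing effect-allele frequencies are written as ``NA``.
Arbitrary source headers are supported through a *dialect* mapping from
canonical names to the names actually present in the file.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Canonical column order of the tab-separated representation.
CANONICAL_COLUMNS = (
    "snp", "chr", "pos", "ea", "oa", "eaf",
    "beta", "se", "pval", "n", "n_case", "n_control",
)

MANDATORY_COLUMNS = ("snp", "chr", "pos", "ea", "oa", "beta", "se", "pval", "n")


class SumStatsError(ValueError):
    """Raised for unrecoverable summary-statistics I/O problems."""


@dataclass(frozen=True)
class SnpRecord:
    """One SNP-trait association.

    ``beta`` is the per-effect-allele estimate: log-odds for binary traits,
    SD units for continuous traits.  ``eaf`` may be ``None`` when the source
    did not report an effect-allele frequency.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pval: float
    n: int
    n_case: Optional[int] = None
    n_control: Optional[int] = None

    def validate(self) -> None:
        """Raise :class:`SumStatsError` if any field violates an invariant."""
        if self.effect_allele not in VALID_ALLELES:
            raise SumStatsError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise SumStatsError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise SumStatsError("effect and other allele identical")
        if not self.se > 0:
            raise SumStatsError(f"se must be positive, got {self.se}")
        if not (0 < self.pval <= 1):
            raise SumStatsError(f"pval must be in (0, 1], got {self.pval}")
        if self.pos < 1:
            raise SumStatsError(f"pos must be >= 1, got {self.pos}")
        if self.n < 1:
            raise SumStatsError(f"n must be positive, got {self.n}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise SumStatsError(f"eaf must be in (0, 1), got {self.eaf}")
        if not math.isfinite(self.beta):
            raise SumStatsError("beta must be finite")

    @property
    def is_palindromic(self) -> bool:
        """True for strand-ambiguous (A/T or G/C) allele pairs."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"G", "C"})


@dataclass
class SumStatsTable:
    """Summary statistics for one trait (one GWAS dataset)."""

    trait_id: str
    trait_type: str  # "continuous" | "binary"
    records: list[SnpRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise SumStatsError(f"unknown trait_type {self.trait_type!r}")

    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            rec.validate()
            if rec.snp_id in seen:
                raise SumStatsError(f"duplicate snp_id {rec.snp_id!r}")
            seen.add(rec.snp_id)
            if self.trait_type == "binary" and (rec.n_case is None or rec.n_control is None):
                raise SumStatsError(
                    f"binary trait {self.trait_id!r} requires n_case/n_control "
                    f"(missing for {rec.snp_id!r})"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_snp(self) -> dict[str, SnpRecord]:
        return {rec.snp_id: rec for rec in self.records}

    def subset(self, snp_ids: Iterable[str]) -> "SumStatsTable":
        """New table restricted to ``snp_ids``, input order preserved."""
        keep = set(snp_ids)
        return replace(self, records=[r for r in self.records if r.snp_id in keep])

    def to_frame(self) -> pd.DataFrame:
        """Canonical-column :class:`pandas.DataFrame` view of the records."""
        rows = [
            {
                "snp": r.snp_id, "chr": r.chrom, "pos": r.pos,
                "ea": r.effect_allele, "oa": r.other_allele, "eaf": r.eaf,
                "beta": r.beta, "se": r.se, "pval": r.pval, "n": r.n,
                "n_case": r.n_case, "n_control": r.n_control,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _parse_optional_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "NA":
        return None
    return int(value)


def _parse_optional_float(value) -> Optional[float]:
    if value is None or value == "NA":
        return None
    out = float(value)
    if math.isnan(out):
        return None
    return out


def read_sumstats(
    path,
    trait_id: str,
    trait_type: str = "continuous",
    dialect: Optional[Mapping[str, str]] = None,
) -> SumStatsTable:
    """Read a tab-separated summary-statistics file into a validated table.

    Parameters
    ----------
    path
        File to read.
    trait_id, trait_type
        Identity of the trait the file describes.
    dialect
        Mapping from canonical column names (:data:`CANONICAL_COLUMNS`) to
        the header names used in the file.  Unmapped canonical names are
        assumed to appear verbatim.

    Rows that fail a field invariant (non-SNV alleles, non-positive SE,
    out-of-range p-value, ...) are dropped and counted in a log message;
    a missing mandatory column is fatal.
    """
    dialect = dict(dialect or {})
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    colmap = {canon: dialect.get(canon, canon) for canon in CANONICAL_COLUMNS}
    missing = [colmap[c] for c in MANDATORY_COLUMNS if colmap[c] not in frame.columns]
    if missing:
        raise SumStatsError(
            f"{path}: missing mandatory column(s): {', '.join(sorted(missing))}"
        )

    records: list[SnpRecord] = []
    dropped = 0
    for row in frame.itertuples(index=False):
        raw = dict(zip(frame.columns, row))
        try:
            rec = SnpRecord(
                snp_id=str(raw[colmap["snp"]]),
                chrom=str(raw[colmap["chr"]]),
                pos=int(raw[colmap["pos"]]),
                effect_allele=str(raw[colmap["ea"]]).upper(),
                other_allele=str(raw[colmap["oa"]]).upper(),
                eaf=_parse_optional_float(raw.get(colmap["eaf"])) if colmap["eaf"] in frame.columns else None,
                beta=float(raw[colmap["beta"]]),
                se=float(raw[colmap["se"]]),
                pval=float(raw[colmap["pval"]]),
                n=int(float(raw[colmap["n"]])),
                n_case=_parse_optional_int(raw.get(colmap["n_case"])) if colmap["n_case"] in frame.columns else None,
                n_control=_parse_optional_int(raw.get(colmap["n_control"])) if colmap["n_control"] in frame.columns else None,
            )
            rec.validate()
        except (SumStatsError, ValueError):
            dropped += 1
            continue
        records.append(rec)

    if dropped:
        logger.info("%s: dropped %d invalid record(s)", path, dropped)

    table = SumStatsTable(trait_id=trait_id, trait_type=trait_type, records=records)
    table.validate()
    return table


def write_sumstats(table: SumStatsTable, path) -> None:
    """Write ``table`` to ``path`` in the canonical tab-separated format.

    Floats are serialized with ``repr`` round-trip precision; missing values
    become ``NA``.
    """

    def fmt(value) -> str:
        if value is None:
            return "NA"
        if isinstance(value, float):
            return repr(value)
        return str(value)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for r in table.records:
            fh.write(
                "\t".join(
                    fmt(v)
                    for v in (
                        r.snp_id, r.chrom, r.pos, r.effect_allele, r.other_allele,
                        r.eaf, r.beta, r.se, r.pval, r.n, r.n_case, r.n_control,
                    )
                )
                + "\n"
            )


def write_results_table(rows: Sequence[Mapping], path, columns: Sequence[str]) -> None:
    """Write generic analysis results as a tab-separated table."""
    pd.DataFrame(list(rows), columns=list(columns)).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )
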