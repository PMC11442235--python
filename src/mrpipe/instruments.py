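"""Instrumental-variable selection: significance filter, greedy LD clumping,
instrument-strength (F-statistic) filter, outcome-association and explicit
exclusion-list screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .sumstats import SnpRecord, SumStatsTable

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    """Thresholds governing instrument selection.

    Defaults follow genome-wide convention: exposure significance 5e-8
    (relaxed to 5e-5 when a mediator trait serves as the exposure), clumping
    at r^2 < 0.001 within a 10,000 kb window, minimum F-statistic 10, and
    removal of SNPs associated with the outcome at p < 1e-5.
    ``outcome_p_exclude=None`` disables the outcome screen.
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    f_min: float = 10.0
    outcome_p_exclude: Optional[float] = 1e-5
    exclusion_list: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if not 0 <= self.clump_r2 <= 1:
            raise ValueError("clump_r2 must be in [0, 1]")
        if self.clump_kb <= 0:
            raise ValueError("clump_kb must be positive")
        if self.f_min < 0:
            raise ValueError("f_min must be >= 0")
        self.exclusion_list = frozenset(self.exclusion_list)


class R2Lookup:
    """Pairwise LD (r-squared) source.

    ``get`` returns the r-squared for a SNP pair or ``None`` when the pair is
    unknown; callers decide how to treat missing pairs.
    """

    def get(self, snp_a: str, snp_b: str) -> Optional[float]:  # pragma: no cover
        raise NotImplementedError


class MatrixR2Lookup(R2Lookup):
    """LD lookup backed by a dense matrix over a fixed SNP list."""

    def __init__(self, snp_ids: Iterable[str], matrix: np.ndarray):
        self._index = {snp: i for i, snp in enumerate(snp_ids)}
        self._matrix = np.asarray(matrix, dtype=float)
        if self._matrix.shape != (len(self._index), len(self._index)):
            raise ValueError("matrix shape does not match snp_ids")

    def get(self, snp_a: str, snp_b: str) -> Optional[float]:
        ia, ib = self._index.get(snp_a), self._index.get(snp_b)
        if ia is None or ib is None:
            return None
        return float(self._matrix[ia, ib])


class TableR2Lookup(R2Lookup):
    """LD lookup from a 3-column table (snp_a, snp_b, r2); symmetric."""

    def __init__(self, pairs: Iterable[tuple[str, str, float]]):
        self._pairs: dict[frozenset[str], float] = {}
        for a, b, r2 in pairs:
            self._pairs[frozenset((a, b))] = float(r2)

    @classmethod
    def from_tsv(cls, path) -> "TableR2Lookup":
        frame = pd.read_csv(path, sep="\t")
        cols = list(frame.columns[:3])
        return cls(frame[cols].itertuples(index=False, name=None))

    def get(self, snp_a: str, snp_b: str) -> Optional[float]:
        if snp_a == snp_b:
            return 1.0
        return self._pairs.get(frozenset((snp_a, snp_b)))


def filter_by_pvalue(table: SumStatsTable, threshold: float) -> SumStatsTable:
    """Keep records with ``pval < threshold``; order preserved."""
    return replace(table, records=[r for r in table.records if r.pval < threshold])


def f_statistic(record: SnpRecord) -> float:
    """Per-SNP instrument strength, Wald form ``(beta / se)^2``."""
    return (record.beta / record.se) ** 2


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def ld_clump(
    table: SumStatsTable, r2_lookup: R2Lookup, config: SelectionConfig
) -> SumStatsTable:
    """Greedy p-value-ordered LD clumping.

    Repeatedly accept the lowest-p remaining SNP (ties broken by genomic
    coordinate) and discard every same-chromosome SNP within ``clump_kb``
    kilobases whose r-squared with it is >= ``clump_r2``.  An unknown
    r-squared for an in-window pair is treated as 1 (conservative removal)
    and logged.  Output is sorted by genomic coordinate.
    """
    window_bp = config.clump_kb * 1_000.0
    remaining = sorted(
        table.records, key=lambda r: (r.pval, _chrom_sort_key(r.chrom), r.pos)
    )
    kept: list[SnpRecord] = []
    missing_pairs = 0
    while remaining:
        lead = remaining.pop(0)
        kept.append(lead)
        survivors = []
        for rec in remaining:
            if rec.chrom == lead.chrom and abs(rec.pos - lead.pos) <= window_bp:
                r2 = r2_lookup.get(lead.snp_id, rec.snp_id)
                if r2 is None:
                    missing_pairs += 1
                    r2 = 1.0
                if r2 >= config.clump_r2:
                    continue  # clumped away
            survivors.append(rec)
        remaining = survivors
    if missing_pairs:
        logger.info(
            "ld_clump: %d in-window pair(s) missing from r2 source, treated as r2=1",
            missing_pairs,
        )
    kept.sort(key=lambda r: (_chrom_sort_key(r.chrom), r.pos))
    return replace(table, records=kept)


@dataclass
class SelectionResult:
    """Selected instruments plus the per-stage removal audit."""

    instruments: SumStatsTable
    stage_log: list[tuple[str, int, int]]  # (stage, removed, remaining)

    @property
    def is_empty(self) -> bool:
        return len(self.instruments) == 0

    def stage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stage_log, columns=["stage", "removed", "remaining"])


def select_instruments(
    exposure: SumStatsTable,
    outcome: Optional[SumStatsTable],
    r2_lookup: R2Lookup,
    config: SelectionConfig,
) -> SelectionResult:
    """Full selection cascade.

    Stages, in order: exposure p-value filter, LD clumping, F >= ``f_min``,
    removal of SNPs associated with the outcome at ``outcome_p_exclude``, and
    removal of ``exclusion_list`` members (confounder-associated SNPs).
    """
    log: list[tuple[str, int, int]] = []
    current = exposure

    def record_stage(stage: str, nxt: SumStatsTable) -> SumStatsTable:
        log.append((stage, len(current) - len(nxt), len(nxt)))
        return nxt

    current = record_stage("pvalue", filter_by_pvalue(current, config.p_threshold))
    current = record_stage("clump", ld_clump(current, r2_lookup, config))
    current = record_stage(
        "f_stat",
        replace(current, records=[r for r in current.records if f_statistic(r) >= config.f_min]),
    )

    if outcome is not None and config.outcome_p_exclude is not None:
        outcome_p = {r.snp_id: r.pval for r in outcome.records}
        kept = [
            r
            for r in current.records
            if outcome_p.get(r.snp_id, 1.0) >= config.outcome_p_exclude
        ]
        current = record_stage("outcome_assoc", replace(current, records=kept))
    else:
        current = record_stage("outcome_assoc", current)

    current = record_stage(
        "exclusion_list",
        replace(
            current,
            records=[r for r in current.records if r.snp_id not in config.exclusion_list],
        ),
    )

    for stage, removed, remaining in log:
        logger.info("select_instruments[%s]: removed=%d remaining=%d", stage, removed, remaining)
    if not current.records:
        logger.warning("select_instruments: no instruments survive for %s", exposure.trait_id)
    return SelectionResult(instruments=current, stage_log=log)
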