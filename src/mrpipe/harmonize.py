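"""Effect-allele harmonization between exposure and outcome tables.

Aligns every shared SNP so both betas refer to the exposure's effect allele.
Palindromic (A/T, G/C) pairs are oriented by allele frequency when both
frequencies fall outside the ambiguity zone, and dropped otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .sumstats import SnpRecord, SumStatsTable

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: allele frequencies in this closed interval cannot orient a palindromic SNP
AMBIGUITY_ZONE = (0.42, 0.58)

KEPT = "kept"
FLIPPED = "flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISMATCH = "dropped_mismatch"


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome effects for one SNP on a common effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: Optional[float]
    eaf_out: Optional[float]
    action: str
    pval_exp: float = 1.0
    pval_out: float = 1.0

    @property
    def ratio(self) -> float:
        """Per-SNP Wald ratio beta_out / beta_exp."""
        return self.beta_out / self.beta_exp


@dataclass
class InstrumentSet:
    """Harmonized instrument effects for one exposure-outcome analysis."""

    exposure_id: str
    outcome_id: str
    pairs: list[HarmonizedPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def arrays(self):
        import numpy as np

        return (
            np.array([p.beta_exp for p in self.pairs]),
            np.array([p.se_exp for p in self.pairs]),
            np.array([p.beta_out for p in self.pairs]),
            np.array([p.se_out for p in self.pairs]),
        )

    def drop(self, snp_id: str) -> "InstrumentSet":
        return InstrumentSet(
            self.exposure_id,
            self.outcome_id,
            [p for p in self.pairs if p.snp_id != snp_id],
        )


@dataclass
class HarmonizationAudit:
    """Per-SNP disposition of the harmonization pass."""

    actions: list[tuple[str, str]] = field(default_factory=list)  # (snp_id, action)

    def count(self, action: str) -> int:
        return sum(1 for _, a in self.actions if a == action)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.actions, columns=["snp", "action"])


def _in_ambiguity_zone(eaf: Optional[float]) -> bool:
    return eaf is None or AMBIGUITY_ZONE[0] <= eaf <= AMBIGUITY_ZONE[1]


def _classify(exp: SnpRecord, out: SnpRecord) -> str:
    """Decide the harmonization action for one shared SNP."""
    e_ea, e_oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele

    if exp.is_palindromic or out.is_palindromic:
        if {e_ea, e_oa} != {o_ea, o_oa} and {e_ea, e_oa} != {
            _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
        }:
            return DROPPED_MISMATCH
        # Allele labels cannot orient a strand-ambiguous pair (the complement
        # of A/T is T/A); only the frequencies can.
        if _in_ambiguity_zone(exp.eaf) or _in_ambiguity_zone(out.eaf):
            return DROPPED_PALINDROMIC
        same_minor = (exp.eaf < 0.5) == (out.eaf < 0.5)
        return KEPT if same_minor else FLIPPED

    if (e_ea, e_oa) == (o_ea, o_oa):
        return KEPT
    if (e_ea, e_oa) == (o_oa, o_ea):
        return FLIPPED
    comp = (_COMPLEMENT[o_ea], _COMPLEMENT[o_oa])
    if (e_ea, e_oa) == comp:
        return KEPT
    if (e_ea, e_oa) == (comp[1], comp[0]):
        return FLIPPED
    return DROPPED_MISMATCH


def harmonize(
    exposure: SumStatsTable, outcome: SumStatsTable
) -> tuple[InstrumentSet, HarmonizationAudit]:
    """Harmonize ``outcome`` effects onto the exposure's effect alleles.

    Returns the kept/flipped pairs (exposure record order) and a per-SNP
    audit covering the full intersection.
    """
    out_by_snp = outcome.by_snp()
    pairs: list[HarmonizedPair] = []
    audit = HarmonizationAudit()

    for exp in exposure.records:
        out = out_by_snp.get(exp.snp_id)
        if out is None:
            continue
        action = _classify(exp, out)
        audit.actions.append((exp.snp_id, action))
        if action in (DROPPED_PALINDROMIC, DROPPED_MISMATCH):
            continue
        beta_out, eaf_out = out.beta, out.eaf
        if action == FLIPPED:
            beta_out = -beta_out
            eaf_out = None if eaf_out is None else 1.0 - eaf_out
        pairs.append(
            HarmonizedPair(
                snp_id=exp.snp_id,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=beta_out,
                se_out=out.se,
                eaf_exp=exp.eaf,
                eaf_out=eaf_out,
                action=action,
                pval_exp=exp.pval,
                pval_out=out.pval,
            )
        )

    return InstrumentSet(exposure.trait_id, outcome.trait_id, pairs), audit
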