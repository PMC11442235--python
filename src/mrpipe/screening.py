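"""Batch exposure-outcome screening with FDR-tiered classification.

Each exposure-outcome pair runs the full single-pair pipeline (instrument
selection, harmonization, estimation, sensitivity) and the IVW p-values are
Benjamini-Hochberg adjusted within each outcome's family of exposures.
Tiers: ``highly_correlative`` (adjusted p < 0.05), ``suggestive`` (raw
p < 0.05 and 0.05 <= adjusted p < 0.2), else ``null``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import MREstimate, estimate_all
from .harmonize import harmonize
from .instruments import R2Lookup, SelectionConfig, select_instruments
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import SumStatsTable

logger = logging.getLogger(__name__)

TIER_HIGH = "highly_correlative"
TIER_SUGGESTIVE = "suggestive"
TIER_NULL = "null"

REASON_OK = "ok"
REASON_NO_INSTRUMENTS = "no_instruments"
REASON_TOO_FEW_SNPS = "too_few_snps"


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adj[i] = min over j with p(j) >= p(i) of m * p(j) / rank(j)``, capped
    at 1; monotone in the raw p-values and never smaller than them.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def assign_tier(pval: Optional[float], adj_pval: Optional[float]) -> str:
    """Pure tier rule on (raw p, adjusted p)."""
    if pval is None or adj_pval is None:
        return TIER_NULL
    if adj_pval < 0.05:
        return TIER_HIGH
    if pval < 0.05 and adj_pval < 0.2:
        return TIER_SUGGESTIVE
    return TIER_NULL


@dataclass
class ScreenConfig:
    """Orchestration knobs for a screening run."""

    selection: SelectionConfig = field(default_factory=SelectionConfig)
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median", "weighted_mode")
    n_boot: int = 1000
    seed: int = 0
    fdr_family: str = "per_outcome"  # per_outcome | global
    with_sensitivity: bool = True

    def __post_init__(self) -> None:
        if self.fdr_family not in ("per_outcome", "global"):
            raise ValueError(f"unknown fdr_family {self.fdr_family!r}")


@dataclass
class ScreenResult:
    """One exposure-outcome row of the screening table."""

    exposure_id: str
    outcome_id: str
    n_snps: int
    beta: Optional[float] = None
    se: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    or_: Optional[float] = None
    pval: Optional[float] = None
    adj_pval: Optional[float] = None
    tier: str = TIER_NULL
    reason: str = REASON_OK
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    sensitivity: Optional[SensitivityReport] = None

    def as_row(self) -> dict:
        return {
            "exposure": self.exposure_id, "outcome": self.outcome_id,
            "n_snps": self.n_snps, "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "or": self.or_,
            "pval": self.pval, "adj_pval": self.adj_pval,
            "tier": self.tier, "reason": self.reason,
        }


def _effective_outcome_n(outcome: SumStatsTable) -> Optional[float]:
    for rec in outcome.records:
        if rec.n_case and rec.n_control:
            return 4.0 / (1.0 / rec.n_case + 1.0 / rec.n_control)
        if rec.n:
            return float(rec.n)
    return None


def _screen_pair(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    r2_lookup: R2Lookup,
    config: ScreenConfig,
) -> ScreenResult:
    selection = select_instruments(exposure, outcome, r2_lookup, config.selection)
    if selection.is_empty:
        return ScreenResult(exposure.trait_id, outcome.trait_id, 0,
                            reason=REASON_NO_INSTRUMENTS)
    instruments, _ = harmonize(selection.instruments, outcome)
    if len(instruments) < 2:
        return ScreenResult(exposure.trait_id, outcome.trait_id, len(instruments),
                            reason=REASON_TOO_FEW_SNPS)
    estimates = estimate_all(
        instruments, methods=config.methods, n_boot=config.n_boot, seed=config.seed
    )
    primary = estimates.get("ivw") or estimates.get("ivw_fe")
    sens = None
    if config.with_sensitivity:
        n_exp = exposure.records[0].n if exposure.records else None
        sens = sensitivity_report(instruments, n_exp=n_exp,
                                  n_out=_effective_outcome_n(outcome))
    return ScreenResult(
        exposure_id=exposure.trait_id, outcome_id=outcome.trait_id,
        n_snps=len(instruments), beta=primary.beta, se=primary.se,
        ci_low=primary.ci_low, ci_high=primary.ci_high, or_=primary.or_,
        pval=primary.pval, estimates=estimates, sensitivity=sens,
    )


def _apply_fdr(results: list[ScreenResult], family: str) -> None:
    if family == "global":
        groups = {None: [r for r in results if r.pval is not None]}
    else:
        groups = {}
        for r in results:
            if r.pval is not None:
                groups.setdefault(r.outcome_id, []).append(r)
    for members in groups.values():
        if not members:
            continue
        adjusted = bh_fdr([r.pval for r in members])
        for r, adj in zip(members, adjusted):
            r.adj_pval = float(adj)
            r.tier = assign_tier(r.pval, r.adj_pval)


def screen(
    exposures: Sequence[SumStatsTable],
    outcomes: Sequence[SumStatsTable],
    r2_lookup: R2Lookup,
    config: Optional[ScreenConfig] = None,
) -> list[ScreenResult]:
    """Run MR for every exposure against every outcome and tier the results."""
    config = config or ScreenConfig()
    results: list[ScreenResult] = []
    for outcome in outcomes:
        for exposure in exposures:
            results.append(_screen_pair(exposure, outcome, r2_lookup, config))
    _apply_fdr(results, config.fdr_family)
    logger.info(
        "screen: %d pairs, %d highly correlative, %d suggestive",
        len(results),
        sum(r.tier == TIER_HIGH for r in results),
        sum(r.tier == TIER_SUGGESTIVE for r in results),
    )
    return results


def reverse_screen(
    outcomes_as_exposures: Sequence[SumStatsTable],
    exposures_as_outcomes: Sequence[SumStatsTable],
    r2_lookup: R2Lookup,
    config: Optional[ScreenConfig] = None,
) -> list[ScreenResult]:
    """Identical machinery with the trait roles swapped.

    Pass a relaxed ``selection.p_threshold`` in ``config`` when the
    role-swapped exposures have few genome-wide-significant SNPs.
    """
    return screen(outcomes_as_exposures, exposures_as_outcomes, r2_lookup, config)


def results_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])
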