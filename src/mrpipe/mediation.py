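"""Multivariable MR and the two-step mediation decomposition.

The decomposition follows the product-of-coefficients scheme:

* step 1 - univariable MR of the mediator on the exposure gives ``beta_a``;
* step 2 - multivariable MR of the outcome on exposure and mediator jointly
  gives the conditional mediator effect ``beta_b``;
* step 3 - ``mediation = beta_a * beta_b``; ``direct = total - mediation``;
  ``proportion = mediation / total * 100`` where ``total`` is the
  univariable exposure-outcome IVW estimate.

Mediation-effect inference uses the delta method (Sobel form):
``var = beta_a^2 * var_b + beta_b^2 * var_a``.  The proportion CI assumes
independence of the mediation and total estimates and is suppressed when the
mediation CI spans zero (the ratio's sign is then unidentified).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats

from .estimators import Z95, InsufficientInstrumentsError, ivw
from .harmonize import harmonize
from .instruments import (
    R2Lookup,
    SelectionConfig,
    filter_by_pvalue,
    ld_clump,
    select_instruments,
)
from .sumstats import SumStatsTable

logger = logging.getLogger(__name__)


class MediationPipelineError(RuntimeError):
    """A mediation step could not proceed (e.g. empty instrument set)."""


@dataclass(frozen=True)
class Estimate:
    """A (beta, se) pair with normal-theory helpers."""

    beta: float
    se: float

    @property
    def ci(self) -> tuple[float, float]:
        return self.beta - Z95 * self.se, self.beta + Z95 * self.se

    @property
    def pval(self) -> float:
        if self.se == 0:
            return 1.0 if self.beta == 0 else 0.0
        return float(2.0 * stats.norm.sf(abs(self.beta) / self.se))


@dataclass
class MVMRInput:
    """Per-SNP effects on exposure, mediator, and outcome, on common alleles."""

    snp_ids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_mediator: np.ndarray
    se_mediator: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.snp_ids)
        arrays = (self.beta_exposure, self.se_exposure, self.beta_mediator,
                  self.se_mediator, self.beta_out, self.se_out)
        if any(a.shape != (k,) for a in arrays):
            raise ValueError("all MVMR arrays must share one length")
        if k < 3:
            raise InsufficientInstrumentsError(f"MVMR needs >= 3 SNPs, got {k}")
        if not np.all(np.isfinite(np.concatenate(arrays))):
            raise ValueError("MVMR input must be complete (no NaN/inf rows)")

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class MVMRResult:
    exposure_direct: Estimate  # conditional exposure effect
    mediator_conditional: Estimate  # beta_b
    q: float
    n_snps: int


def mvmr_ivw(mvmr_input: MVMRInput) -> MVMRResult:
    """Multivariable IVW: zero-intercept WLS of outcome betas on exposure and
    mediator betas with weights ``1 / se_out^2``; SEs carry the multiplicative
    random-effects inflation ``sqrt(max(1, Q / (k - 2)))``.
    """
    x = np.column_stack([mvmr_input.beta_exposure, mvmr_input.beta_mediator])
    y = mvmr_input.beta_out
    w = 1.0 / mvmr_input.se_out**2
    k = len(mvmr_input)

    # a degenerate all-zero column carries no information: drop it from the
    # fit and report a null coefficient with infinite SE
    active = [j for j in range(2) if np.any(x[:, j] != 0)]
    if len(active) < 2:
        if not active:
            raise np.linalg.LinAlgError("MVMR design is all zeros")
        xa = x[:, active]
        xtwx = xa.T @ (xa * w[:, None])
        cov = np.linalg.inv(xtwx)
        coef_a = cov @ xa.T @ (w * y)
        resid = y - xa @ coef_a
        q = float(np.sum(w * resid**2))
        scale = max(1.0, q / (k - 1)) if k > 1 else 1.0
        se_a = float(np.sqrt(cov[0, 0] * scale))
        estimates = [Estimate(0.0, math.inf), Estimate(0.0, math.inf)]
        estimates[active[0]] = Estimate(float(coef_a[0]), se_a)
        return MVMRResult(exposure_direct=estimates[0],
                          mediator_conditional=estimates[1], q=q, n_snps=k)

    xtwx = x.T @ (x * w[:, None])
    cond = np.linalg.cond(xtwx)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "MVMR design is rank-deficient: exposure and mediator instrument "
            "effects are collinear"
        )
    cov_unscaled = np.linalg.inv(xtwx)
    coef = cov_unscaled @ x.T @ (w * y)
    resid = y - x @ coef
    q = float(np.sum(w * resid**2))
    scale = max(1.0, q / (k - 2)) if k > 2 else 1.0
    ses = np.sqrt(np.diag(cov_unscaled) * scale)
    return MVMRResult(
        exposure_direct=Estimate(float(coef[0]), float(ses[0])),
        mediator_conditional=Estimate(float(coef[1]), float(ses[1])),
        q=q,
        n_snps=k,
    )


@dataclass
class MediationResult:
    """Product-of-coefficients decomposition for one exposure/mediator/outcome."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    total_effect: float
    total_se: float
    beta_a: float
    se_a: float
    beta_b: float
    se_b: float
    mediation_effect: float
    mediation_se: float
    mediation_ci_low: float
    mediation_ci_high: float
    mediation_pval: float
    direct_effect: float
    proportion_mediated: Optional[float]  # percent
    proportion_ci_low: Optional[float]
    proportion_ci_high: Optional[float]

    def as_row(self) -> dict:
        return {
            "exposure": self.exposure_id, "mediator": self.mediator_id,
            "outcome": self.outcome_id, "total_effect": self.total_effect,
            "direct_effect": self.direct_effect,
            "mediation_effect": self.mediation_effect,
            "mediation_ci_low": self.mediation_ci_low,
            "mediation_ci_high": self.mediation_ci_high,
            "pval": self.mediation_pval,
            "proportion": self.proportion_mediated,
            "proportion_ci_low": self.proportion_ci_low,
            "proportion_ci_high": self.proportion_ci_high,
        }


def mediate(
    beta_a: Estimate,
    beta_b: Estimate,
    total: Estimate,
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
) -> MediationResult:
    """Combine step estimates into the mediation decomposition.

    ``mediation = beta_a * beta_b`` with the delta-method variance
    ``beta_a^2 var_b + beta_b^2 var_a``; ``direct = total - mediation`` holds
    as an exact identity.  The proportion CI is reported only when the
    mediation CI excludes zero and the total effect is nonzero.
    """
    mediation = beta_a.beta * beta_b.beta
    var_med = beta_a.beta**2 * beta_b.se**2 + beta_b.beta**2 * beta_a.se**2
    se_med = math.sqrt(var_med)
    ci_low, ci_high = mediation - Z95 * se_med, mediation + Z95 * se_med
    if se_med == 0:
        pval = 1.0 if mediation == 0 else 0.0
    else:
        pval = float(2.0 * stats.norm.sf(abs(mediation) / se_med))
    direct = total.beta - mediation

    proportion = prop_lo = prop_hi = None
    if total.beta != 0:
        proportion = mediation / total.beta * 100.0
        ci_spans_zero = ci_low <= 0.0 <= ci_high
        if not ci_spans_zero:
            # delta method on the ratio, mediation and total treated as
            # independent (they come from non-overlapping estimation steps)
            var_ratio = (
                var_med / total.beta**2
                + mediation**2 * total.se**2 / total.beta**4
            )
            se_prop = math.sqrt(var_ratio) * 100.0
            prop_lo, prop_hi = proportion - Z95 * se_prop, proportion + Z95 * se_prop

    return MediationResult(
        exposure_id=exposure_id, mediator_id=mediator_id, outcome_id=outcome_id,
        total_effect=total.beta, total_se=total.se,
        beta_a=beta_a.beta, se_a=beta_a.se,
        beta_b=beta_b.beta, se_b=beta_b.se,
        mediation_effect=mediation, mediation_se=se_med,
        mediation_ci_low=ci_low, mediation_ci_high=ci_high,
        mediation_pval=pval, direct_effect=direct,
        proportion_mediated=proportion,
        proportion_ci_low=prop_lo, proportion_ci_high=prop_hi,
    )


def build_mvmr_input(
    exposure: SumStatsTable,
    mediator: SumStatsTable,
    outcome: SumStatsTable,
    r2_lookup: R2Lookup,
    exposure_p: float = 5e-8,
    mediator_p: float = 5e-5,
    selection: Optional[SelectionConfig] = None,
) -> MVMRInput:
    """Assemble the joint instrument set for multivariable MR.

    Candidates are the union of SNPs passing the exposure threshold and SNPs
    passing the (relaxed) mediator threshold; the union is clumped jointly on
    each SNP's better p-value, then harmonized to the exposure's alleles with
    complete rows in all three tables required.
    """
    selection = selection or SelectionConfig(p_threshold=exposure_p)

    exp_hits = {r.snp_id for r in filter_by_pvalue(exposure, exposure_p).records}
    med_hits = {r.snp_id for r in filter_by_pvalue(mediator, mediator_p).records}
    candidates = exp_hits | med_hits
    if not candidates:
        raise MediationPipelineError("MVMR: no SNP passes either threshold")

    med_p = {r.snp_id: r.pval for r in mediator.records}
    union_records = []
    for rec in exposure.records:
        if rec.snp_id not in candidates:
            continue
        best_p = min(rec.pval, med_p.get(rec.snp_id, 1.0))
        union_records.append(replace(rec, pval=best_p))
    union = replace(exposure, records=union_records)
    clumped = ld_clump(union, r2_lookup, selection)
    keep = {
        r.snp_id for r in clumped.records if r.snp_id not in selection.exclusion_list
    }

    exp_sub = exposure.subset(keep)
    med_set, _ = harmonize(exp_sub, mediator)
    out_set, _ = harmonize(exp_sub, outcome)
    med_by = {p.snp_id: p for p in med_set}
    out_by = {p.snp_id: p for p in out_set}
    shared = [s for s in (r.snp_id for r in exp_sub.records) if s in med_by and s in out_by]
    if len(shared) < 3:
        raise MediationPipelineError(
            f"MVMR: only {len(shared)} complete instrument rows after harmonization"
        )

    return MVMRInput(
        snp_ids=shared,
        beta_exposure=np.array([med_by[s].beta_exp for s in shared]),
        se_exposure=np.array([med_by[s].se_exp for s in shared]),
        beta_mediator=np.array([med_by[s].beta_out for s in shared]),
        se_mediator=np.array([med_by[s].se_out for s in shared]),
        beta_out=np.array([out_by[s].beta_out for s in shared]),
        se_out=np.array([out_by[s].se_out for s in shared]),
    )


@dataclass
class MediationPipelineResult:
    result: MediationResult
    step1_estimate: Estimate  # beta_a (univariable exposure -> mediator)
    step2: MVMRResult  # beta_b (conditional mediator -> outcome)
    total_estimate: Estimate  # univariable exposure -> outcome IVW


def _univariable_ivw(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    r2_lookup: R2Lookup,
    selection: SelectionConfig,
    step_name: str,
) -> Estimate:
    sel = select_instruments(exposure, outcome, r2_lookup, selection)
    if sel.is_empty:
        raise MediationPipelineError(f"{step_name}: empty instrument set")
    instruments, _ = harmonize(sel.instruments, outcome)
    try:
        est = ivw(instruments, random_effects=True)
    except InsufficientInstrumentsError as err:
        raise MediationPipelineError(f"{step_name}: {err}") from err
    return Estimate(est.beta, est.se)


def run_mediation_pipeline(
    exposure: SumStatsTable,
    mediator: SumStatsTable,
    outcome: SumStatsTable,
    r2_lookup: R2Lookup,
    selection: Optional[SelectionConfig] = None,
    mediator_p: float = 5e-5,
) -> MediationPipelineResult:
    """Run the three-step decomposition end to end.

    Step 1 estimates ``beta_a`` by univariable MR of the mediator on the
    exposure (genome-wide instrument threshold); step 2 estimates ``beta_b``
    by multivariable MR with the mediator instrumented at the relaxed
    threshold; step 3 takes the total effect from univariable
    exposure-outcome IVW and combines everything with :func:`mediate`.
    """
    selection = selection or SelectionConfig()

    beta_a = _univariable_ivw(exposure, mediator, r2_lookup, selection, "step1(beta_a)")
    mvmr_input = build_mvmr_input(
        exposure, mediator, outcome, r2_lookup,
        exposure_p=selection.p_threshold, mediator_p=mediator_p,
        selection=selection,
    )
    step2 = mvmr_ivw(mvmr_input)
    total = _univariable_ivw(exposure, outcome, r2_lookup, selection, "step3(total)")

    result = mediate(
        beta_a, step2.mediator_conditional, total,
        exposure_id=exposure.trait_id, mediator_id=mediator.trait_id,
        outcome_id=outcome.trait_id,
    )
    return MediationPipelineResult(
        result=result, step1_estimate=beta_a, step2=step2, total_estimate=total
    )
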