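"""Heterogeneity, pleiotropy, influence, and directionality diagnostics."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import InsufficientInstrumentsError, Z95, egger, ivw
from .harmonize import InstrumentSet

EXPOSURE_TO_OUTCOME = "exposure_to_outcome"
OUTCOME_TO_EXPOSURE = "outcome_to_exposure"


def cochran_q(instruments: InstrumentSet) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic around the fixed-effect IVW point.

    Returns ``(q, df, pval)`` with ``df = k - 1`` and a chi-square upper-tail
    p-value; p > 0.05 is conventionally read as no heterogeneity.
    """
    k = len(instruments)
    if k < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q needs >= 2 SNPs, got {k}")
    beta_exp, _, beta_out, se_out = instruments.arrays()
    ratios = beta_out / beta_exp
    weights = beta_exp**2 / se_out**2
    beta_fe = np.sum(weights * ratios) / np.sum(weights)
    q = float(np.sum(weights * (ratios - beta_fe) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


@dataclass(frozen=True)
class LeaveOneOutRow:
    snp_id: str
    beta_without: float
    se_without: float
    flagged: bool  # removal moves the estimate outside the full-set 95% CI


def leave_one_out(instruments: InstrumentSet) -> list[LeaveOneOutRow]:
    """Re-estimate (random-effects IVW) with each SNP removed in turn.

    A SNP is flagged when the estimate without it falls outside the full-set
    95% confidence interval, i.e. that single SNP drives the result.
    """
    k = len(instruments)
    if k < 3:
        raise InsufficientInstrumentsError(f"leave-one-out needs >= 3 SNPs, got {k}")
    full = ivw(instruments, random_effects=True)
    rows = []
    for pair in instruments:
        sub = ivw(instruments.drop(pair.snp_id), random_effects=True)
        flagged = not (full.ci_low <= sub.beta <= full.ci_high)
        rows.append(LeaveOneOutRow(pair.snp_id, sub.beta, sub.se, flagged))
    return rows


def _r2_from_t(t: np.ndarray, n: float) -> np.ndarray:
    return t**2 / (t**2 + n - 2.0)


def steiger_test(
    instruments: InstrumentSet, n_exp: int, n_out: float
) -> tuple[str, float]:
    """Directionality test comparing variance explained on each side.

    Per-SNP variance explained is ``t^2 / (t^2 + n - 2)`` with ``t`` the Wald
    statistic; totals are compared via Fisher-transformed correlations.  For
    binary outcomes pass the effective sample size as ``n_out``.
    Returns ``(direction, pval)``.
    """
    if n_exp is None or n_out is None or n_exp <= 3 or n_out <= 3:
        raise ValueError("steiger_test requires sample sizes > 3 on both sides")
    beta_exp, se_exp, beta_out, se_out = instruments.arrays()
    r2_exp = float(np.sum(_r2_from_t(beta_exp / se_exp, n_exp)))
    r2_out = float(np.sum(_r2_from_t(beta_out / se_out, n_out)))
    r2_exp = min(r2_exp, 1.0 - 1e-12)
    r2_out = min(r2_out, 1.0 - 1e-12)
    direction = EXPOSURE_TO_OUTCOME if r2_exp > r2_out else OUTCOME_TO_EXPOSURE
    z = (math.atanh(math.sqrt(r2_exp)) - math.atanh(math.sqrt(r2_out))) / math.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out - 3)
    )
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return direction, pval


def funnel_data(instruments: InstrumentSet) -> pd.DataFrame:
    """Per-SNP (ratio, precision) table for funnel plots; no inference."""
    if len(instruments) < 1:
        raise InsufficientInstrumentsError("funnel_data needs >= 1 SNP")
    rows = [
        {
            "snp": p.snp_id,
            "ratio": p.beta_out / p.beta_exp,
            "precision": abs(p.beta_exp) / p.se_out,
        }
        for p in instruments
    ]
    return pd.DataFrame(rows, columns=["snp", "ratio", "precision"])


@dataclass
class SensitivityReport:
    """Full diagnostic battery for one instrument set."""

    cochran_q: float
    q_df: int
    q_pval: float
    egger_intercept: Optional[float]
    egger_intercept_p: Optional[float]
    leave_one_out: list[LeaveOneOutRow] = field(default_factory=list)
    steiger_direction: Optional[str] = None
    steiger_pval: Optional[float] = None
    steiger_inconclusive: Optional[bool] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cochran_q": self.cochran_q,
                    "q_df": self.q_df,
                    "q_pval": self.q_pval,
                    "egger_intercept": self.egger_intercept,
                    "egger_intercept_p": self.egger_intercept_p,
                    "steiger_direction": self.steiger_direction,
                    "steiger_pval": self.steiger_pval,
                }
            ]
        )

    def loo_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "snp": r.snp_id,
                    "beta_without": r.beta_without,
                    "se_without": r.se_without,
                    "flagged": r.flagged,
                }
                for r in self.leave_one_out
            ]
        )


def sensitivity_report(
    instruments: InstrumentSet,
    n_exp: Optional[int] = None,
    n_out: Optional[float] = None,
) -> SensitivityReport:
    """Assemble every diagnostic the instrument count permits."""
    q, df, q_p = cochran_q(instruments)
    report = SensitivityReport(cochran_q=q, q_df=df, q_pval=q_p,
                               egger_intercept=None, egger_intercept_p=None)
    if len(instruments) >= 3:
        egg = egger(instruments)
        report.egger_intercept = egg.egger_intercept
        report.egger_intercept_p = egg.egger_intercept_p
        report.leave_one_out = leave_one_out(instruments)
    if n_exp is not None and n_out is not None:
        direction, pval = steiger_test(instruments, n_exp, n_out)
        report.steiger_direction = direction
        report.steiger_pval = pval
        report.steiger_inconclusive = pval >= 0.05
    return report
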