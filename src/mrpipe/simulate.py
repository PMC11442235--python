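"""Synthetic GWAS summary statistics with a known causal structure.

A single structural model generates an exposure, a continuous mediator, and a
binary outcome:

* instrument SNPs carry exposure effects ``g_j ~ N(0, exposure_effect_sd^2)``;
* the mediator inherits ``beta_a * g_j`` plus optional mediator-specific
  effects ``m_j`` on a disjoint SNP set;
* the outcome receives ``delta * g_j + beta_b * (beta_a * g_j + m_j)`` plus a
  per-SNP pleiotropy term aligned to the exposure-increasing allele.

Observed effects add sampling noise with the standard summary-statistic
approximation ``se = 1 / sqrt(2 * n * maf * (1 - maf))`` (binary traits use
the effective sample size ``4 / (1/n_case + 1/n_control)`` on the log-odds
scale).  SNPs are laid out in LD blocks separated by more than the default
clumping window, and observed effects are correlated within blocks.

Separate RNG streams drive the SNP panel, the effect draws, the sampling
noise, and the allele-coding corruptions, so toggling ``flip_frac`` or
``palindromic_frac`` perturbs nothing else — the property harmonization
round-trip tests rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .sumstats import SnpRecord, SumStatsTable

#: within-block SNP spacing (bp); keeps every block far inside the clump window
_BLOCK_SPAN_BP = 1_000
#: gap between consecutive block starts (bp); > 10,000 kb so blocks never clump
_BLOCK_GAP_BP = 20_000_000
_N_CHROMS = 22

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_NON_PALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimConfig:
    """Generating parameters for one exposure/mediator/outcome triple."""

    n_snps: int = 200
    n_instruments: int = 50
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_exp: int = 50_000
    n_med: int = 50_000
    n_case: int = 8_000
    n_control: int = 192_000
    n_out: Optional[int] = None  # defaults to n_case + n_control
    beta_a: float = 0.0  # exposure -> mediator
    beta_b: float = 0.0  # mediator -> outcome
    delta: float = 0.0  # direct exposure -> outcome
    pleio_mode: str = "none"  # none | balanced | directional
    pleio_sd: float = 0.0
    pleio_mean: float = 0.0
    ld_block_size: int = 1
    ld_r2: float = 0.0
    palindromic_frac: float = 0.0
    flip_frac: float = 0.0
    exposure_effect_sd: float = 0.05
    n_med_instruments: int = 0
    med_effect_sd: float = 0.05
    seed: int = 0
    panel_seed: Optional[int] = None  # share a SNP panel across sims

    def __post_init__(self) -> None:
        if self.n_instruments > self.n_snps:
            raise ValueError("n_instruments must be <= n_snps")
        if self.n_instruments + self.n_med_instruments > self.n_snps:
            raise ValueError("instrument sets exceed n_snps")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        for name in ("n_exp", "n_med", "n_case", "n_control"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("palindromic_frac", "flip_frac"):
            frac = getattr(self, name)
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.pleio_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleio_mode {self.pleio_mode!r}")
        if not 0 <= self.ld_r2 <= 1:
            raise ValueError("ld_r2 must be in [0, 1]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.n_out is None:
            self.n_out = self.n_case + self.n_control

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        return cls(**raw)


@dataclass
class SimTruth:
    """Generating effects behind one simulated triple."""

    snp_ids: list[str]
    exposure_effects: np.ndarray  # true per-SNP effect on the exposure
    mediator_effects: np.ndarray
    outcome_effects: np.ndarray
    block_index: np.ndarray  # LD block id per SNP
    config: SimConfig = field(repr=False)

    @property
    def mediation_effect(self) -> float:
        return self.config.beta_a * self.config.beta_b

    @property
    def total_effect(self) -> float:
        return self.config.delta + self.mediation_effect

    @property
    def direct_effect(self) -> float:
        return self.config.delta

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "block": self.block_index,
                "beta_exposure_true": self.exposure_effects,
                "beta_mediator_true": self.mediator_effects,
                "beta_outcome_true": self.outcome_effects,
            }
        )


def _effective_n(n_case: int, n_control: int) -> float:
    return 4.0 / (1.0 / n_case + 1.0 / n_control)


def _se_model(n: float, maf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _block_correlated_normal(
    rng: np.random.Generator, block_index: np.ndarray, rho: float
) -> np.ndarray:
    """Standard normals with compound-symmetric correlation ``rho`` per block."""
    n = block_index.size
    eps = rng.standard_normal(n)
    if rho <= 0:
        return eps
    n_blocks = int(block_index.max()) + 1
    shared = rng.standard_normal(n_blocks)
    return math.sqrt(rho) * shared[block_index] + math.sqrt(1.0 - rho) * eps


def _wald_pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    # keep p in the (0, 1] record invariant
    return np.clip(p, np.nextafter(0, 1), 1.0)


def simulate_triple(
    config: SimConfig,
) -> tuple[SumStatsTable, SumStatsTable, SumStatsTable, SimTruth]:
    """Generate (exposure, mediator, outcome, truth) under ``config``."""
    n = config.n_snps

    panel_entropy = config.seed if config.panel_seed is None else config.panel_seed
    panel_rng = np.random.default_rng(np.random.SeedSequence([panel_entropy, 11]))
    effect_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 22]))
    noise_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 33]))
    corrupt_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 44]))

    # --- SNP panel: ids, positions, alleles, frequencies -------------------
    snp_ids = [f"rs{i + 1:06d}" for i in range(n)]
    block_index = np.arange(n) // config.ld_block_size
    within = np.arange(n) % config.ld_block_size
    chroms = (block_index % _N_CHROMS) + 1
    pos = 1 + (block_index // _N_CHROMS) * _BLOCK_GAP_BP + within * _BLOCK_SPAN_BP

    maf = panel_rng.uniform(config.maf_range[0], config.maf_range[1], size=n)
    palindromic = panel_rng.random(n) < config.palindromic_frac
    pal_choice = panel_rng.integers(0, len(_PALINDROMIC_PAIRS), size=n)
    std_choice = panel_rng.integers(0, len(_NON_PALINDROMIC_PAIRS), size=n)
    alleles = [
        _PALINDROMIC_PAIRS[pal_choice[i]] if palindromic[i] else _NON_PALINDROMIC_PAIRS[std_choice[i]]
        for i in range(n)
    ]

    # --- true effects ------------------------------------------------------
    g = np.zeros(n)
    order = effect_rng.permutation(n)
    iv_idx = order[: config.n_instruments]
    med_idx = order[config.n_instruments : config.n_instruments + config.n_med_instruments]
    g[iv_idx] = effect_rng.normal(0.0, config.exposure_effect_sd, size=iv_idx.size)

    m = np.zeros(n)
    if med_idx.size:
        m[med_idx] = effect_rng.normal(0.0, config.med_effect_sd, size=med_idx.size)

    alpha = np.zeros(n)
    if config.pleio_mode != "none":
        mean = config.pleio_mean if config.pleio_mode == "directional" else 0.0
        draw = effect_rng.normal(mean, config.pleio_sd, size=iv_idx.size)
        # pleiotropy is defined relative to the exposure-increasing allele
        alpha[iv_idx] = np.sign(g[iv_idx]) * draw

    exposure_true = g
    mediator_true = config.beta_a * g + m
    outcome_true = config.delta * g + config.beta_b * mediator_true + alpha

    # --- observed effects --------------------------------------------------
    se_exp = _se_model(config.n_exp, maf)
    se_med = _se_model(config.n_med, maf)
    se_out = _se_model(_effective_n(config.n_case, config.n_control), maf)

    rho = config.ld_r2
    beta_exp = exposure_true + se_exp * _block_correlated_normal(noise_rng, block_index, rho)
    beta_med = mediator_true + se_med * _block_correlated_normal(noise_rng, block_index, rho)
    beta_out = outcome_true + se_out * _block_correlated_normal(noise_rng, block_index, rho)

    flipped = corrupt_rng.random(n) < config.flip_frac

    def build(trait_id, trait_type, beta, se, n_trait, n_case=None, n_control=None, flip=None):
        records = []
        for i in range(n):
            ea, oa = alleles[i]
            b, eaf = float(beta[i]), float(maf[i])
            if flip is not None and flip[i]:
                ea, oa, b, eaf = oa, ea, -b, 1.0 - eaf
            records.append(
                SnpRecord(
                    snp_id=snp_ids[i], chrom=str(int(chroms[i])), pos=int(pos[i]),
                    effect_allele=ea, other_allele=oa, eaf=eaf,
                    beta=b, se=float(se[i]),
                    pval=float(_wald_pvalues(beta[i : i + 1], se[i : i + 1])[0]),
                    n=n_trait, n_case=n_case, n_control=n_control,
                )
            )
        return SumStatsTable(trait_id=trait_id, trait_type=trait_type, records=records)

    exposure = build("exposure", "continuous", beta_exp, se_exp, config.n_exp)
    mediator = build("mediator", "continuous", beta_med, se_med, config.n_med)
    outcome = build(
        "outcome", "binary", beta_out, se_out, config.n_out,
        n_case=config.n_case, n_control=config.n_control, flip=flipped,
    )

    truth = SimTruth(
        snp_ids=snp_ids,
        exposure_effects=exposure_true,
        mediator_effects=mediator_true,
        outcome_effects=outcome_true,
        block_index=block_index,
        config=config,
    )
    return exposure, mediator, outcome, truth


def ld_r2_matrix(truth: SimTruth) -> np.ndarray:
    """Block-diagonal pairwise r-squared matrix implied by the simulation."""
    block = truth.block_index
    r2 = np.where(block[:, None] == block[None, :], truth.config.ld_r2, 0.0)
    np.fill_diagonal(r2, 1.0)
    return r2
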