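import numpy as np
import pytest

from mrpipe.harmonize import HarmonizedPair, InstrumentSet
from mrpipe.instruments import MatrixR2Lookup
from mrpipe.simulate import SimConfig, ld_r2_matrix, simulate_triple
from mrpipe.sumstats import SnpRecord, SumStatsTable


def make_record(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
                beta=0.1, se=0.02, pval=1e-9, n=10_000, **kw) -> SnpRecord:
    return SnpRecord(snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea,
                     other_allele=oa, eaf=eaf, beta=beta, se=se, pval=pval,
                     n=n, **kw)


def make_table(records, trait_id="trait", trait_type="continuous") -> SumStatsTable:
    return SumStatsTable(trait_id=trait_id, trait_type=trait_type,
                         records=list(records))


def make_set(beta_exp, beta_out, se_out, se_exp=None, exposure_id="exp",
             outcome_id="out") -> InstrumentSet:
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.broadcast_to(np.asarray(se_out, dtype=float), beta_exp.shape)
    if se_exp is None:
        se_exp = np.full_like(beta_exp, 0.01)
    else:
        se_exp = np.broadcast_to(np.asarray(se_exp, dtype=float), beta_exp.shape)
    pairs = [
        HarmonizedPair(snp_id=f"rs{i}", beta_exp=float(bx), se_exp=float(sx),
                       beta_out=float(by), se_out=float(sy),
                       eaf_exp=0.3, eaf_out=0.3, action="kept")
        for i, (bx, sx, by, sy) in enumerate(zip(beta_exp, se_exp, beta_out, se_out))
    ]
    return InstrumentSet(exposure_id, outcome_id, pairs)


@pytest.fixture(scope="session")
def effect_triple():
    """Simulated triple with a known nonzero total effect (0.32)."""
    config = SimConfig(
        n_snps=200, n_instruments=50, beta_a=0.3, beta_b=0.4, delta=0.2,
        n_exp=50_000, n_med=50_000, n_case=8_000, n_control=192_000, seed=1,
    )
    return simulate_triple(config)


@pytest.fixture(scope="session")
def effect_r2(effect_triple):
    truth = effect_triple[3]
    return MatrixR2Lookup(truth.snp_ids, ld_r2_matrix(truth))
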