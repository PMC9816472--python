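import numpy as np
import pytest

from dtmr.gwas_io import GwasTable, SnpRecord
from dtmr.harmonize import HarmonizedPair, HarmonizedSet


def make_record(rsid="rs1", ea="A", nea="G", beta=-0.1, se=0.01, pval=1e-6,
                chrom="12", pos=6_330_000, eaf=0.3, n=10_000.0):
    return SnpRecord(rsid=rsid, ea=ea, nea=nea, beta=beta, se=se, pval=pval,
                     chrom=chrom, pos=pos, eaf=eaf, n=n)


def make_table(records, trait_name="trait", trait_scale="continuous"):
    return GwasTable(trait_name=trait_name, trait_scale=trait_scale, records=tuple(records))


def make_pair(rsid="rs1", beta_x=-0.1, se_x=0.01, beta_y=0.02, se_y=0.005,
              ea="A", nea="G", eaf_x=0.3, eaf_y=0.3, status="aligned"):
    return HarmonizedPair(rsid=rsid, ea=ea, nea=nea, beta_x=beta_x, se_x=se_x,
                          beta_y=beta_y, se_y=se_y, eaf_x=eaf_x, eaf_y=eaf_y, status=status)


def make_hset(pairs):
    return HarmonizedSet(pairs=tuple(pairs), exclusions={})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_hset(rng, j=10, theta=0.5, intercept=0.0):
    """A HarmonizedSet with linear beta_y = intercept + theta*beta_x + noise."""
    bx = rng.uniform(-0.3, -0.05, size=j)
    sx = rng.uniform(0.005, 0.02, size=j)
    sy = rng.uniform(0.002, 0.01, size=j)
    by = intercept + theta * bx + rng.normal(0, sy)
    pairs = [make_pair(rsid=f"rs{i}", beta_x=bx[i], se_x=sx[i], beta_y=by[i], se_y=sy[i])
             for i in range(j)]
    return make_hset(pairs)
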