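import numpy as np
import pytest
from hypothesis import settings

from mrkit.gwas_io import HarmonizedSet, SummaryStats

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_summary(
    variant_ids,
    beta,
    se,
    pval=None,
    ea=None,
    oa=None,
    eaf=None,
    chrom=None,
    pos=None,
    trait_id="trait",
    n=None,
):
    """Compact SummaryStats builder for hand-constructed instances."""
    m = len(variant_ids)
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if pval is None:
        from scipy import stats

        pval = 2 * stats.norm.sf(np.abs(beta / se))
        pval = np.clip(pval, 5e-324, 1.0)
    return SummaryStats.from_arrays(
        variant_id=list(variant_ids),
        chromosome=chrom or ["1"] * m,
        position=pos or list(range(1000, 1000 + m)),
        effect_allele=ea or ["A"] * m,
        other_allele=oa or ["G"] * m,
        beta=beta,
        se=se,
        pval=np.asarray(pval, float),
        eaf=eaf,
        n=n,
        trait_id=trait_id,
    )


def make_harmonized(beta_exp, se_exp, beta_out, se_out, ids=None):
    n = len(beta_exp)
    return HarmonizedSet(
        ids or [f"rs{i:04d}" for i in range(n)],
        np.asarray(beta_exp, float),
        np.asarray(se_exp, float),
        np.asarray(beta_out, float),
        np.asarray(se_out, float),
        exposure_id="exp",
        outcome_id="out",
    )


@pytest.fixture
def small_harmonized():
    """Five strong instruments around a true ratio of 0.2."""
    return make_harmonized(
        beta_exp=[0.5, 0.8, 1.0, 1.2, 0.6],
        se_exp=[0.02, 0.02, 0.02, 0.02, 0.02],
        beta_out=[0.11, 0.15, 0.21, 0.23, 0.13],
        se_out=[0.02, 0.02, 0.02, 0.02, 0.02],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
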