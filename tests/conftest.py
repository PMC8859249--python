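import numpy as np
import pytest

from tsmr.harmonization import HarmonizedSet
from tsmr.summary_data import AssociationTable, SnpAssociation


def random_harmonized(seed: int, j: int = 20, theta: float = -0.27) -> HarmonizedSet:
    """Random harmonized dataset with true causal effect ``theta``."""
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(0.01, 0.05, j) * rng.choice([-1, 1], j)
    se_exp = rng.uniform(0.002, 0.005, j)
    se_out = rng.uniform(0.01, 0.02, j)
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(theta * gamma, se_out)
    return HarmonizedSet.from_arrays(beta_exp, se_exp, beta_out, se_out)


def make_record(
    snp_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.02,
    se=0.003,
    chrom="1",
    pos=1_000_000,
    eaf=0.3,
    pval=1e-10,
    n=None,
):
    return SnpAssociation(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
    )


def make_table(records, label="trait"):
    return AssociationTable(label, list(records))


@pytest.fixture
def h20():
    return random_harmonized(seed=42, j=20)


@pytest.fixture
def h50():
    return random_harmonized(seed=7, j=50)
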