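import numpy as np
import pandas as pd
import pytest

from revtwmr import EqtlRecord, GwasRecord, InstrumentSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_iset():
    """Five-SNP instrument set with proportional effects plus noise scale."""
    beta = np.array([0.10, -0.15, 0.20, 0.12, -0.08])
    gamma = 0.3 * beta
    return InstrumentSet(
        gene_id="ENSG00000001",
        trait_id="BMI",
        snp_ids=tuple(f"rs{i}" for i in range(5)),
        beta=beta,
        se_beta=np.full(5, 0.002),
        gamma=gamma,
        se_gamma=np.full(5, 0.006),
    )


def random_iset(rng, n_snps=8, alpha=0.25, se_beta=0.002, se_gamma=0.006, gene_id="g"):
    """Noisy instrument set with known generating slope."""
    beta_true = rng.uniform(0.05, 0.2, n_snps) * rng.choice([-1, 1], n_snps)
    beta = beta_true + se_beta * rng.standard_normal(n_snps)
    gamma = alpha * beta_true + se_gamma * rng.standard_normal(n_snps)
    return InstrumentSet(
        gene_id=gene_id,
        trait_id="trait",
        snp_ids=tuple(f"rs{i}" for i in range(n_snps)),
        beta=beta,
        se_beta=np.full(n_snps, se_beta),
        gamma=gamma,
        se_gamma=np.full(n_snps, se_gamma),
    )


def gwas_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                 "beta", "se", "pval", "n"],
    )


def eqtl_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["snp_id", "gene_id", "effect_allele", "other_allele",
                 "gamma", "se", "pval", "n"],
    )


def write_tsv(df, path):
    df.to_csv(path, sep="\t", index=False)
    return path


def make_gwas_record(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.01, pval=1e-10,
                     chrom="1", pos=1000, n=10000):
    return GwasRecord(snp_id=snp_id, effect_allele=ea, other_allele=oa,
                      beta_std=beta, se_beta=se, pval=pval, chrom=chrom, pos=pos, n=n)


def make_eqtl_record(snp_id="rs1", gene_id="g1", gamma=0.05, se=0.01, pval=1e-6,
                     n=30000, ea=None, oa=None):
    return EqtlRecord(snp_id=snp_id, gene_id=gene_id, gamma_std=gamma, se_gamma=se,
                      pval=pval, n=n, effect_allele=ea, other_allele=oa)
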