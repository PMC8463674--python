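"""Synthetic GWAS / trans-eQTL and cohort data with known causal structure.

The generator draws from the same structural model the decomposition
assumes:

    T = alpha_fwd * E + q_T * U + eps_T
    E = alpha_rev * T + q_E * U + eps_E

with a shared confounder U and residual scales chosen so that E and T have
unit variance (which the correlation identity requires).  Summary-statistics
tables mimic the two-sample design: standardized SNP effects on the trait
(truncated at genome-wide significance, so instrument selection is
exercised), implied trans effects alpha_rev * beta on each gene's
expression, optional pleiotropic direct effects on expression for a masked
subset of SNPs, and independent estimation noise at GWAS and eQTL sample
sizes.  Every draw is reproducible from the seed alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortData

#: two-sided genome-wide significance z threshold for 5e-8
GENOME_WIDE_P = 5e-8


def _as_gene_array(value, n_genes: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n_genes, float(arr))
    if arr.shape != (n_genes,):
        raise ValueError(f"{name} must be scalar or length n_genes={n_genes}")
    return arr.copy()


@dataclass
class SimConfig:
    """Generating parameters of a synthetic dataset.

    ``alpha_rev``/``alpha_fwd`` and the confounder loadings ``q_t``/``q_e``
    may be scalars or per-gene arrays.  Defaults mirror the study design
    the estimators target: a UK-Biobank-scale GWAS (n = 300,000), an
    eQTLGen-scale trans-eQTL study (n = 30,000), 50 genome-wide-significant
    LD-independent instruments per gene, and cohorts of ~2,000 individuals
    for the observational correlations.
    """

    seed: int
    n_genes: int = 100
    n_snps_per_gene: int = 50
    n_gwas: int = 300_000
    n_eqtl: int = 30_000
    alpha_rev: float | np.ndarray = 0.0
    alpha_fwd: float | np.ndarray = 0.0
    q_t: float | np.ndarray = 0.0
    q_e: float | np.ndarray = 0.0
    pleiotropy_fraction: float = 0.0
    pleiotropy_scale: float = 5.0
    sigma_beta: float = 0.02
    sigma_beta_cis: float = 0.1
    gwas_p_threshold: float = GENOME_WIDE_P
    n_individuals: int = 2000
    covar_effect: float = 0.2
    trait_id: str = "trait"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)
        for name in ("n_gwas", "n_eqtl", "n_individuals"):
            if getattr(self, name) < 10:
                raise ValueError(f"{name} must be >= 10")
        if self.n_genes < 1 or self.n_snps_per_gene < 1:
            raise ValueError("n_genes and n_snps_per_gene must be >= 1")
        if not (0.0 <= self.pleiotropy_fraction <= 1.0):
            raise ValueError("pleiotropy_fraction must lie in [0, 1]")
        self.alpha_rev = _as_gene_array(self.alpha_rev, self.n_genes, "alpha_rev")
        self.alpha_fwd = _as_gene_array(self.alpha_fwd, self.n_genes, "alpha_fwd")
        self.q_t = _as_gene_array(self.q_t, self.n_genes, "q_t")
        self.q_e = _as_gene_array(self.q_e, self.n_genes, "q_e")
        if np.any(np.abs(self.alpha_rev * self.alpha_fwd) >= 1):
            raise ValueError("|alpha_rev * alpha_fwd| must be < 1 (stationarity)")

    @property
    def gene_ids(self) -> list:
        return [f"ENSG{g:08d}" for g in range(self.n_genes)]


@dataclass
class SimTruth:
    """All generating values needed to assert recovery."""

    config: SimConfig
    gene_ids: list
    alpha_rev: np.ndarray
    alpha_fwd: np.ndarray
    q_product: np.ndarray
    beta_true: dict = field(default_factory=dict)       # gene -> trans instrument effects
    pleiotropy_mask: dict = field(default_factory=dict)  # gene -> bool array
    pleiotropy_effects: dict = field(default_factory=dict)
    corr_true: np.ndarray | None = None                  # population corr(E, T) per gene


@dataclass
class SimOutput:
    gwas_table: pd.DataFrame
    eqtl_table: pd.DataFrame
    fwd_gwas_table: pd.DataFrame | None
    fwd_eqtl_table: pd.DataFrame | None
    truth: SimTruth
    cohort: CohortData | None = None


def _truncated_abs_normal(rng, n: int, sigma: float, lower: float) -> np.ndarray:
    """|N(0, sigma^2)| conditioned on exceeding ``lower`` (inverse-CDF)."""
    a = lower / sigma
    tail = stats.norm.sf(a)
    u = rng.uniform(0.0, 1.0, size=n)
    return sigma * stats.norm.isf((1.0 - u) * tail)


def draw_gene_instruments(
    rng: np.random.Generator,
    n_snps: int,
    n_gwas: int,
    n_eqtl: int,
    alpha: float,
    sigma_beta: float,
    p_threshold: float = GENOME_WIDE_P,
    pleiotropy_fraction: float = 0.0,
    pleiotropy_scale: float = 5.0,
) -> dict:
    """Draw one gene's instrument-level truth and noisy estimates.

    True exposure effects are truncated so each passes the two-sided
    ``p_threshold`` at the exposure sample size before estimation noise,
    and are oriented positive — instruments reported on the
    trait-increasing allele, the usual convention for GWAS-derived
    instrument lists.  Pleiotropic SNPs receive a direct outcome effect of
    fixed magnitude ``pleiotropy_scale`` times the outcome-estimation SE,
    with a common positive sign (directional pleiotropy — the worst case
    for IVW).
    """
    se_b = 1.0 / math.sqrt(n_gwas)
    se_g = 1.0 / math.sqrt(n_eqtl)
    z_min = stats.norm.isf(p_threshold / 2.0)
    beta_true = _truncated_abs_normal(rng, n_snps, sigma_beta, z_min * se_b)
    mask = rng.random(n_snps) < pleiotropy_fraction
    pleio = np.where(mask, pleiotropy_scale * se_g, 0.0)
    gamma_true = alpha * beta_true + pleio
    beta_hat = beta_true + se_b * rng.standard_normal(n_snps)
    gamma_hat = gamma_true + se_g * rng.standard_normal(n_snps)
    return {
        "beta_true": beta_true,
        "beta_hat": beta_hat,
        "se_beta": np.full(n_snps, se_b),
        "gamma_true": gamma_true,
        "gamma_hat": gamma_hat,
        "se_gamma": np.full(n_snps, se_g),
        "pleiotropy_mask": mask,
        "pleiotropy_effects": pleio,
    }


def _pvals(effects: np.ndarray, ses: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(effects / ses))


def simulate_summary_stats(config: SimConfig, include_forward: bool = True) -> SimOutput:
    """Generate harmonization-ready GWAS and trans-eQTL tables.

    The reverse direction (trait -> expression) shares nothing with the
    forward direction: each gene additionally gets a disjoint set of
    cis-like instruments (larger effect scale ``sigma_beta_cis`` on
    expression) whose trait effects are alpha_fwd times the expression
    effect, emitted as a second table pair for forward MR.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = config.gene_ids
    n = config.n_snps_per_gene

    truth = SimTruth(
        config=config,
        gene_ids=gene_ids,
        alpha_rev=config.alpha_rev,
        alpha_fwd=config.alpha_fwd,
        q_product=config.q_t * config.q_e,
    )

    gwas_rows, eqtl_rows = [], []
    fwd_gwas_rows, fwd_eqtl_rows = [], []
    for g, gene_id in enumerate(gene_ids):
        draw = draw_gene_instruments(
            rng,
            n_snps=n,
            n_gwas=config.n_gwas,
            n_eqtl=config.n_eqtl,
            alpha=float(config.alpha_rev[g]),
            sigma_beta=config.sigma_beta,
            p_threshold=config.gwas_p_threshold,
            pleiotropy_fraction=config.pleiotropy_fraction,
            pleiotropy_scale=config.pleiotropy_scale,
        )
        truth.beta_true[gene_id] = draw["beta_true"]
        truth.pleiotropy_mask[gene_id] = draw["pleiotropy_mask"]
        truth.pleiotropy_effects[gene_id] = draw["pleiotropy_effects"]
        snp_ids = [f"rs{g}_{j}" for j in range(n)]
        gwas_rows.append(
            pd.DataFrame(
                {
                    "snp_id": snp_ids,
                    "chrom": [str(j % 22 + 1) for j in range(n)],
                    "pos": np.arange(1, n + 1) * 1000 + g,
                    "effect_allele": "A",
                    "other_allele": "G",
                    "beta": draw["beta_hat"],
                    "se": draw["se_beta"],
                    "pval": _pvals(draw["beta_hat"], draw["se_beta"]),
                    "n": config.n_gwas,
                }
            )
        )
        eqtl_rows.append(
            pd.DataFrame(
                {
                    "snp_id": snp_ids,
                    "gene_id": gene_id,
                    "effect_allele": "A",
                    "other_allele": "G",
                    "gamma": draw["gamma_hat"],
                    "se": draw["se_gamma"],
                    "pval": _pvals(draw["gamma_hat"], draw["se_gamma"]),
                    "n": config.n_eqtl,
                }
            )
        )
        if include_forward:
            fwd = draw_gene_instruments(
                rng,
                n_snps=n,
                n_gwas=config.n_eqtl,   # exposure here is expression
                n_eqtl=config.n_gwas,   # outcome is the trait
                alpha=float(config.alpha_fwd[g]),
                sigma_beta=config.sigma_beta_cis,
                p_threshold=config.gwas_p_threshold,
            )
            cis_ids = [f"cis{g}_{j}" for j in range(n)]
            fwd_eqtl_rows.append(
                pd.DataFrame(
                    {
                        "snp_id": cis_ids,
                        "gene_id": gene_id,
                        "effect_allele": "A",
                        "other_allele": "G",
                        "gamma": fwd["beta_hat"],
                        "se": fwd["se_beta"],
                        "pval": _pvals(fwd["beta_hat"], fwd["se_beta"]),
                        "n": config.n_eqtl,
                    }
                )
            )
            fwd_gwas_rows.append(
                pd.DataFrame(
                    {
                        "snp_id": cis_ids,
                        "chrom": [str(j % 22 + 1) for j in range(n)],
                        "pos": np.arange(1, n + 1) * 1000 + g,
                        "effect_allele": "A",
                        "other_allele": "G",
                        "beta": fwd["gamma_hat"],
                        "se": fwd["se_gamma"],
                        "pval": _pvals(fwd["gamma_hat"], fwd["se_gamma"]),
                        "n": config.n_gwas,
                    }
                )
            )

    return SimOutput(
        gwas_table=pd.concat(gwas_rows, ignore_index=True),
        eqtl_table=pd.concat(eqtl_rows, ignore_index=True),
        fwd_gwas_table=pd.concat(fwd_gwas_rows, ignore_index=True) if include_forward else None,
        fwd_eqtl_table=pd.concat(fwd_eqtl_rows, ignore_index=True) if include_forward else None,
        truth=truth,
    )


def residual_scales(alpha_fwd, alpha_rev, q_t, q_e) -> tuple[np.ndarray, np.ndarray]:
    """Residual variances (sigma_T^2, sigma_E^2) enforcing unit variances.

    Solves the two linear moment equations implied by var(E) = var(T) = 1
    under the structural model.  Raises when the requested loadings leave
    no room for positive residual variance.
    """
    af = np.asarray(alpha_fwd, dtype=float)
    ar = np.asarray(alpha_rev, dtype=float)
    qt = np.asarray(q_t, dtype=float)
    qe = np.asarray(q_e, dtype=float)
    den = 1.0 - ar * af
    c_e = den**2 - (ar * qt + qe) ** 2
    c_t = den**2 - (af * qe + qt) ** 2
    det = ar**2 * af**2 - 1.0
    sig_t2 = (c_e * af**2 - c_t) / det
    sig_e2 = (ar**2 * c_t - c_e) / det
    if np.any(sig_t2 <= 0) or np.any(sig_e2 <= 0):
        raise ValueError(
            "causal effects and confounder loadings leave no positive "
            "residual variance (would require var > 1)"
        )
    return sig_t2, sig_e2


def population_correlation(alpha_fwd, alpha_rev, q_t, q_e) -> np.ndarray:
    """corr(E, T) implied by the structural model with unit variances."""
    af = np.asarray(alpha_fwd, dtype=float)
    ar = np.asarray(alpha_rev, dtype=float)
    q = np.asarray(q_t, dtype=float) * np.asarray(q_e, dtype=float)
    return (af + ar + q) / (1.0 + af * ar)


def simulate_cohort(config: SimConfig, cohort_id: str = "sim") -> tuple[CohortData, SimTruth]:
    """Individual-level draw from the exact reduced forms of the model.

    With a single gene the full bidirectional reduced forms are used.
    With a multi-gene panel the trait cannot receive feedback from every
    gene at once, so ``alpha_fwd`` must be zero (and ``q_t`` common across
    genes): one trait T = q_t*U + eps_T is shared, and each gene's
    expression is E_g = alpha_rev_g*T + q_e_g*U + eps_E_g with the shared
    confounder U.  Either way E and T have unit population variance, so
    corr(E_g, T) follows the structural identity exactly.

    Age/sex covariate effects are added to both the recorded phenotype and
    every expression column; the adjustment step removes them.
    """
    rng = np.random.default_rng(config.seed + 1)
    n, g = config.n_individuals, config.n_genes
    ar, af = config.alpha_rev, config.alpha_fwd
    qt, qe = config.q_t, config.q_e

    if g == 1:
        sig_t2, sig_e2 = residual_scales(af, ar, qt, qe)
        sig_t, sig_e = np.sqrt(sig_t2), np.sqrt(sig_e2)
        den = 1.0 - ar * af
        U = rng.standard_normal((n, 1))
        zt = rng.standard_normal((n, 1))
        ze = rng.standard_normal((n, 1))
        E = ((ar * qt + qe) * U + ar * sig_t * zt + sig_e * ze) / den
        T = ((af * qe + qt) * U + af * sig_e * ze + sig_t * zt) / den
        trait = T[:, 0]
    else:
        if np.any(af != 0):
            raise ValueError(
                "multi-gene cohort simulation requires alpha_fwd = 0 "
                "(a single trait cannot receive feedback from every gene)"
            )
        if np.ptp(qt) != 0:
            raise ValueError("multi-gene cohort simulation requires a common q_t")
        qt0 = float(qt[0])
        sig_t2 = 1.0 - qt0**2
        sig_e2 = 1.0 - ar**2 - qe**2 - 2.0 * ar * qt0 * qe
        if sig_t2 <= 0 or np.any(sig_e2 <= 0):
            raise ValueError(
                "causal effects and confounder loadings leave no positive "
                "residual variance (would require var > 1)"
            )
        U = rng.standard_normal(n)
        trait = qt0 * U + math.sqrt(sig_t2) * rng.standard_normal(n)
        ze = rng.standard_normal((n, g))
        E = ar * trait[:, None] + qe * U[:, None] + np.sqrt(sig_e2) * ze

    age = rng.normal(50.0, 10.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    age_std = (age - age.mean()) / age.std()
    covar_shift = config.covar_effect * age_std + 0.5 * config.covar_effect * (sex - 0.5)

    phenotype = trait + covar_shift
    expression = E + covar_shift[:, None]
    covariates = pd.DataFrame({"sex": sex, "age": age, "age2": age**2})

    truth = SimTruth(
        config=config,
        gene_ids=config.gene_ids,
        alpha_rev=ar,
        alpha_fwd=af,
        q_product=qt * qe,
        corr_true=population_correlation(af, ar, qt, qe),
    )
    cohort = CohortData(
        phenotype=phenotype,
        covariates=covariates,
        expression=expression,
        gene_ids=config.gene_ids,
        cohort_id=cohort_id,
    )
    return cohort, truth
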