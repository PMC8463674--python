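"""Causal-effect estimators for summary-statistics Mendelian randomization.

The workhorse is the inverse-variance-weighted (IVW) estimator

    alpha_hat = (beta' C^-1 beta)^-1 (beta' C^-1 gamma)

which with C = identity (strongly LD-pruned instruments) reduces to the
ratio of cross-products sum(beta*gamma) / sum(beta^2) — the no-intercept
regression of outcome effects on exposure effects.  Its variance comes from
a first-order delta expansion treating the exposure and outcome effect
estimates as independent (they come from non-overlapping studies).

Two robustness estimators tolerate invalid instruments: the weighted median
(consistent when >50% of the weight is on valid instruments) and the
weighted mode (consistent when the largest group of instruments sharing a
ratio estimate is valid).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInstrumentsError, NoInstrumentsError
from .io import (
    EqtlRecord,
    GwasRecord,
    InstrumentSet,
    harmonize,
    select_instruments,
)

logger = logging.getLogger("revtwmr")

LOG10E = math.log10(math.e)

#: direction labels
TRAIT_TO_EXPRESSION = "trait_to_expression"
EXPRESSION_TO_TRAIT = "expression_to_trait"


@dataclass
class CausalEstimate:
    """One causal-effect estimate for a (trait, gene, direction) triple.

    ``alpha`` is in SD of outcome per SD of exposure.  ``log10_pval`` is
    kept alongside ``pval`` because genome-scale analyses produce p-values
    below the smallest positive float.
    """

    gene_id: str
    trait_id: str
    direction: str
    alpha: float
    se_alpha: float
    z: float
    pval: float
    log10_pval: float
    n_snps_used: int
    method: str
    removed_snps: tuple = ()
    q_stat: float | None = None
    q_pval: float | None = None


def z_and_p(alpha: float, se_alpha: float) -> tuple[float, float]:
    """Z-statistic and two-sided normal p-value for an estimate."""
    if se_alpha <= 0:
        raise ValueError("se_alpha must be positive")
    z = alpha / se_alpha
    return z, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def log10_two_sided_p(z: float) -> float:
    """log10 of the two-sided normal p-value, safe far into the tail."""
    return float((math.log(2.0) + stats.norm.logsf(abs(z))) * LOG10E)


def delta_variance(iset: InstrumentSet, alpha: float) -> float:
    """First-order delta-method variance of the IVW estimate.

    Uses the analytic gradients of the ratio-of-cross-products form:
    d(alpha)/d(gamma_j) = beta_j / S and
    d(alpha)/d(beta_j) = (gamma_j - 2 alpha beta_j) / S with S the
    (LD-weighted) sum of squared exposure effects.  The cross-covariance
    between exposure and outcome estimates is zero for non-overlapping
    samples.
    """
    beta, gamma = iset.beta, iset.gamma
    if iset.ld is None:
        s = float(beta @ beta)
        ci_beta, ci_gamma = beta, gamma
    else:
        ci_beta = np.linalg.solve(iset.ld, beta)
        ci_gamma = np.linalg.solve(iset.ld, gamma)
        s = float(beta @ ci_beta)
    if s == 0:
        raise DegenerateInstrumentsError("sum of squared exposure effects is zero")
    g_gamma = ci_beta / s
    g_beta = (ci_gamma - 2.0 * alpha * ci_beta) / s
    var = float(g_beta**2 @ iset.se_beta**2 + g_gamma**2 @ iset.se_gamma**2)
    return var


def ivw_estimate(
    iset: InstrumentSet,
    direction: str = TRAIT_TO_EXPRESSION,
) -> CausalEstimate:
    """Inverse-variance-weighted causal estimate for one gene.

    With an LD matrix C supplied, computes the generalized form
    (beta' C^-1 beta)^-1 (beta' C^-1 gamma); with C = None (identity) this
    is exactly sum(beta*gamma)/sum(beta^2).
    """
    beta, gamma = iset.beta, iset.gamma
    if iset.ld is None:
        s = float(beta @ beta)
        if s == 0:
            raise DegenerateInstrumentsError(
                f"gene {iset.gene_id}: all exposure effects are zero"
            )
        alpha = float(beta @ gamma) / s
    else:
        cond = np.linalg.cond(iset.ld)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"gene {iset.gene_id}: LD matrix is singular or ill-conditioned "
                f"(condition number {cond:.3g})"
            )
        ci_beta = np.linalg.solve(iset.ld, beta)
        s = float(beta @ ci_beta)
        if s == 0:
            raise DegenerateInstrumentsError(
                f"gene {iset.gene_id}: beta' C^-1 beta is zero"
            )
        alpha = float(ci_beta @ gamma) / s

    var = delta_variance(iset, alpha)
    se = math.sqrt(var)
    if se > 0:
        z, pval = z_and_p(alpha, se)
        log10p = log10_two_sided_p(z)
    else:  # exact (noise-free) synthetic input
        z, pval, log10p = math.nan, math.nan, math.nan
        logger.warning("gene %s: zero variance estimate; z/p undefined", iset.gene_id)
    return CausalEstimate(
        gene_id=iset.gene_id,
        trait_id=iset.trait_id,
        direction=direction,
        alpha=alpha,
        se_alpha=se,
        z=z,
        pval=pval,
        log10_pval=log10p,
        n_snps_used=iset.n_snps,
        method="ivw",
    )


def _ratio_inputs(iset: InstrumentSet) -> tuple[np.ndarray, ...]:
    """Per-SNP ratio estimates and first-order inverse-variance weights.

    SNPs with beta == 0 have an undefined ratio and are excluded with a
    warning; if none remain a NoInstrumentsError is raised.
    """
    valid = iset.beta != 0
    n_excluded = int(np.sum(~valid))
    if n_excluded:
        logger.warning(
            "gene %s: excluded %d SNP(s) with zero exposure effect from "
            "ratio-based estimator", iset.gene_id, n_excluded,
        )
    if not valid.any():
        raise NoInstrumentsError(
            f"gene {iset.gene_id}: all exposure effects are zero"
        )
    beta = iset.beta[valid]
    gamma = iset.gamma[valid]
    se_beta = iset.se_beta[valid]
    se_gamma = iset.se_gamma[valid]
    ratios = gamma / beta
    weights = beta**2 / se_gamma**2  # 1 / var(ratio), first order
    return ratios, weights, beta, gamma, se_beta, se_gamma


def _weighted_percentile(values: np.ndarray, weights: np.ndarray, q: float = 0.5) -> float:
    """Weighted percentile with linear interpolation of cumulative weight."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    p = cum / np.sum(w)
    return float(np.interp(q, p, v))


def weighted_median(
    iset: InstrumentSet,
    n_boot: int = 1000,
    seed: int = 0,
) -> CausalEstimate:
    """Weighted-median estimator: the 50th weighted percentile of the
    per-SNP ratio estimates, consistent when valid instruments carry a
    majority of the weight.  SE by seeded parametric bootstrap.
    """
    if iset.n_snps < 3:
        logger.warning(
            "gene %s: weighted median with %d < 3 instruments", iset.gene_id, iset.n_snps
        )
    ratios, weights, beta, gamma, se_beta, se_gamma = _ratio_inputs(iset)
    est = _weighted_percentile(ratios, weights, 0.5)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bb = beta + se_beta * rng.standard_normal(beta.size)
        gb = gamma + se_gamma * rng.standard_normal(gamma.size)
        ok = bb != 0
        if not ok.any():
            boot[b] = est
            continue
        boot[b] = _weighted_percentile(gb[ok] / bb[ok], bb[ok] ** 2 / se_gamma[ok] ** 2, 0.5)
    se = float(np.std(boot, ddof=1)) if n_boot > 1 else math.nan
    if se > 0:
        z, pval = z_and_p(est, se)
        log10p = log10_two_sided_p(z)
    else:
        z, pval, log10p = math.nan, math.nan, math.nan
    return CausalEstimate(
        gene_id=iset.gene_id,
        trait_id=iset.trait_id,
        direction=TRAIT_TO_EXPRESSION,
        alpha=est,
        se_alpha=se,
        z=z,
        pval=pval,
        log10_pval=log10p,
        n_snps_used=int(np.sum(iset.beta != 0)),
        method="weighted_median",
    )


def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    if np.ptp(ratios) == 0:
        return float(ratios[0])
    n = ratios.size
    sd = float(np.std(ratios))
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])) * -1.0)
    spread_candidates = [s for s in (sd, iqr / 1.349) if s > 0]
    s = 0.9 * min(spread_candidates) * n ** (-0.2) * bandwidth_factor
    w = weights / np.sum(weights)
    lo, hi = ratios.min() - 3 * s, ratios.max() + 3 * s
    grid = np.linspace(lo, hi, 2048)
    # normal-kernel weighted density on the grid
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / s) ** 2) @ w
    return float(grid[np.argmax(dens)])


def weighted_mode(
    iset: InstrumentSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> CausalEstimate:
    """Weighted mode-based estimator: the argmax of a weighted normal-kernel
    density over per-SNP ratio estimates (modified Silverman bandwidth),
    consistent when the largest cluster of ratios comes from valid
    instruments.  SE by seeded parametric bootstrap.
    """
    if iset.n_snps < 3:
        logger.warning(
            "gene %s: weighted mode with %d < 3 instruments", iset.gene_id, iset.n_snps
        )
    ratios, weights, beta, gamma, se_beta, se_gamma = _ratio_inputs(iset)
    est = _weighted_mode_point(ratios, weights, bandwidth_factor)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bb = beta + se_beta * rng.standard_normal(beta.size)
        gb = gamma + se_gamma * rng.standard_normal(gamma.size)
        ok = bb != 0
        if not ok.any():
            boot[b] = est
            continue
        boot[b] = _weighted_mode_point(
            gb[ok] / bb[ok], bb[ok] ** 2 / se_gamma[ok] ** 2, bandwidth_factor
        )
    se = float(np.std(boot, ddof=1)) if n_boot > 1 else math.nan
    if se > 0:
        z, pval = z_and_p(est, se)
        log10p = log10_two_sided_p(z)
    else:
        z, pval, log10p = math.nan, math.nan, math.nan
    return CausalEstimate(
        gene_id=iset.gene_id,
        trait_id=iset.trait_id,
        direction=TRAIT_TO_EXPRESSION,
        alpha=est,
        se_alpha=se,
        z=z,
        pval=pval,
        log10_pval=log10p,
        n_snps_used=int(np.sum(iset.beta != 0)),
        method="weighted_mode",
    )


def bonferroni_threshold(alpha_fw: float = 0.05, n_tests: int = 1) -> float:
    """Family-wise significance threshold alpha_fw / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha_fw / n_tests


@dataclass
class GeneFailure:
    """Reason a gene could not be estimated (reported, never silent)."""

    gene_id: str
    reason: str
    removal_counts: dict = field(default_factory=dict)


@dataclass
class RunResult:
    estimates: list[CausalEstimate]
    failures: list[GeneFailure]


DEFAULT_RUN_CONFIG: dict = {
    "p_max": 5e-8,
    "drop_reverse": True,
    "heterogeneity": True,
    "het_p_threshold": 1e-4,
    "het_min_snps": 2,
    "het_variance": "printed",
    "method": "ivw",
    "seed": 0,
    "trait_id": "trait",
}


def run_direction(
    gwas_records: Sequence[GwasRecord],
    eqtl_records: Sequence[EqtlRecord],
    gene_list: Iterable[str],
    direction: str = TRAIT_TO_EXPRESSION,
    config: Mapping | None = None,
) -> RunResult:
    """Run one MR direction over a gene panel.

    Reverse MR (``trait_to_expression``) instruments each gene with
    GWAS-significant SNPs: exposure = trait (GWAS effects), outcome =
    trans-eQTL effects.  Forward MR (``expression_to_trait``) swaps the
    roles: exposure = expression (eQTL effects, selected on the eQTL
    p-value), outcome = GWAS effects.  Genes failing harmonization or
    selection are returned as :class:`GeneFailure`, not dropped silently.
    """
    from .heterogeneity import iterative_outlier_removal  # cycle avoidance

    cfg = dict(DEFAULT_RUN_CONFIG)
    if config:
        cfg.update(config)
    if direction not in (TRAIT_TO_EXPRESSION, EXPRESSION_TO_TRAIT):
        raise ValueError(f"unknown direction {direction!r}")

    estimates: list[CausalEstimate] = []
    failures: list[GeneFailure] = []
    for gene_id in gene_list:
        try:
            iset = harmonize(gwas_records, eqtl_records, gene_id, trait_id=cfg["trait_id"])
            if direction == EXPRESSION_TO_TRAIT:
                iset = iset.swapped()
            iset = select_instruments(
                iset, p_max=cfg["p_max"], drop_reverse=cfg["drop_reverse"]
            )
        except NoInstrumentsError as exc:
            failures.append(GeneFailure(gene_id, str(exc), exc.removal_counts))
            continue

        try:
            method = cfg["method"]
            if method == "ivw":
                if cfg["heterogeneity"] and iset.n_snps >= cfg["het_min_snps"]:
                    het = iterative_outlier_removal(
                        iset,
                        p_threshold=cfg["het_p_threshold"],
                        min_snps=cfg["het_min_snps"],
                        variance=cfg["het_variance"],
                        direction=direction,
                    )
                    est = het.final_estimate
                    est.removed_snps = tuple(het.removed)
                    est.q_stat = het.global_q
                    est.q_pval = het.global_q_pval
                else:
                    est = ivw_estimate(iset, direction=direction)
            elif method == "weighted_median":
                est = weighted_median(iset, seed=cfg["seed"])
                est.direction = direction
            elif method == "weighted_mode":
                est = weighted_mode(iset, seed=cfg["seed"])
                est.direction = direction
            else:
                raise ValueError(f"unknown method {method!r}")
        except (DegenerateInstrumentsError, NoInstrumentsError) as exc:
            failures.append(GeneFailure(gene_id, str(exc)))
            continue
        estimates.append(est)

    if not estimates and failures:
        logger.warning("no genes could be estimated (%d failures)", len(failures))
    return RunResult(estimates=estimates, failures=failures)


def estimates_to_frame(estimates: Sequence[CausalEstimate]):
    """Flatten estimates to the output TSV schema."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in estimates],
            "trait_id": [e.trait_id for e in estimates],
            "direction": [e.direction for e in estimates],
            "method": [e.method for e in estimates],
            "alpha": [e.alpha for e in estimates],
            "se": [e.se_alpha for e in estimates],
            "z": [e.z for e in estimates],
            "pval": [e.pval for e in estimates],
            "log10_pval": [e.log10_pval for e in estimates],
            "n_snps": [e.n_snps_used for e in estimates],
            "q_stat": [e.q_stat for e in estimates],
            "q_pval": [e.q_pval for e in estimates],
            "removed_snps": [",".join(e.removed_snps) for e in estimates],
        }
    )
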