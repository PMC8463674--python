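"""Decomposing observational expression-trait correlation into causal and
confounder contributions, with errors-in-variables dilution correction.

Under the linear structural model

    T = a_fwd * E + q_T * U + eps_T
    E = a_rev * T + q_E * U + eps_E

with E, T, U standardized, the observational correlation satisfies

    corr(E, T) = (a_fwd + a_rev + q_T*q_E) / (1 + a_fwd*a_rev)

so each gene's observed correlation r splits into a forward-causal share
a_fwd/r, a reverse-causal share a_rev/r and a confounder share
1 - a_fwd/r - a_rev/r (the product a_fwd*a_rev is negligible for real
effect sizes, so the denominator is taken as 1 by default; the exact form
is selectable).  Shares are combined across genes within |r| bins by fixed-
effect inverse-variance meta-analysis.

The dilution adjustment corrects the Pearson correlation between two noisy
estimate vectors (e.g. per-gene causal effects vs observational
correlations) for attenuation due to estimation error in both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import NoiseDominatesError, RevtwmrError

#: default |r| bin edges: width 0.02 up to 0.1 plus a terminal open bin
DEFAULT_BIN_EDGES = (0.0, 0.02, 0.04, 0.06, 0.08, 0.1, np.inf)


@dataclass
class GeneDecomposition:
    """Per-gene split of observed correlation into three signed shares.

    ``frac_fwd + frac_rev + frac_conf == 1`` exactly by construction.
    Shares can be negative when a causal estimate opposes the sign of the
    observed correlation; they are deliberately not clipped.
    """

    gene_id: str
    r_obs: float
    se_r: float
    alpha_fwd: float
    se_fwd: float
    alpha_rev: float
    se_rev: float
    frac_fwd: float
    frac_rev: float
    frac_conf: float
    se_frac_fwd: float
    se_frac_rev: float
    se_frac_conf: float


@dataclass
class ConfounderProduct:
    """The identified confounder loading product q_T * q_E for one gene."""

    gene_id: str
    q_product: float


@dataclass
class BinnedContribution:
    """Inverse-variance combined shares within one |r| bin."""

    bin_low: float
    bin_high: float
    n_genes: int
    frac_fwd: float | None = None
    se_fwd: float | None = None
    ci_fwd: tuple | None = None
    p_fwd: float | None = None
    frac_rev: float | None = None
    se_rev: float | None = None
    ci_rev: tuple | None = None
    p_rev: float | None = None
    frac_conf: float | None = None
    se_conf: float | None = None
    ci_conf: tuple | None = None
    p_conf: float | None = None


def decompose_gene(
    r_obs: float,
    se_r: float,
    alpha_fwd: float,
    se_fwd: float,
    alpha_rev: float,
    se_rev: float,
    gene_id: str = "gene",
    denominator: str = "approx",
    include_var_r: bool = False,
) -> GeneDecomposition:
    """Split one gene's observed correlation into three signed shares.

    ``denominator="approx"`` divides by r (the default, since
    |a_fwd*a_rev| is negligible); ``"exact"`` divides by r*(1+a_fwd*a_rev)
    so the confounder share is q_T*q_E / (r*(1+a_fwd*a_rev)).  Share SEs
    treat r as fixed by default (its SE is an order of magnitude smaller
    than the MR SEs at cohort scale); ``include_var_r`` adds the
    delta-method var(r) term.
    """
    if r_obs == 0:
        raise RevtwmrError(f"gene {gene_id}: fractions undefined for r_obs = 0")
    if denominator not in ("approx", "exact"):
        raise ValueError("denominator must be 'approx' or 'exact'")
    denom = r_obs if denominator == "approx" else r_obs * (1.0 + alpha_fwd * alpha_rev)
    if denom == 0:
        raise RevtwmrError(f"gene {gene_id}: exact denominator is zero")
    frac_fwd = alpha_fwd / denom
    frac_rev = alpha_rev / denom
    frac_conf = 1.0 - (frac_fwd + frac_rev)
    se_frac_fwd = abs(se_fwd / denom)
    se_frac_rev = abs(se_rev / denom)
    if include_var_r:
        # delta method on alpha / r with independent errors
        se_frac_fwd = math.sqrt((se_fwd / denom) ** 2 + (alpha_fwd * se_r / denom**2) ** 2)
        se_frac_rev = math.sqrt((se_rev / denom) ** 2 + (alpha_rev * se_r / denom**2) ** 2)
    se_frac_conf = math.sqrt(se_frac_fwd**2 + se_frac_rev**2)
    return GeneDecomposition(
        gene_id=gene_id,
        r_obs=r_obs,
        se_r=se_r,
        alpha_fwd=alpha_fwd,
        se_fwd=se_fwd,
        alpha_rev=alpha_rev,
        se_rev=se_rev,
        frac_fwd=frac_fwd,
        frac_rev=frac_rev,
        frac_conf=frac_conf,
        se_frac_fwd=se_frac_fwd,
        se_frac_rev=se_frac_rev,
        se_frac_conf=se_frac_conf,
    )


def confounder_product(
    r_obs: float, alpha_fwd: float, alpha_rev: float, gene_id: str = "gene"
) -> ConfounderProduct:
    """Exact algebraic inversion of the structural correlation identity:
    q_T*q_E = r*(1 + a_fwd*a_rev) - a_fwd - a_rev."""
    q = r_obs * (1.0 + alpha_fwd * alpha_rev) - alpha_fwd - alpha_rev
    return ConfounderProduct(gene_id=gene_id, q_product=float(q))


def structural_correlation(alpha_fwd: float, alpha_rev: float, q_product: float) -> float:
    """Forward map: corr(E,T) implied by the structural model."""
    return (alpha_fwd + alpha_rev + q_product) / (1.0 + alpha_fwd * alpha_rev)


def _ivw_combine(values: np.ndarray, ses: np.ndarray) -> tuple[float, float, tuple, float]:
    w = 1.0 / ses**2
    est = float(np.sum(w * values) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    ci = (est - 1.959964 * se, est + 1.959964 * se)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(est / se)))) if se > 0 else math.nan
    return est, se, ci, p


def bin_and_meta(
    decompositions: list[GeneDecomposition],
    bin_edges=DEFAULT_BIN_EDGES,
) -> list[BinnedContribution]:
    """Combine per-gene shares within half-open |r_obs| bins.

    Each share is meta-analyzed separately with fixed-effect inverse-
    variance weights 1/SE^2; the combined SE is sqrt(1/sum(w)) and the
    p-value tests the combined share against zero.  Empty bins are
    reported with n_genes = 0 and absent estimates.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 values")
    abs_r = np.array([abs(d.r_obs) for d in decompositions])
    out: list[BinnedContribution] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        idx = np.flatnonzero((abs_r >= lo) & (abs_r < hi))
        if idx.size == 0:
            out.append(BinnedContribution(bin_low=float(lo), bin_high=float(hi), n_genes=0))
            continue
        sub = [decompositions[i] for i in idx]
        fw, se_fw, ci_fw, p_fw = _ivw_combine(
            np.array([d.frac_fwd for d in sub]), np.array([d.se_frac_fwd for d in sub])
        )
        rv, se_rv, ci_rv, p_rv = _ivw_combine(
            np.array([d.frac_rev for d in sub]), np.array([d.se_frac_rev for d in sub])
        )
        cf, se_cf, ci_cf, p_cf = _ivw_combine(
            np.array([d.frac_conf for d in sub]), np.array([d.se_frac_conf for d in sub])
        )
        out.append(
            BinnedContribution(
                bin_low=float(lo),
                bin_high=float(hi),
                n_genes=int(idx.size),
                frac_fwd=fw, se_fwd=se_fw, ci_fwd=ci_fw, p_fwd=p_fw,
                frac_rev=rv, se_rev=se_rv, ci_rev=ci_rv, p_rev=p_rv,
                frac_conf=cf, se_conf=se_cf, ci_conf=ci_cf, p_conf=p_cf,
            )
        )
    return out


@dataclass
class DilutionResult:
    """Observed and dilution-adjusted correlation between two estimate
    vectors, with the two attenuation factors and a Fisher-scale 95% CI
    for the adjusted value."""

    observed: float
    adjusted: float
    attenuation_alpha: float
    attenuation_corr: float
    n: int
    ci95: tuple


def dilution_adjust(
    corr_vec,
    se_corr_vec,
    alpha_vec,
    se_alpha_vec,
) -> DilutionResult:
    """Correct the correlation between two noisy estimate vectors for
    regression dilution.

    The observed Pearson correlation between per-gene causal-effect
    estimates and observational correlations is attenuated by the factor
    sqrt(1 - sum(SE_a^2)/sum(a^2)) * sqrt(1 - sum(SE_r^2)/sum(r^2));
    dividing by it recovers the correlation between the underlying true
    quantities.  Raises when estimation noise dominates the signal (an
    attenuation factor <= 0).
    """
    r = np.asarray(corr_vec, dtype=float)
    se_r = np.asarray(se_corr_vec, dtype=float)
    a = np.asarray(alpha_vec, dtype=float)
    se_a = np.asarray(se_alpha_vec, dtype=float)
    if not (r.shape == se_r.shape == a.shape == se_a.shape):
        raise ValueError("all four vectors must have the same shape")
    n = r.size
    if n < 4:
        raise ValueError("need at least 4 genes")
    observed = float(np.corrcoef(a, r)[0, 1])
    att_a_sq = 1.0 - float(np.sum(se_a**2) / np.sum(a**2))
    att_r_sq = 1.0 - float(np.sum(se_r**2) / np.sum(r**2))
    if att_a_sq <= 0 or att_r_sq <= 0:
        raise NoiseDominatesError(
            "estimation noise exceeds signal; dilution adjustment undefined "
            f"(attenuation^2: alpha={att_a_sq:.3g}, corr={att_r_sq:.3g})"
        )
    k = math.sqrt(att_a_sq) * math.sqrt(att_r_sq)
    adjusted = observed / k
    z = math.atanh(max(-1 + 1e-15, min(1 - 1e-15, observed)))
    half = 1.959964 / math.sqrt(n - 3)
    ci95 = (math.tanh(z - half) / k, math.tanh(z + half) / k)
    return DilutionResult(
        observed=observed,
        adjusted=adjusted,
        attenuation_alpha=math.sqrt(att_a_sq),
        attenuation_corr=math.sqrt(att_r_sq),
        n=n,
        ci95=ci95,
    )
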