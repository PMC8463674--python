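"""Cochran's-Q-style detection and removal of pleiotropic instruments.

A valid instrument's outcome effect should equal the causal effect times its
exposure effect; the per-SNP deviation d_i = gamma_i - alpha*beta_i referred
to its variance gives a chi-square(1 df) test statistic.  SNPs acting on the
outcome through pathways other than the exposure (pleiotropy) inflate |d_i|
and are removed one at a time — largest |d_i| first, re-estimating the
causal effect after each removal — until no SNP fails at the p-value
threshold or a minimum instrument count is reached.

Two variance formulas are available for d_i.  The "printed" form is

    var(d_i) = var(g_i) + b_i^2 var(a) + var(g_i) a^2 + var(b_i) var(a)

while the "corrected" form replaces the dimensionally odd third term with
the delta-expansion term a^2 var(b_i):

    var(d_i) = var(g_i) + b_i^2 var(a) + a^2 var(b_i) + var(b_i) var(a)

The two agree whenever var(b_i) = var(g_i); the printed form is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import RevtwmrError
from .io import InstrumentSet
from .mr import TRAIT_TO_EXPRESSION, CausalEstimate, ivw_estimate

logger = logging.getLogger("revtwmr")

VARIANCE_FORMS = ("printed", "corrected")


@dataclass
class SnpDeviation:
    """Per-SNP deviation from proportionality and its chi-square test."""

    snp_id: str
    d: float
    var_d: float
    t_stat: float
    pval: float


def _deviation_arrays(
    iset: InstrumentSet, estimate: CausalEstimate, variance: str
) -> tuple[np.ndarray, np.ndarray]:
    if variance not in VARIANCE_FORMS:
        raise ValueError(f"variance must be one of {VARIANCE_FORMS}")
    alpha = estimate.alpha
    var_alpha = estimate.se_alpha**2
    var_beta = iset.se_beta**2
    var_gamma = iset.se_gamma**2
    d = iset.gamma - alpha * iset.beta
    if variance == "printed":
        var_d = var_gamma + iset.beta**2 * var_alpha + var_gamma * alpha**2 + var_beta * var_alpha
    else:
        var_d = var_gamma + iset.beta**2 * var_alpha + alpha**2 * var_beta + var_beta * var_alpha
    return d, var_d


def snp_deviations(
    iset: InstrumentSet,
    estimate: CausalEstimate,
    variance: str = "printed",
) -> list[SnpDeviation]:
    """Per-SNP deviation statistics T_i = d_i^2 / var(d_i) ~ chi2(1)."""
    d, var_d = _deviation_arrays(iset, estimate, variance)
    bad = np.flatnonzero(var_d <= 0)
    if bad.size:
        raise RevtwmrError(
            f"non-positive deviation variance for SNP(s) "
            f"{[iset.snp_ids[i] for i in bad]}"
        )
    t = d**2 / var_d
    pvals = stats.chi2.sf(t, df=1)
    return [
        SnpDeviation(snp_id=s, d=float(di), var_d=float(vi), t_stat=float(ti), pval=float(pi))
        for s, di, vi, ti, pi in zip(iset.snp_ids, d, var_d, t, pvals)
    ]


@dataclass
class HeterogeneityResult:
    """Outcome of the iterative pleiotropy filter for one gene."""

    final_iset: InstrumentSet
    final_estimate: CausalEstimate
    removed: list
    global_q: float
    global_q_pval: float
    n_iterations: int
    converged: bool
    trace: list  # one (n_snps, alpha, worst_snp, worst_pval) tuple per iteration


def iterative_outlier_removal(
    iset: InstrumentSet,
    p_threshold: float = 1e-4,
    min_snps: int = 2,
    variance: str = "printed",
    direction: str = TRAIT_TO_EXPRESSION,
) -> HeterogeneityResult:
    """Iteratively remove the most deviant SNP while any fails the test.

    Each iteration re-estimates the causal effect on the current set,
    computes per-SNP deviations, and — if any p-value falls below
    ``p_threshold`` — removes the single SNP with the largest absolute
    deviation (ties broken by lexicographically smallest snp_id, logged).
    Stops when no SNP fails (converged) or when ``min_snps`` instruments
    remain (not converged).  The global Q statistic (sum of final per-SNP
    T_i, chi-square with n-1 df) is reported as a diagnostic.
    """
    if iset.n_snps < min_snps:
        raise ValueError(
            f"gene {iset.gene_id}: {iset.n_snps} instruments < min_snps={min_snps}"
        )
    current = iset
    removed: list[str] = []
    trace = []
    while True:
        est = ivw_estimate(current, direction=direction)
        d, var_d = _deviation_arrays(current, est, variance)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(var_d > 0, d**2 / np.where(var_d > 0, var_d, 1.0), np.inf)
        pvals = stats.chi2.sf(t, df=1)
        fails = pvals < p_threshold
        abs_d = np.abs(d)
        worst = int(np.argmax(abs_d))
        ties = np.flatnonzero(abs_d == abs_d[worst])
        if ties.size > 1:
            worst = min(ties, key=lambda i: current.snp_ids[i])
            logger.info(
                "gene %s: |d| tie broken lexicographically -> %s",
                iset.gene_id, current.snp_ids[worst],
            )
        trace.append(
            (current.n_snps, est.alpha, current.snp_ids[worst], float(pvals[worst]))
        )
        if not fails.any():
            converged = True
            break
        if current.n_snps <= min_snps:
            converged = False
            break
        removed.append(current.snp_ids[worst])
        current = current.drop_snp(current.snp_ids[worst])

    global_q = float(np.sum(t))
    df = current.n_snps - 1
    global_q_pval = float(stats.chi2.sf(global_q, df=df)) if df >= 1 else float("nan")
    return HeterogeneityResult(
        final_iset=current,
        final_estimate=est,
        removed=removed,
        global_q=global_q,
        global_q_pval=global_q_pval,
        n_iterations=len(removed) + 1,
        converged=converged,
        trace=trace,
    )


def trace_frame(result: HeterogeneityResult):
    """Per-iteration trace as a DataFrame (for the CLI TSV output)."""
    import pandas as pd

    return pd.DataFrame(
        trace_row
        for trace_row in (
            {
                "iteration": i + 1,
                "n_snps": n,
                "alpha": a,
                "worst_snp": s,
                "worst_pval": p,
            }
            for i, (n, a, s, p) in enumerate(result.trace)
        )
    )
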