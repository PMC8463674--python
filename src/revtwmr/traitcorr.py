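"""Gene-expression perturbation correlation between trait pairs.

Two traits that perturb the transcriptome similarly will have correlated
trait-to-expression causal-effect vectors.  For each trait pair the
perturbation correlation rho_P is the Pearson correlation of their per-gene
causal effects across a caller-supplied panel of independent genes, with a
two-sided t-test p-value and Benjamini-Hochberg FDR control over all pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class TraitPairCorrelation:
    trait_i: str
    trait_j: str
    rho_p: float
    n_genes: int
    pval: float
    fdr_q: float | None = None


@dataclass
class PerturbationResult:
    pairs: list = field(default_factory=list)
    skipped: list = field(default_factory=list)  # (trait_i, trait_j, reason)


def _pearson_t_pval(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(min(1.0, 2.0 * stats.t.sf(abs(t), df=n - 2)))


def perturbation_correlation(
    alpha_matrix: pd.DataFrame,
    fdr_method: str = "fdr_bh",
) -> PerturbationResult:
    """Pairwise perturbation correlations from a genes x traits matrix.

    Missing entries are handled pairwise-complete; pairs with fewer than 3
    complete genes are skipped with a reason code.  The gene panel is
    assumed independent (selection is the caller's responsibility).
    """
    if not isinstance(alpha_matrix, pd.DataFrame):
        alpha_matrix = pd.DataFrame(np.asarray(alpha_matrix))
    traits = list(alpha_matrix.columns)
    result = PerturbationResult()
    for ti, tj in itertools.combinations(traits, 2):
        pair = alpha_matrix[[ti, tj]].dropna()
        n = len(pair)
        if n < 3:
            result.skipped.append((ti, tj, f"only {n} complete genes (< 3)"))
            continue
        x = pair[ti].to_numpy(dtype=float)
        y = pair[tj].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            result.skipped.append((ti, tj, "zero variance in effect vector"))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        result.pairs.append(
            TraitPairCorrelation(
                trait_i=str(ti),
                trait_j=str(tj),
                rho_p=r,
                n_genes=n,
                pval=_pearson_t_pval(r, n),
            )
        )
    if result.pairs:
        qvals = fdr_adjust([p.pval for p in result.pairs], method=fdr_method)
        for pair_res, q in zip(result.pairs, qvals):
            pair_res.fdr_q = float(q)
    return result


def fdr_adjust(pvals, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-equivariant)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def pairs_to_frame(result: PerturbationResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trait_i": [p.trait_i for p in result.pairs],
            "trait_j": [p.trait_j for p in result.pairs],
            "rho_p": [p.rho_p for p in result.pairs],
            "n_genes": [p.n_genes for p in result.pairs],
            "pval": [p.pval for p in result.pairs],
            "fdr_q": [p.fdr_q for p in result.pairs],
        }
    )
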