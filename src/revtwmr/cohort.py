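"""Cohort-level observational phenotype-expression correlations.

Mirrors the differential-expression surrogate used at cohort level: both
the phenotype and each gene's expression are rank-based inverse-normal
transformed, residualized on covariates (sex, age, age^2 for the phenotype;
additionally any expression-specific technical covariates), and correlated
by Pearson's r.  Per-cohort correlations are combined by fixed-effect
inverse-variance meta-analysis on the Fisher-z scale with var(z) = 1/(n-3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearCovariatesError, DegenerateInputError

logger = logging.getLogger("revtwmr")


@dataclass
class CohortData:
    """Individual-level data for one cohort.

    ``expression`` is individuals x genes; ``covariates`` holds the
    phenotype covariates and ``expression_covariates`` any additional
    technical covariates applied to expression only.
    """

    phenotype: np.ndarray
    covariates: pd.DataFrame
    expression: np.ndarray
    gene_ids: Sequence[str]
    cohort_id: str
    expression_covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        self.expression = np.asarray(self.expression, dtype=float)
        if not isinstance(self.covariates, pd.DataFrame):
            self.covariates = pd.DataFrame(np.asarray(self.covariates))
        n = self.phenotype.shape[0]
        if self.covariates.shape[0] != n or self.expression.shape[0] != n:
            raise ValueError("row counts of phenotype, covariates, expression differ")
        if self.expression.shape[1] != len(self.gene_ids):
            raise ValueError("expression column count != number of gene ids")
        const = [c for c in self.covariates.columns
                 if np.ptp(self.covariates[c].to_numpy(dtype=float)) == 0]
        if const:
            raise ValueError(f"constant covariate column(s): {const}")

    @property
    def n(self) -> int:
        return self.phenotype.shape[0]


@dataclass
class ObsCorrelation:
    gene_id: str
    r: float
    se_r: float
    n: int
    cohort_id: str


def inverse_normal_transform(values, axis: int = 0) -> np.ndarray:
    """Rank-based inverse normal transformation with the Blom offset.

    Ranks (average for ties) are mapped through Phi^-1((rank - 3/8) /
    (n + 1/4)).  Invariant to monotone transforms of the input; constant
    input is a degenerate error.
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[axis]
    if n < 2:
        raise DegenerateInputError("need at least 2 observations")
    if v.ndim == 1:
        if np.ptp(v) == 0:
            raise DegenerateInputError("all input values are equal")
    else:
        if np.any(np.ptp(v, axis=axis) == 0):
            raise DegenerateInputError("at least one column is constant")
    ranks = stats.rankdata(v, method="average", axis=axis)
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list]:
    X = covariates.to_numpy(dtype=float)
    names = ["intercept"] + [str(c) for c in covariates.columns]
    X1 = np.column_stack([np.ones(X.shape[0]), X])
    return X1, names

def _collinear_columns(X1: np.ndarray, names: list) -> list:
    # columns whose QR diagonal is (near-)zero relative to the largest
    _, R = np.linalg.qr(X1)
    diag = np.abs(np.diag(R))
    tol = diag.max() * 1e-10
    return [names[i] for i in np.flatnonzero(diag < tol)]


def adjust_covariates(y, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of y (vector or matrix of columns) on covariates.

    An intercept is added; the residuals are orthogonal to every covariate
    column.  Rank deficiency raises naming the collinear columns.
    """
    if not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(np.asarray(covariates))
    y = np.asarray(y, dtype=float)
    X1, names = _design_matrix(covariates)
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise CollinearCovariatesError(
            f"covariate matrix is rank deficient: {_collinear_columns(X1, names)}",
            columns=_collinear_columns(X1, names),
        )
    coef, *_ = np.linalg.lstsq(X1, y, rcond=None)
    return y - X1 @ coef


def pheno_expr_corr(cohort: CohortData) -> tuple[list[ObsCorrelation], list]:
    """Per-gene adjusted phenotype-expression Pearson correlations.

    Returns the correlations and a list of (gene_id, reason) for genes
    skipped (zero expression variance).  se(r) = sqrt((1-r^2)/(n-2)).
    """
    n = cohort.n
    pheno = inverse_normal_transform(cohort.phenotype)
    pheno_adj = adjust_covariates(pheno, cohort.covariates)

    expr_cov = cohort.covariates
    if cohort.expression_covariates is not None:
        expr_cov = pd.concat(
            [cohort.covariates.reset_index(drop=True),
             cohort.expression_covariates.reset_index(drop=True)],
            axis=1,
        )

    variances = np.ptp(cohort.expression, axis=0)
    skipped = [
        (cohort.gene_ids[i], "zero expression variance")
        for i in np.flatnonzero(variances == 0)
    ]
    keep = np.flatnonzero(variances > 0)
    expr = inverse_normal_transform(cohort.expression[:, keep])
    expr_adj = adjust_covariates(expr, expr_cov)

    # vectorized Pearson correlation of each residualized gene with phenotype
    pc = pheno_adj - pheno_adj.mean()
    ec = expr_adj - expr_adj.mean(axis=0)
    num = ec.T @ pc
    den = np.sqrt((ec**2).sum(axis=0) * (pc**2).sum())
    r = np.clip(num / den, -1.0, 1.0)
    se = np.sqrt(np.maximum(1e-300, 1.0 - r**2) / (n - 2))
    out = [
        ObsCorrelation(
            gene_id=str(cohort.gene_ids[i]), r=float(ri), se_r=float(si),
            n=n, cohort_id=cohort.cohort_id,
        )
        for i, ri, si in zip(keep, r, se)
    ]
    if skipped:
        logger.warning(
            "cohort %s: skipped %d gene(s) with zero variance",
            cohort.cohort_id, len(skipped),
        )
    return out, skipped


def meta_correlations(per_cohort: list[list[ObsCorrelation]]) -> list[ObsCorrelation]:
    """Fixed-effect inverse-variance meta-analysis on the Fisher-z scale.

    Each cohort contributes z = atanh(r) with weight n - 3; the combined z
    is back-transformed and its SE mapped to the r scale by the delta
    method.  Genes present in a single cohort pass through.
    """
    by_gene: dict[str, list[ObsCorrelation]] = {}
    for cohort_list in per_cohort:
        for oc in cohort_list:
            by_gene.setdefault(oc.gene_id, []).append(oc)
    out = []
    for gene_id, ocs in by_gene.items():
        z = np.array([math.atanh(max(-1 + 1e-15, min(1 - 1e-15, o.r))) for o in ocs])
        w = np.array([o.n - 3 for o in ocs], dtype=float)
        if np.any(w <= 0):
            raise ValueError(f"gene {gene_id}: cohort with n <= 3 cannot be meta-analyzed")
        z_meta = float(np.sum(w * z) / np.sum(w))
        se_z = math.sqrt(1.0 / float(np.sum(w)))
        r_meta = math.tanh(z_meta)
        se_r = (1.0 - r_meta**2) * se_z
        out.append(
            ObsCorrelation(
                gene_id=gene_id, r=r_meta, se_r=se_r,
                n=int(sum(o.n for o in ocs)), cohort_id="meta",
            )
        )
    return out


def correlations_to_frame(correlations: list[ObsCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in correlations],
            "r": [c.r for c in correlations],
            "se_r": [c.se_r for c in correlations],
            "n": [c.n for c in correlations],
            "cohort_id": [c.cohort_id for c in correlations],
        }
    )
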