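"""Reading, harmonizing and filtering GWAS / trans-eQTL summary statistics.

The unit of work downstream is the :class:`InstrumentSet`: per-SNP pairs of
standardized exposure effects (``beta``) and outcome effects (``gamma``) with
their standard errors, aligned to the same effect allele.  This module parses
the two summary-statistics tables, reconciles allele codings (including
strand flips), removes strand-ambiguous palindromic SNPs, and applies the
instrument-selection filters (genome-wide significance of the exposure
association and removal of SNPs with a larger outcome than exposure effect,
which flags likely reverse causation or confounding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DuplicateRecordError,
    EmptyInputError,
    NoInstrumentsError,
)

logger = logging.getLogger("revtwmr")

AUTOSOMES = {str(i) for i in range(1, 23)}
VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: allele pairs whose strand cannot be resolved from the alleles alone
PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})

#: default minimum instrument count below which a warning is emitted
MIN_INSTRUMENTS_WARN = 3


@dataclass(frozen=True)
class GwasRecord:
    """One SNP row of a GWAS summary-statistics table.

    Effects are standardized: SD of trait per SD of genotype.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_std: float
    se_beta: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    n: int | None = None


@dataclass(frozen=True)
class EqtlRecord:
    """One (SNP, gene) row of a trans-eQTL summary-statistics table.

    Allele fields are optional; when absent the effect is assumed to be
    reported on the same effect allele as the GWAS table.
    """

    snp_id: str
    gene_id: str
    gamma_std: float
    se_gamma: float
    pval: float
    n: int | None = None
    effect_allele: str | None = None
    other_allele: str | None = None


@dataclass
class InstrumentSet:
    """Harmonized per-SNP exposure/outcome effect pairs for one gene.

    ``beta`` is the exposure effect vector, ``gamma`` the outcome effect
    vector, aligned row by row.  ``ld`` is an optional pairwise LD matrix C
    (unit diagonal, entries in [-1, 1]); when None the identity is assumed,
    appropriate for strongly LD-pruned instruments.
    """

    gene_id: str
    trait_id: str
    snp_ids: tuple
    beta: np.ndarray
    se_beta: np.ndarray
    gamma: np.ndarray
    se_gamma: np.ndarray
    pval_beta: np.ndarray | None = None
    pval_gamma: np.ndarray | None = None
    ld: np.ndarray | None = None

    def __post_init__(self):
        self.snp_ids = tuple(str(s) for s in self.snp_ids)
        for name in ("beta", "se_beta", "gamma", "se_gamma"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.snp_ids)
        if n < 1:
            raise ValueError("InstrumentSet requires at least one SNP")
        for name in ("beta", "se_beta", "gamma", "se_gamma"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} has wrong length (expected {n})")
        if np.any(self.se_beta < 0) or np.any(self.se_gamma < 0):
            raise ValueError("standard errors must be non-negative")
        for name in ("pval_beta", "pval_gamma"):
            p = getattr(self, name)
            if p is not None:
                p = np.asarray(p, dtype=float)
                if p.shape != (n,):
                    raise ValueError(f"{name} has wrong length (expected {n})")
                setattr(self, name, p)
        if self.ld is not None:
            C = np.asarray(self.ld, dtype=float)
            if C.shape != (n, n):
                raise ValueError("LD matrix shape does not match instrument count")
            if not np.allclose(C, C.T, atol=1e-8):
                raise ValueError("LD matrix must be symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-8):
                raise ValueError("LD matrix must have unit diagonal")
            if np.any(np.abs(C) > 1 + 1e-8):
                raise ValueError("LD matrix entries must be in [-1, 1]")
            self.ld = C

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, indices: Sequence[int]) -> "InstrumentSet":
        """Row-aligned subset preserving order of ``indices``."""
        idx = np.asarray(indices, dtype=int)
        return InstrumentSet(
            gene_id=self.gene_id,
            trait_id=self.trait_id,
            snp_ids=tuple(self.snp_ids[i] for i in idx),
            beta=self.beta[idx],
            se_beta=self.se_beta[idx],
            gamma=self.gamma[idx],
            se_gamma=self.se_gamma[idx],
            pval_beta=None if self.pval_beta is None else self.pval_beta[idx],
            pval_gamma=None if self.pval_gamma is None else self.pval_gamma[idx],
            ld=None if self.ld is None else self.ld[np.ix_(idx, idx)],
        )

    def drop_snp(self, snp_id: str) -> "InstrumentSet":
        keep = [i for i, s in enumerate(self.snp_ids) if s != snp_id]
        if len(keep) == self.n_snps:
            raise KeyError(f"SNP {snp_id!r} not in instrument set")
        return self.subset(keep)

    def swapped(self) -> "InstrumentSet":
        """Exchange exposure and outcome roles (forward <-> reverse MR)."""
        return InstrumentSet(
            gene_id=self.gene_id,
            trait_id=self.trait_id,
            snp_ids=self.snp_ids,
            beta=self.gamma.copy(),
            se_beta=self.se_gamma.copy(),
            gamma=self.beta.copy(),
            se_gamma=self.se_beta.copy(),
            pval_beta=None if self.pval_gamma is None else self.pval_gamma.copy(),
            pval_gamma=None if self.pval_beta is None else self.pval_beta.copy(),
            ld=None if self.ld is None else self.ld.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "snp_id": list(self.snp_ids),
                "beta": self.beta,
                "se_beta": self.se_beta,
                "gamma": self.gamma,
                "se_gamma": self.se_gamma,
            }
        )
        if self.pval_beta is not None:
            df["pval_beta"] = self.pval_beta
        if self.pval_gamma is not None:
            df["pval_gamma"] = self.pval_gamma
        return df


DEFAULT_GWAS_COLUMNS: dict[str, str] = {
    "snp_id": "snp_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

DEFAULT_EQTL_COLUMNS: dict[str, str] = {
    "snp_id": "snp_id",
    "gene_id": "gene_id",
    "gamma": "gamma",
    "se": "se",
    "pval": "pval",
    "n": "n",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
}

_GWAS_MANDATORY = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")
_EQTL_MANDATORY = ("snp_id", "gene_id", "gamma", "se", "pval")


def _read_table(path, column_map, defaults, mandatory) -> tuple[pd.DataFrame, dict]:
    cm = dict(defaults)
    if column_map:
        unknown = set(column_map) - set(defaults)
        if unknown:
            raise ConfigurationError(
                f"unknown column-map keys: {sorted(unknown)}"
            )
        cm.update(column_map)
    try:
        df = pd.read_csv(path, sep="\t", compression="infer")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    for key in mandatory:
        if cm[key] not in df.columns:
            raise ConfigurationError(
                f"{path}: mandatory column {cm[key]!r} (field {key!r}) not found"
            )
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    return df, cm


def _normalize_chrom(value) -> str | None:
    if pd.isna(value):
        return None
    s = str(value).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.endswith(".0"):  # pandas float-parsed integer chromosomes
        s = s[:-2]
    return s


def read_gwas(path, column_map: Mapping[str, str] | None = None) -> list[GwasRecord]:
    """Parse a GWAS summary-statistics TSV (optionally gzipped).

    ``column_map`` maps field names (keys of :data:`DEFAULT_GWAS_COLUMNS`)
    to the actual header names.  Rows with missing mandatory fields,
    non-single-base or invalid alleles, non-positive SEs, out-of-range
    p-values, or non-autosomal chromosomes are dropped with a logged count.
    """
    df, cm = _read_table(path, column_map, DEFAULT_GWAS_COLUMNS, _GWAS_MANDATORY)

    n_total = len(df)
    mand_cols = [cm[k] for k in _GWAS_MANDATORY]
    df = df.dropna(subset=mand_cols)
    n_missing = n_total - len(df)
    if n_missing:
        logger.warning("%s: dropped %d rows with missing mandatory fields", path, n_missing)

    records: list[GwasRecord] = []
    n_bad_allele = n_bad_value = n_nonauto = 0
    has_chrom = cm["chrom"] in df.columns
    has_pos = cm["pos"] in df.columns
    has_n = cm["n"] in df.columns
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        ea = str(row[cm["effect_allele"]]).strip().upper()
        oa = str(row[cm["other_allele"]]).strip().upper()
        if (
            len(ea) != 1
            or len(oa) != 1
            or ea not in VALID_BASES
            or oa not in VALID_BASES
            or ea == oa
        ):
            n_bad_allele += 1
            continue
        se = float(row[cm["se"]])
        pval = float(row[cm["pval"]])
        if se <= 0 or not (0.0 <= pval <= 1.0):
            n_bad_value += 1
            continue
        chrom = _normalize_chrom(row[cm["chrom"]]) if has_chrom else None
        if has_chrom and chrom not in AUTOSOMES:
            n_nonauto += 1
            continue
        records.append(
            GwasRecord(
                snp_id=str(row[cm["snp_id"]]),
                effect_allele=ea,
                other_allele=oa,
                beta_std=float(row[cm["beta"]]),
                se_beta=se,
                pval=pval,
                chrom=chrom,
                pos=int(row[cm["pos"]]) if has_pos and not pd.isna(row[cm["pos"]]) else None,
                n=int(row[cm["n"]]) if has_n and not pd.isna(row[cm["n"]]) else None,
            )
        )
    if n_bad_allele:
        logger.warning("%s: dropped %d rows with invalid alleles", path, n_bad_allele)
    if n_bad_value:
        logger.warning("%s: dropped %d rows with invalid SE or p-value", path, n_bad_value)
    if n_nonauto:
        logger.warning("%s: dropped %d non-autosomal rows", path, n_nonauto)
    return records


def read_eqtl(path, column_map: Mapping[str, str] | None = None) -> list[EqtlRecord]:
    """Parse a long-format trans-eQTL TSV keyed by (SNP, gene).

    Duplicate (SNP, gene) keys are a hard error; rows with non-positive SE
    or out-of-range p-values are dropped with a warning.
    """
    df, cm = _read_table(path, column_map, DEFAULT_EQTL_COLUMNS, _EQTL_MANDATORY)

    n_total = len(df)
    mand_cols = [cm[k] for k in _EQTL_MANDATORY]
    df = df.dropna(subset=mand_cols)
    if n_total - len(df):
        logger.warning(
            "%s: dropped %d rows with missing mandatory fields", path, n_total - len(df)
        )

    key_cols = [cm["snp_id"], cm["gene_id"]]
    dup_mask = df.duplicated(subset=key_cols, keep=False)
    if dup_mask.any():
        dups = sorted(set(map(tuple, df.loc[dup_mask, key_cols].astype(str).values)))
        raise DuplicateRecordError(
            f"{path}: duplicate (snp, gene) rows: {dups[:20]}", duplicates=dups
        )

    has_n = cm["n"] in df.columns
    has_ea = cm["effect_allele"] in df.columns
    has_oa = cm["other_allele"] in df.columns
    records: list[EqtlRecord] = []
    n_bad = 0
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        se = float(row[cm["se"]])
        pval = float(row[cm["pval"]])
        if se <= 0 or not (0.0 <= pval <= 1.0):
            n_bad += 1
            continue
        ea = str(row[cm["effect_allele"]]).strip().upper() if has_ea and not pd.isna(row[cm["effect_allele"]]) else None
        oa = str(row[cm["other_allele"]]).strip().upper() if has_oa and not pd.isna(row[cm["other_allele"]]) else None
        records.append(
            EqtlRecord(
                snp_id=str(row[cm["snp_id"]]),
                gene_id=str(row[cm["gene_id"]]),
                gamma_std=float(row[cm["gamma"]]),
                se_gamma=se,
                pval=pval,
                n=int(row[cm["n"]]) if has_n and not pd.isna(row[cm["n"]]) else None,
                effect_allele=ea,
                other_allele=oa,
            )
        )
    if n_bad:
        logger.warning("%s: dropped %d rows with invalid SE or p-value", path, n_bad)
    return records


def standardize_effects(beta_raw, se_raw, n):
    """Convert raw effect estimates to the standardized scale.

    The convention is beta_std = z / sqrt(n), se_std = 1 / sqrt(n), which
    preserves the z-score and puts effects from different traits on a
    comparable per-SD scale.  Requires n > 1 and se_raw > 0.
    """
    beta_raw = np.asarray(beta_raw, dtype=float)
    se_raw = np.asarray(se_raw, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 1):
        raise ValueError("sample size n must be > 1 to standardize effects")
    if np.any(se_raw <= 0):
        raise ValueError("se_raw must be positive")
    z = beta_raw / se_raw
    se_std = 1.0 / np.sqrt(n)
    beta_std = z * se_std
    if beta_std.ndim == 0:
        return float(beta_std), float(se_std)
    return beta_std, np.broadcast_to(se_std, beta_std.shape).copy()


def gwas_records_from_frame(df: pd.DataFrame, column_map: Mapping[str, str] | None = None) -> list[GwasRecord]:
    """Build records from an in-memory GWAS table (default column names)."""
    cm = dict(DEFAULT_GWAS_COLUMNS)
    if column_map:
        cm.update(column_map)
    has_chrom, has_pos, has_n = (cm[k] in df.columns for k in ("chrom", "pos", "n"))
    return [
        GwasRecord(
            snp_id=str(getattr(r, cm["snp_id"])),
            effect_allele=str(getattr(r, cm["effect_allele"])),
            other_allele=str(getattr(r, cm["other_allele"])),
            beta_std=float(getattr(r, cm["beta"])),
            se_beta=float(getattr(r, cm["se"])),
            pval=float(getattr(r, cm["pval"])),
            chrom=str(getattr(r, cm["chrom"])) if has_chrom else None,
            pos=int(getattr(r, cm["pos"])) if has_pos else None,
            n=int(getattr(r, cm["n"])) if has_n else None,
        )
        for r in df.itertuples(index=False)
    ]


def eqtl_records_from_frame(df: pd.DataFrame, column_map: Mapping[str, str] | None = None) -> list[EqtlRecord]:
    """Build records from an in-memory trans-eQTL table."""
    cm = dict(DEFAULT_EQTL_COLUMNS)
    if column_map:
        cm.update(column_map)
    has_n = cm["n"] in df.columns
    has_ea = cm["effect_allele"] in df.columns
    has_oa = cm["other_allele"] in df.columns
    return [
        EqtlRecord(
            snp_id=str(getattr(r, cm["snp_id"])),
            gene_id=str(getattr(r, cm["gene_id"])),
            gamma_std=float(getattr(r, cm["gamma"])),
            se_gamma=float(getattr(r, cm["se"])),
            pval=float(getattr(r, cm["pval"])),
            n=int(getattr(r, cm["n"])) if has_n else None,
            effect_allele=str(getattr(r, cm["effect_allele"])) if has_ea else None,
            other_allele=str(getattr(r, cm["other_allele"])) if has_oa else None,
        )
        for r in df.itertuples(index=False)
    ]


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in PALINDROMIC_PAIRS


def _align_sign(gwas: GwasRecord, eqtl: EqtlRecord) -> float | None:
    """Return the sign to apply to gamma, or None if irreconcilable.

    Tries the direct coding, the swapped coding (sign flip), and both after
    complementing the eQTL alleles (opposite-strand report).  Palindromic
    SNPs never reach this point.
    """
    if eqtl.effect_allele is None:
        return 1.0
    ea, oa = eqtl.effect_allele, eqtl.other_allele
    if oa is None:
        if ea == gwas.effect_allele:
            return 1.0
        if ea == gwas.other_allele:
            return -1.0
        return None
    candidates = [(ea, oa, 1.0), (oa, ea, -1.0)]
    if ea in COMPLEMENT and oa in COMPLEMENT:
        cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
        candidates += [(cea, coa, 1.0), (coa, cea, -1.0)]
    for a1, a2, sign in candidates:
        if a1 == gwas.effect_allele and a2 == gwas.other_allele:
            return sign
    return None


def harmonize(
    gwas_records: Iterable[GwasRecord],
    eqtl_records: Iterable[EqtlRecord],
    gene_id: str,
    trait_id: str = "trait",
) -> InstrumentSet:
    """Build a harmonized :class:`InstrumentSet` for one gene.

    Shared SNPs are aligned to the GWAS effect allele (sign-flipping the
    trans-eQTL effect when the alleles are swapped or strand-flipped),
    strand-ambiguous (A/T, C/G) SNPs are removed, and SNPs whose allele
    sets cannot be reconciled are dropped with a warning.
    """
    gwas_by_snp: dict[str, GwasRecord] = {}
    for rec in gwas_records:
        gwas_by_snp.setdefault(rec.snp_id, rec)
    eqtl_by_snp = {rec.snp_id: rec for rec in eqtl_records if rec.gene_id == gene_id}

    snp_ids, beta, se_beta, gamma, se_gamma, pb, pg = [], [], [], [], [], [], []
    n_palindromic = n_irreconcilable = 0
    for snp_id, g in gwas_by_snp.items():
        e = eqtl_by_snp.get(snp_id)
        if e is None:
            continue
        if _is_palindromic(g.effect_allele, g.other_allele):
            n_palindromic += 1
            continue
        sign = _align_sign(g, e)
        if sign is None:
            n_irreconcilable += 1
            logger.warning(
                "gene %s: SNP %s has irreconcilable alleles (%s/%s vs %s/%s); dropped",
                gene_id, snp_id, g.effect_allele, g.other_allele,
                e.effect_allele, e.other_allele,
            )
            continue
        snp_ids.append(snp_id)
        beta.append(g.beta_std)
        se_beta.append(g.se_beta)
        gamma.append(sign * e.gamma_std)
        se_gamma.append(e.se_gamma)
        pb.append(g.pval)
        pg.append(e.pval)

    if not snp_ids:
        raise NoInstrumentsError(
            f"gene {gene_id}: no shared SNPs survive harmonization",
            removal_counts={
                "palindromic": n_palindromic,
                "irreconcilable": n_irreconcilable,
            },
        )
    return InstrumentSet(
        gene_id=gene_id,
        trait_id=trait_id,
        snp_ids=tuple(snp_ids),
        beta=np.array(beta),
        se_beta=np.array(se_beta),
        gamma=np.array(gamma),
        se_gamma=np.array(se_gamma),
        pval_beta=np.array(pb),
        pval_gamma=np.array(pg),
    )


def select_instruments(
    iset: InstrumentSet,
    p_max: float = 5e-8,
    drop_reverse: bool = True,
) -> InstrumentSet:
    """Apply the instrument-selection filters, preserving SNP order.

    Keeps SNPs whose exposure association reaches ``p_max`` (genome-wide
    significance by default) and, when ``drop_reverse``, removes SNPs with a
    larger absolute effect on the outcome than on the exposure — such SNPs
    likely act on the exposure through the outcome or a confounder.
    Instruments are assumed already LD-pruned unless an LD matrix is given.
    """
    if iset.pval_beta is None:
        raise ConfigurationError(
            "select_instruments requires exposure p-values (pval_beta)"
        )
    keep_p = iset.pval_beta < p_max
    keep_rev = np.abs(iset.gamma) <= np.abs(iset.beta) if drop_reverse else np.ones(
        iset.n_snps, dtype=bool
    )
    keep = keep_p & keep_rev
    counts = {
        "not_significant": int(np.sum(~keep_p)),
        "reverse_effect": int(np.sum(keep_p & ~keep_rev)),
    }
    if not keep.any():
        raise NoInstrumentsError(
            f"gene {iset.gene_id}: no instruments pass selection", removal_counts=counts
        )
    out = iset.subset(np.flatnonzero(keep))
    if out.n_snps < MIN_INSTRUMENTS_WARN:
        logger.warning(
            "gene %s: only %d instrument(s) after selection", iset.gene_id, out.n_snps
        )
    return out


def write_instruments(iset: InstrumentSet, path) -> None:
    """Write a harmonized instrument table as TSV."""
    iset.to_frame().to_csv(path, sep="\t", index=False)


def read_instruments(path, gene_id: str = "gene", trait_id: str = "trait") -> InstrumentSet:
    """Read an instrument table written by :func:`write_instruments`."""
    df = pd.read_csv(path, sep="\t")
    return InstrumentSet(
        gene_id=gene_id,
        trait_id=trait_id,
        snp_ids=tuple(df["snp_id"].astype(str)),
        beta=df["beta"].to_numpy(),
        se_beta=df["se_beta"].to_numpy(),
        gamma=df["gamma"].to_numpy(),
        se_gamma=df["se_gamma"].to_numpy(),
        pval_beta=df["pval_beta"].to_numpy() if "pval_beta" in df else None,
        pval_gamma=df["pval_gamma"].to_numpy() if "pval_gamma" in df else None,
    )
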