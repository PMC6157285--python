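"""Regression scans: EWAS of log TG on methylation, GWAS/EWAS of TG change.

The exploratory stages around the network analysis are ordinary linear
regressions of log triglyceride levels. The per-visit EWAS regresses
log(TG) at a visit on each CpG's beta-value with age, sex, center and
four methylation principal components as covariates. The change-in-TG
scans regress log(TG4) on a marker with log(TG2) among the covariates:
conditioning the post-treatment level on the pre-treatment level tests
association with the drug response rather than with baseline TG. Scan
summaries report the genomic-control inflation factor lambda (median
association chi-square over its null median) and the Bonferroni
threshold alpha/m.

Individuals are treated as unrelated (no mixed-model relatedness
adjustment); missing data are handled complete-case per regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA

from .cohort import CohortTable, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionSpec",
    "AssocResult",
    "fit_ols",
    "methylation_pcs",
    "run_ewas",
    "run_gwas_change",
    "lambda_gc",
    "bonferroni",
    "qq_table",
    "SingularDesignError",
    "DimensionError",
]

CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.45494


class SingularDesignError(ValueError):
    """Design matrix is rank-deficient; message names the collinear columns."""


class DimensionError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionSpec:
    """One marker regression: outcome ~ exposure + covariates.

    Discrete covariates are expanded to indicator terms in the design.
    """

    outcome: str
    exposure: str
    covariates: tuple = ()

    def __post_init__(self) -> None:
        if self.outcome == self.exposure:
            raise SchemaError("outcome and exposure must be distinct")


@dataclass
class AssocResult:
    """Per-marker coefficient table plus scan-level summaries."""

    table: pd.DataFrame  # marker, beta, se, t, p, n
    lambda_gc: float
    bonferroni: float
    m: int
    alpha: float
    skipped: list[str] = field(default_factory=list)

    def significant(self) -> pd.DataFrame:
        """Markers passing the Bonferroni threshold (strict less-than)."""
        return self.table[self.table["p"] < self.bonferroni]


# ---------------------------------------------------------------------------
# primitives


def fit_ols(y, design: pd.DataFrame) -> pd.DataFrame:
    """Least-squares fit of ``y`` on a design matrix that includes its intercept.

    Complete-case: rows with any missing value are dropped. Returns one
    row per design column with estimate, se, t and the two-sided p-value
    from the t distribution on n - k df. Rank-deficient designs raise
    :class:`SingularDesignError` naming the collinear columns.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=design.index, name="y")
    X = design.astype(float)
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    n, k = X.shape
    if n <= k:
        raise SchemaError(f"need more rows ({n}) than design columns ({k})")
    Xv = X.to_numpy()
    if np.linalg.matrix_rank(Xv) < k:
        collinear = _collinear_columns(X)
        raise SingularDesignError(f"design is rank deficient; collinear columns: {collinear}")
    res = sm.OLS(y.to_numpy(), Xv).fit()
    return pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
            "n": n,
        },
        index=list(X.columns),
    )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    Xv = X.to_numpy()
    full_rank = np.linalg.matrix_rank(Xv)
    out = []
    for j, col in enumerate(X.columns):
        rest = np.delete(Xv, j, axis=1)
        if np.linalg.matrix_rank(rest) == full_rank:  # dropping j loses nothing
            out.append(str(col))
    return out


def methylation_pcs(cpg_matrix, k: int) -> np.ndarray:
    """Top-``k`` principal-component scores of a CpG beta-value matrix.

    The matrix (individuals x CpGs) is column-centered; scores come back
    ordered by decreasing explained variance and mutually orthogonal.
    """
    M = np.asarray(cpg_matrix, dtype=float)
    if M.ndim != 2:
        raise DimensionError("cpg_matrix must be 2-dimensional")
    if np.isnan(M).any():
        raise DimensionError("cpg_matrix must be complete (no missing values)")
    if not 1 <= k <= min(M.shape):
        raise DimensionError(f"k={k} out of range for matrix of shape {M.shape}")
    centered = M - M.mean(axis=0)
    if k > np.linalg.matrix_rank(centered):
        raise DimensionError(f"k={k} exceeds matrix rank {np.linalg.matrix_rank(centered)}")
    return PCA(n_components=k, svd_solver="full").fit_transform(centered)


def lambda_gc(pvalues) -> float:
    """Genomic-control inflation factor of a scan's p-values.

    Median of the implied 1-df chi-square statistics divided by the
    1-df chi-square median (0.4549); 1.0 indicates a calibrated scan.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def qq_table(pvalues) -> pd.DataFrame:
    """Observed vs expected -log10 p for a QQ plot (sorted ascending p)."""
    p = np.sort(np.asarray(list(pvalues), dtype=float))
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    return pd.DataFrame({"obs_neglog10p": -np.log10(p), "exp_neglog10p": expected})


# ---------------------------------------------------------------------------
# scans


def _log_tg(cohort: CohortTable, col: str) -> pd.Series:
    vals = cohort.data[col].astype(float)
    if (vals.dropna() <= 0).any():
        raise ValueError(f"{col} must be strictly positive before logging")
    return np.log(vals)


def _covariate_design(cohort: CohortTable, covariates: list[str]) -> pd.DataFrame:
    """Intercept + covariates with discrete columns expanded to indicators."""
    parts = [pd.Series(1.0, index=cohort.data.index, name="intercept")]
    for c in covariates:
        if cohort.kinds[c] == "discrete":
            dummies = pd.get_dummies(cohort.data[c].astype("category"),
                                     prefix=c, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(cohort.data[c].astype(float))
    return pd.concat(parts, axis=1)


def _cpg_columns(cohort: CohortTable, markers=None) -> list[str]:
    if markers is not None:
        return list(markers)
    out = [c for c in cohort.columns_of_kind("continuous") if c.startswith("cg")]
    if not out:
        raise SchemaError("no CpG columns found (continuous columns named cg*)")
    return out


def _scan(cohort, outcome, markers, base_design, alpha) -> AssocResult:
    rows, skipped = [], []
    for marker in markers:
        design = base_design.copy()
        design.insert(1, marker, cohort.data[marker].astype(float))
        try:
            fit = fit_ols(outcome, design)
        except SingularDesignError:
            logger.warning("marker %s skipped: singular design", marker)
            skipped.append(marker)
            continue
        row = fit.loc[marker]
        rows.append({"marker": marker, "beta": row["estimate"], "se": row["se"],
                     "t": row["t"], "p": row["p"], "n": int(row["n"])})
    if not rows:
        raise SchemaError("no markers could be tested")
    table = pd.DataFrame(rows)
    m = len(table)
    return AssocResult(
        table=table,
        lambda_gc=lambda_gc(table["p"]),
        bonferroni=bonferroni(alpha, m),
        m=m,
        alpha=alpha,
        skipped=skipped,
    )


def run_ewas(
    cohort: CohortTable,
    visit: int = 2,
    change_model: bool = False,
    n_pcs: int = 4,
    alpha: float = 0.05,
    markers=None,
) -> AssocResult:
    """Per-CpG regression of log TG on methylation.

    ``visit`` selects the outcome (TG2 or TG4, logged internally);
    covariates are age, sex, center and ``n_pcs`` principal components of
    the tested CpG matrix. With ``change_model`` the outcome is log(TG4)
    and log(TG2) joins the covariates, so each CpG is tested against the
    drug response. CpG columns are the continuous ``cg*`` columns unless
    ``markers`` is given.
    """
    if visit not in (2, 4):
        raise ValueError("visit must be 2 or 4")
    cpgs = _cpg_columns(cohort, markers)
    outcome = _log_tg(cohort, "TG4" if (change_model or visit == 4) else "TG2")
    design = _covariate_design(cohort, ["age", "sex", "center"])
    if change_model:
        design["log_TG2"] = _log_tg(cohort, "TG2")
    if n_pcs > 0:
        M = cohort.data[cpgs].to_numpy(dtype=float)
        if np.isnan(M).any():
            complete = ~np.isnan(M).any(axis=1)
            scores = np.full((cohort.n, n_pcs), np.nan)
            scores[complete] = methylation_pcs(M[complete], n_pcs)
        else:
            scores = methylation_pcs(M, n_pcs)
        for j in range(n_pcs):
            design[f"pc{j + 1}"] = scores[:, j]
    return _scan(cohort, outcome, cpgs, design, alpha)


def run_gwas_change(
    cohort: CohortTable,
    maf_min: float = 0.01,
    alpha: float = 0.05,
) -> AssocResult:
    """Per-SNP regression of log(TG4) on dosage with log(TG2), age, sex, center.

    SNPs are the cohort's genotype columns; markers with minor allele
    frequency at or below ``maf_min`` are excluded before testing, and
    monomorphic markers are skipped with a logged warning.
    """
    snps = cohort.columns_of_kind("genotype")
    if not snps:
        raise SchemaError("no genotype columns in cohort")
    outcome = _log_tg(cohort, "TG4")
    design = _covariate_design(cohort, ["age", "sex", "center"])
    design["log_TG2"] = _log_tg(cohort, "TG2")
    kept, skipped = [], []
    for snp in snps:
        dosage = cohort.data[snp].dropna().astype(float)
        freq = dosage.mean() / 2.0
        maf = min(freq, 1.0 - freq)
        if maf <= maf_min:
            if dosage.nunique() <= 1:
                logger.warning("SNP %s skipped: monomorphic", snp)
            else:
                logger.info("SNP %s excluded: maf %.4g <= %.4g", snp, maf, maf_min)
            skipped.append(snp)
            continue
        kept.append(snp)
    if not kept:
        raise SchemaError("no SNPs pass the MAF filter")
    result = _scan(cohort, outcome, kept, design, alpha)
    result.skipped = skipped + result.skipped
    return result
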