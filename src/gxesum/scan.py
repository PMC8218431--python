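"""SNP-by-environment interaction GWAS.

The outcome is first pre-adjusted (OLS residuals on confounders plus the
main effect of E), then each SNP is fit with ``y = a + b_m * x_j +
b_1 * (x_j * E) + e`` and the interaction coefficient's Wald chi-square
``(b_1 / se_1)^2`` is emitted. Binary 0/1 outcomes use the same linear
model. The scan is vectorized via per-SNP 3x3 normal equations but matches
the one-SNP-at-a-time OLS fit exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .simulate import EnvironmentVector, GenotypeMatrix, PhenotypeVector, _standardize

__all__ = [
    "CovariateMatrix",
    "InteractionSummaryStats",
    "preadjust_phenotype",
    "interaction_scan",
]

logger = logging.getLogger(__name__)


@dataclass
class CovariateMatrix:
    """Named per-individual covariates, including an intercept column.

    Construction drops exactly duplicated/constant extra columns and then
    requires full column rank.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        if "intercept" not in df.columns:
            df.insert(0, "intercept", 1.0)
        # drop constant columns other than the intercept, then duplicates
        for col in [c for c in df.columns if c != "intercept"]:
            if df[col].nunique(dropna=True) <= 1:
                df = df.drop(columns=col)
        df = df.T.drop_duplicates().T
        self.data = df

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def validate_rank(self) -> None:
        vals = np.nan_to_num(self.values())
        if np.linalg.matrix_rank(vals) < vals.shape[1]:
            raise ValueError("covariate matrix is rank deficient")

    @classmethod
    def from_environment(cls, E: EnvironmentVector) -> "CovariateMatrix":
        return cls(pd.DataFrame({"E": E.values}))


@dataclass
class InteractionSummaryStats:
    """Per-SNP interaction-effect estimates and Wald chi-squares."""

    snp_ids: np.ndarray
    beta1_hat: np.ndarray
    se1: np.ndarray
    chisq: np.ndarray
    n_eff: np.ndarray

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": self.snp_ids,
                "N": self.n_eff,
                "BETA1": self.beta1_hat,
                "SE1": self.se1,
                "CHISQ": self.chisq,
                "Z": self.beta1_hat / self.se1,
            }
        )


def preadjust_phenotype(
    y: Union[PhenotypeVector, np.ndarray],
    covariates: CovariateMatrix,
    impute_missing: bool = False,
    return_mask: bool = False,
):
    """Residualize the outcome on confounders and the main effect of E.

    Returns OLS residuals re-standardized to unit variance. With
    ``impute_missing`` missing phenotype/covariate entries are replaced by
    their column mean (maximizing the usable sample size); otherwise rows
    with any missing value are dropped — pass ``return_mask=True`` to also
    get the boolean kept-row mask, so genotypes and environment can be
    subset consistently before the scan.
    """
    yv = np.asarray(y.y if isinstance(y, PhenotypeVector) else y, dtype=float)
    df = covariates.data.copy()
    if len(df) != len(yv):
        raise ValueError("phenotype and covariates have different lengths")
    df["_y"] = yv
    if impute_missing:
        df = df.fillna(df.mean())
        kept = np.ones(len(df), dtype=bool)
    else:
        kept = ~df.isna().any(axis=1).to_numpy()
        df = df[kept]
    C = df.drop(columns="_y").to_numpy(dtype=float)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    yy = df["_y"].to_numpy()
    coef, *_ = np.linalg.lstsq(C, yy, rcond=None)
    resid = yy - C @ coef
    out = PhenotypeVector(_standardize(resid), components={})
    return (out, kept) if return_mask else out


def interaction_scan(
    y_adj: Union[PhenotypeVector, np.ndarray],
    X: GenotypeMatrix,
    E: EnvironmentVector,
    robust_se: bool = False,
    _precomputed_sq: Optional[np.ndarray] = None,
) -> InteractionSummaryStats:
    """Per-SNP linear fit of main + interaction effects.

    For every SNP j the model ``y = a + b_m x_j + b_1 (x_j * E) + e`` is fit
    by least squares on standardized genotypes and standardized E; the
    returned chi-square is the squared t-ratio of the interaction
    coefficient (homoskedastic SE by default; ``robust_se`` switches to the
    HC0 sandwich). SNPs with a constant interaction column are dropped with
    a log entry.
    """
    yv = np.asarray(y_adj.y if isinstance(y_adj, PhenotypeVector) else y_adj, float)
    Xs = X.standardized
    e = np.asarray(E.values, dtype=float)
    n, m = Xs.shape
    if len(yv) != n or len(e) != n:
        raise ValueError("dimension mismatch between y, X, and E")
    if n < 4:
        raise ValueError("need at least 4 individuals for the 3-parameter fit")
    if np.var(e) == 0:
        raise ValueError("environment is constant; no interaction column exists")

    X2 = Xs**2 if _precomputed_sq is None else _precomputed_sq
    e2 = e * e
    ones = np.ones(n)

    s1 = Xs.T @ ones
    sxe = Xs.T @ e
    s2 = X2.T @ ones
    s2e = X2.T @ e
    s2e2 = X2.T @ e2
    sy = float(yv.sum())
    sxy = Xs.T @ yv
    sxey = Xs.T @ (e * yv)
    yty = float(yv @ yv)

    A = np.empty((m, 3, 3))
    A[:, 0, 0] = n
    A[:, 0, 1] = A[:, 1, 0] = s1
    A[:, 0, 2] = A[:, 2, 0] = sxe
    A[:, 1, 1] = s2
    A[:, 1, 2] = A[:, 2, 1] = s2e
    A[:, 2, 2] = s2e2
    b = np.stack([np.full(m, sy), sxy, sxey], axis=1)

    # drop SNPs whose interaction column is (numerically) constant:
    # Var(x_j * e) = s2e2/n - (sxe/n)^2 on standardized columns
    var_int = s2e2 / n - (sxe / n) ** 2
    ok = var_int > 1e-12
    dropped = np.flatnonzero(~ok)
    if dropped.size:
        logger.warning(
            "dropping %d SNP(s) with constant interaction column: %s",
            dropped.size,
            list(np.asarray(X.snp_ids)[dropped[:10]]),
        )
    idx = np.flatnonzero(ok)
    A, b = A[idx], b[idx]

    Ainv = np.linalg.inv(A)
    beta = np.einsum("mij,mj->mi", Ainv, b)
    rss = yty - np.einsum("mi,mi->m", beta, b)
    dof = n - 3
    sigma2 = np.maximum(rss, 0.0) / dof
    if robust_se:
        resid_var = _hc0_interaction_var(yv, Xs[:, idx], e, beta, Ainv)
        se1 = np.sqrt(resid_var)
    else:
        se1 = np.sqrt(sigma2 * Ainv[:, 2, 2])
    b1 = beta[:, 2]
    chisq = (b1 / se1) ** 2
    return InteractionSummaryStats(
        snp_ids=np.asarray(X.snp_ids)[idx],
        beta1_hat=b1,
        se1=se1,
        chisq=chisq,
        n_eff=np.full(idx.size, n),
    )


def _hc0_interaction_var(yv, Xs, e, beta, Ainv):
    """HC0 sandwich variance of the interaction coefficient, per SNP."""
    m = Xs.shape[1]
    out = np.empty(m)
    for j in range(m):
        D = np.column_stack([np.ones_like(e), Xs[:, j], Xs[:, j] * e])
        u = yv - D @ beta[j]
        meat = D.T @ (D * (u**2)[:, None])
        V = Ainv[j] @ meat @ Ainv[j]
        out[j] = V[2, 2]
    return out
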