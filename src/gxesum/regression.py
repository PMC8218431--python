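"""LD score regression on interaction chi-squares (the GxEsum estimator).

Under a polygenic reaction-norm model the expected per-SNP interaction
chi-square is linear in the LD score:

    E[chisq_j] = (N * h2_g1 / M) * l_j + 1 + (k - 1) * (h2_g1 + h2_tau1)

with N the sample size, M the SNP count, l_j the LD score and k the
kurtosis of the environment (k = 3 for a normal E, giving the familiar
intercept 1 + 2*(h2_g1 + h2_tau1)). A weighted regression of chi-square on
LD score therefore yields the GxE variance fraction h2_g1 from the slope,
while residual-by-environment (RxE) heterogeneity and scale effects are
absorbed by the intercept, from which h2_tau1 is recovered. Uncertainty
comes from a delete-one-block jackknife over contiguous SNP blocks and
significance from a Wald test; binary-trait estimates are moved to the
liability scale with the Robertson transformation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .ldscore import LDScoreTable
from .scan import InteractionSummaryStats

__all__ = [
    "GxESum",
    "GxEEstimate",
    "fit_gxesum",
    "jackknife_se",
    "wald_test",
    "observed_to_liability",
    "rxe_from_intercept",
]

logger = logging.getLogger(__name__)


@dataclass
class GxEEstimate:
    """Fitted GxE variance decomposition and its uncertainty."""

    h2_g1: float
    se_h2_g1: float
    intercept: float
    se_intercept: float
    h2_tau1: float
    kurtosis_used: float
    p_wald: float
    n: float
    m: int
    scale: str = "observed"
    prevalence: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "h2_g1": self.h2_g1,
            "se": self.se_h2_g1,
            "intercept": self.intercept,
            "se_intercept": self.se_intercept,
            "h2_tau1": self.h2_tau1,
            "kurtosis": self.kurtosis_used,
            "p": self.p_wald,
            "n": self.n,
            "m": self.m,
            "scale": self.scale,
            "prevalence": self.prevalence,
        }


def wald_test(h2_g1: float, se: float) -> float:
    """Two-sided normal p-value for H0: h2_g1 = 0."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = h2_g1 / se
    return float(2.0 * stats.norm.sf(abs(z)))


def rxe_from_intercept(intercept: float, h2_g1: float, kurtosis: float = 3.0) -> float:
    """Recover the RxE variance fraction from the fitted intercept.

    ``h2_tau1 = (intercept - 1 - (k - 1) * h2_g1) / (k - 1)``; at k = 3 this
    is the normal-environment special case (intercept - 1 - 2*h2_g1)/2.
    Negative values (estimation noise) are returned as-is with a warning.
    """
    if kurtosis <= 1:
        raise ValueError("kurtosis must exceed 1")
    h2_tau1 = (intercept - 1.0 - (kurtosis - 1.0) * h2_g1) / (kurtosis - 1.0)
    if h2_tau1 < 0:
        warnings.warn(
            f"negative RxE estimate {h2_tau1:.4g} (estimation noise)", stacklevel=2
        )
    return h2_tau1


def observed_to_liability(estimate: GxEEstimate, prevalence: float) -> GxEEstimate:
    """Robertson transformation of an observed-scale 0/1-trait estimate.

    Multiplies h2_g1 and its SE by ``k(1-k)/z^2`` with z the standard-normal
    density at the liability threshold Phi^-1(1-k). The factor is pi/2 at
    k = 0.5 and grows without bound as k approaches 0 or 1.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie strictly in (0, 1)")
    if estimate.scale != "observed":
        raise ValueError("estimate is not on the observed scale")
    t = stats.norm.ppf(1.0 - prevalence)
    z = stats.norm.pdf(t)
    factor = prevalence * (1.0 - prevalence) / z**2
    return replace(
        estimate,
        h2_g1=estimate.h2_g1 * factor,
        se_h2_g1=estimate.se_h2_g1 * factor,
        scale="liability",
        prevalence=prevalence,
    )


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Closed-form weighted least squares of y on x with free intercept."""
    W = w.sum()
    sx = w @ x
    sy = w @ y
    sxx = w @ (x * x)
    sxy = w @ (x * y)
    det = W * sxx - sx * sx
    if det <= 0:
        raise ValueError("degenerate regressor: LD scores have no variance")
    slope = (W * sxy - sx * sy) / det
    intercept = (sy - slope * sx) / W
    return slope, intercept


def _ldsc_weights(
    l2: np.ndarray, x: np.ndarray, slope: float, intercept: float
) -> np.ndarray:
    """Overcounting (1/l) times heteroskedasticity (1/(2 mu^2)) weights."""
    mu = np.maximum(intercept + np.maximum(slope, 0.0) * x, 1e-3)
    return 1.0 / (np.maximum(l2, 1.0) * 2.0 * mu**2)


class GxESum(RegressorMixin, BaseEstimator):
    """Weighted LD score regression of interaction chi-squares.

    Parameters
    ----------
    kurtosis : fourth standardized moment of the environment used to split
        the intercept into its GxE and RxE parts; 3.0 for a normal E.
    weighting : "ldsc" (1/l overcounting times 1/(2 mu^2) heteroskedasticity
        weights, iterated twice) or "none" (unit weights, exact on noise-free
        algebra).
    n_blocks : jackknife block count; None picks 200, or m // 10 when m is
        below 2000.
    max_chisq : optional clamp discarding SNPs with chi-square above this
        value before fitting (off by default).
    approx_large_n : use N in the regressor rather than the exact N - 3
        small-sample form.
    min_snps : minimum SNP count for a fit (jackknife feasibility).

    Attributes (after fit)
    ----------------------
    h2_g1_, intercept_ : slope-derived GxE fraction and fitted intercept.
    h2_tau1_ : RxE fraction recovered from the intercept.
    se_h2_g1_, se_intercept_ : block-jackknife standard errors.
    p_value_ : two-sided Wald p-value for h2_g1 = 0.
    n_, m_ : sample size and SNP count used.
    """

    def __init__(
        self,
        kurtosis: float = 3.0,
        weighting: str = "ldsc",
        n_blocks: Optional[int] = None,
        max_chisq: Optional[float] = None,
        approx_large_n: bool = True,
        min_snps: int = 200,
    ):
        self.kurtosis = kurtosis
        self.weighting = weighting
        self.n_blocks = n_blocks
        self.max_chisq = max_chisq
        self.approx_large_n = approx_large_n
        self.min_snps = min_snps

    # ---- sklearn interface -------------------------------------------------

    def fit(
        self,
        X,
        y,
        sample_size: Optional[float] = None,
        n_snps: Optional[int] = None,
    ) -> "GxESum":
        """Fit the regression.

        Parameters
        ----------
        X : LD scores, shape (m,) or (m, 1).
        y : interaction chi-squares, shape (m,), in genomic SNP order
            (contiguity matters for the jackknife).
        sample_size : GWAS sample size N (median per-SNP N); required.
        n_snps : total SNP count M of the scan; defaults to len(y).
        """
        l2 = np.asarray(X, dtype=float).reshape(-1)
        chisq = np.asarray(y, dtype=float).reshape(-1)
        if l2.shape != chisq.shape:
            raise ValueError("LD scores and chi-squares differ in length")
        if sample_size is None:
            raise ValueError("sample_size (GWAS N) is required")
        if self.kurtosis <= 1:
            raise ValueError("kurtosis must exceed 1")
        if np.any(chisq < 0):
            raise ValueError("chi-squares must be non-negative")
        if self.max_chisq is not None:
            keep = chisq <= self.max_chisq
            l2, chisq = l2[keep], chisq[keep]
        m = len(chisq)
        if m < self.min_snps:
            raise ValueError(
                f"only {m} SNPs after filtering; need >= {self.min_snps} "
                "for a stable jackknife"
            )
        if self.weighting not in ("ldsc", "none"):
            raise ValueError(f"unknown weighting scheme {self.weighting!r}")

        N = float(sample_size)
        M = int(n_snps) if n_snps is not None else m
        scale = N / M if self.approx_large_n else (N - 3.0) / M
        self.scale_ = scale
        x = scale * l2

        if self.weighting == "none":
            w = np.ones(m)
        else:
            # two-step: crude moment-matched starting point, then weights
            # recomputed from the first-pass fit
            slope0 = max(float(chisq.mean() - 1.0) / max(float(x.mean()), 1e-12), 0.0)
            w = _ldsc_weights(l2, x, slope0, 1.0)
            s1, c1 = _wls(x, chisq, w)
            w = _ldsc_weights(l2, x, s1, c1)
        slope, intercept = _wls(x, chisq, w)

        n_blocks = self.n_blocks
        if n_blocks is None:
            n_blocks = 200 if m >= 2000 else max(2, m // 10)
        se_slope, se_intercept = _block_jackknife(x, chisq, w, n_blocks)

        self.h2_g1_ = slope
        self.intercept_ = intercept
        self.se_h2_g1_ = se_slope
        self.se_intercept_ = se_intercept
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # negative-RxE warning is re-raised
            self.h2_tau1_ = rxe_from_intercept(intercept, slope, self.kurtosis)
        if self.se_h2_g1_ > 0:
            self.p_value_ = wald_test(self.h2_g1_, self.se_h2_g1_)
        else:
            self.p_value_ = 1.0 if self.h2_g1_ == 0 else 0.0
        self.n_ = N
        self.m_ = m
        self.weights_ = w
        self.n_blocks_ = n_blocks
        return self

    def predict(self, X) -> np.ndarray:
        """Expected chi-square at the given LD scores under the fitted line."""
        l2 = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.h2_g1_ * self.scale_ * l2

    def to_estimate(self) -> GxEEstimate:
        return GxEEstimate(
            h2_g1=self.h2_g1_,
            se_h2_g1=self.se_h2_g1_,
            intercept=self.intercept_,
            se_intercept=self.se_intercept_,
            h2_tau1=self.h2_tau1_,
            kurtosis_used=self.kurtosis,
            p_wald=self.p_value_,
            n=self.n_,
            m=self.m_,
        )


def _block_jackknife(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, n_blocks: int
) -> tuple[float, float]:
    """Delete-one-block jackknife SEs of the WLS slope and intercept.

    Blocks are contiguous index ranges; weights are held fixed across
    deletions, so subtracting per-block cross-product sums from the totals
    reproduces each leave-one-out refit exactly.
    """
    m = len(x)
    if not 2 <= n_blocks <= m:
        raise ValueError("n_blocks must lie in [2, number of SNPs]")
    bounds = np.linspace(0, m, n_blocks + 1).astype(int)
    terms = np.column_stack([w, w * x, w * x * x, w * y, w * x * y])
    block_sums = np.add.reduceat(terms, bounds[:-1], axis=0)
    totals = terms.sum(axis=0)
    W, sx, sxx, sy, sxy = (totals - block_sums).T
    det = W * sxx - sx * sx
    if np.any(det <= 0):
        raise ValueError("degenerate leave-one-out regressor in jackknife")
    slopes = (W * sxy - sx * sy) / det
    intercepts = (sy - slopes * sx) / W
    B = n_blocks
    se_slope = np.sqrt((B - 1) / B * np.sum((slopes - slopes.mean()) ** 2))
    se_intercept = np.sqrt((B - 1) / B * np.sum((intercepts - intercepts.mean()) ** 2))
    return float(se_slope), float(se_intercept)


def _join(
    sumstats: Union[InteractionSummaryStats, pd.DataFrame],
    ldscores: Union[LDScoreTable, pd.DataFrame],
) -> pd.DataFrame:
    ss = sumstats.to_frame() if isinstance(sumstats, InteractionSummaryStats) else sumstats
    if isinstance(ldscores, LDScoreTable):
        ld = pd.DataFrame({"SNP": ldscores.snp_ids, "L2": ldscores.l2})
    else:
        ld = ldscores
    if "CHISQ" not in ss.columns:
        if "Z" not in ss.columns:
            raise ValueError("summary statistics need a CHISQ or Z column")
        ss = ss.assign(CHISQ=ss["Z"] ** 2)
    merged = ss.merge(ld[["SNP", "L2"]], on="SNP", how="inner")
    lost = len(ss) - len(merged)
    if lost:
        logger.warning("%d SNP(s) in sumstats had no LD score and were dropped", lost)
    return merged


def fit_gxesum(
    sumstats: Union[InteractionSummaryStats, pd.DataFrame],
    ldscores: Union[LDScoreTable, pd.DataFrame],
    kurtosis: float = 3.0,
    weighting: str = "ldsc",
    n_blocks: Optional[int] = None,
    max_chisq: Optional[float] = None,
    approx_large_n: bool = True,
    min_snps: int = 200,
) -> GxEEstimate:
    """Join sumstats with LD scores (on SNP id) and fit the regression."""
    merged = _join(sumstats, ldscores)
    model = GxESum(
        kurtosis=kurtosis,
        weighting=weighting,
        n_blocks=n_blocks,
        max_chisq=max_chisq,
        approx_large_n=approx_large_n,
        min_snps=min_snps,
    )
    n = float(np.median(merged["N"])) if "N" in merged.columns else None
    model.fit(merged["L2"].to_numpy(), merged["CHISQ"].to_numpy(), sample_size=n)
    est = model.to_estimate()
    if est.h2_tau1 < 0:
        logger.debug("negative RxE estimate %.4g (estimation noise)", est.h2_tau1)
    return est


def jackknife_se(
    sumstats: Union[InteractionSummaryStats, pd.DataFrame],
    ldscores: Union[LDScoreTable, pd.DataFrame],
    n_blocks: int,
    kurtosis: float = 3.0,
    weighting: str = "ldsc",
) -> tuple[float, float]:
    """Block-jackknife SEs of (h2_g1, intercept), usable at tiny SNP counts."""
    merged = _join(sumstats, ldscores)
    model = GxESum(
        kurtosis=kurtosis, weighting=weighting, n_blocks=n_blocks, min_snps=2
    )
    n = float(np.median(merged["N"])) if "N" in merged.columns else None
    model.fit(merged["L2"].to_numpy(), merged["CHISQ"].to_numpy(), sample_size=n)
    return model.se_h2_g1_, model.se_intercept_
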