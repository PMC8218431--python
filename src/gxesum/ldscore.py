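"""Per-SNP LD scores from a genotype reference panel.

The LD score of SNP j is ``l_j = 1 + sum_{k != j} r2_jk`` over neighbours
within a SNP-count window, with r2 the squared sample correlation of
standardized dosages. The bias-adjusted estimator subtracts the expected
upward sampling bias, ``r2 - (1 - r2) / (n_ref - 2)``, and is the default;
the raw estimator is exact for toy algebra (duplicated SNPs give integer
scores).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .simulate import GenotypeMatrix

__all__ = ["LDScoreTable", "estimate_ld_scores"]

_CHUNK = 512


@dataclass
class LDScoreTable:
    snp_ids: np.ndarray
    l2: np.ndarray
    n_ref: int
    window_spec: str

    @property
    def m(self) -> int:
        return len(self.l2)


def estimate_ld_scores(
    X_ref: GenotypeMatrix,
    window: Union[int, str] = "all",
    adjusted: bool = True,
) -> LDScoreTable:
    """Estimate l_j for every SNP of a reference panel.

    Parameters
    ----------
    X_ref : reference genotypes; monomorphic SNPs are an error.
    window : SNP-count window to each side, or "all" for all pairs. A window
        of at least m-1 is equivalent to all pairs.
    adjusted : apply the (1 - r2)/(n_ref - 2) sampling-bias correction.
    """
    n, m = X_ref.n, X_ref.m
    if n < 3:
        raise ValueError("need n_ref >= 3 individuals")
    if window == "all" or (isinstance(window, int) and window >= m - 1):
        w = m - 1
        spec = "all-pairs"
    else:
        w = int(window)
        if w < 0:
            raise ValueError("window must be non-negative or 'all'")
        spec = f"window={w} SNPs"
    Xs = X_ref.standardized  # raises with the SNP id on monomorphic input
    denom = n - 1  # columns are unit-sample-variance, so X'X/(n-1) is corr

    l2 = np.ones(m)
    for j0 in range(0, m, _CHUNK):
        j1 = min(j0 + _CHUNK, m)
        k0, k1 = max(0, j0 - w), min(m, j1 + w)
        r = (Xs[:, j0:j1].T @ Xs[:, k0:k1]) / denom
        r2 = r**2
        if adjusted:
            r2 = r2 - (1.0 - r2) / (n - 2)
        # mask self-pairs and anything outside each SNP's own window
        cols = np.arange(k0, k1)
        for jj in range(j0, j1):
            row = r2[jj - j0]
            keep = (np.abs(cols - jj) <= w) & (cols != jj)
            l2[jj] += row[keep].sum()
    return LDScoreTable(np.asarray(X_ref.snp_ids), l2, n, spec)
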