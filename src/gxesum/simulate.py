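"""Synthetic genotype/phenotype generator for the reaction-norm model.

Phenotypes follow ``y = b + g0 + g1*E + tau0 + tau1*E``: a polygenic main
genetic value ``g0``, per-SNP interaction effects whose aggregate ``g1`` is
modulated by a standardized environment ``E`` (GxE), an environment-stable
residual ``tau0`` and an environment-modulated residual ``tau1`` (RxE).
Genotypes carry block-exchangeable LD from a Gaussian copula so that LD
scores vary across SNPs without any external reference panel.

Confounding is available on purpose: the environment can be drawn with a
target correlation against the aggregate genetic value (G-E correlation)
and/or against the stable residual (R-E correlation), and continuous
phenotypes can be dichotomized under the liability threshold model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "EnvironmentVector",
    "SimulationConfig",
    "PhenotypeVector",
    "simulate_genotypes",
    "simulate_environment",
    "simulate_phenotype",
    "dichotomize",
    "simulate_dataset",
]

_MAX_RESAMPLE = 100


def _standardize(v: np.ndarray) -> np.ndarray:
    """Center and scale to unit sample variance (ddof=1)."""
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def sample_kurtosis(v: np.ndarray) -> float:
    """Fourth standardized sample moment (population formula, no correction)."""
    v = np.asarray(v, dtype=float)
    c = v - v.mean()
    m2 = np.mean(c**2)
    return float(np.mean(c**4) / m2**2)


@dataclass
class GenotypeMatrix:
    """n x m allele-count matrix with per-SNP metadata.

    ``dosages`` are 0/1/2 allele counts; ``standardized`` is the derived
    column-standardized real matrix used by every downstream stage. Missing
    entries (only possible when reading real files) are flagged in
    ``missing_mask`` and mean-imputed per SNP in the standardized view.
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    block_id: np.ndarray
    allele_freq: np.ndarray
    missing_mask: Optional[np.ndarray] = None
    _std: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.snp_ids = np.asarray(self.snp_ids)
        self.block_id = np.asarray(self.block_id)
        self.allele_freq = np.asarray(self.allele_freq, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional (n x m)")
        m = self.dosages.shape[1]
        if not (len(self.snp_ids) == len(self.block_id) == len(self.allele_freq) == m):
            raise ValueError("per-SNP metadata length mismatch")
        if np.any(np.diff(self.block_id) < 0):
            raise ValueError("block_id must be non-decreasing along the SNP axis")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @property
    def standardized(self) -> np.ndarray:
        if self._std is None:
            d = self.dosages.astype(float)
            if self.missing_mask is not None and self.missing_mask.any():
                d = d.copy()
                for j in np.flatnonzero(self.missing_mask.any(axis=0)):
                    col = d[:, j]
                    obs = ~self.missing_mask[:, j]
                    if not obs.any():
                        raise ValueError(f"SNP {self.snp_ids[j]} is entirely missing")
                    col[~obs] = col[obs].mean()
            mean = d.mean(axis=0)
            sd = d.std(axis=0, ddof=1)
            bad = np.flatnonzero(sd == 0)
            if bad.size:
                raise ValueError(
                    f"monomorphic SNP(s) cannot be standardized: {self.snp_ids[bad[:5]]}"
                )
            self._std = (d - mean) / sd
        return self._std


@dataclass
class EnvironmentVector:
    """Standardized environmental covariate with its sample kurtosis."""

    values: np.ndarray
    distribution_name: str
    kurtosis: float

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class SimulationConfig:
    """One complete phenotype-generating scenario.

    Variance fractions are on the standardized-phenotype scale: ``h2_g0``
    main genetic, ``h2_g1`` GxE, ``h2_tau1`` RxE; the stable residual tau0
    fills the remainder. ``rho_ge``/``rho_re`` are target correlations of E
    with the aggregate genetic value and the stable residual. ``prevalence``
    switches on liability-threshold dichotomization.
    """

    n: int = 2500
    m: int = 10000
    h2_g0: float = 0.3
    h2_g1: float = 0.0
    h2_tau1: float = 0.0
    rho_ge: float = 0.0
    rho_re: float = 0.0
    prevalence: Optional[float] = None
    env_distribution: str = "normal"
    seed: int = 0
    ld_block_size: int = 50
    within_block_r: float = 0.3
    maf_bounds: tuple[float, float] = (0.01, 0.5)
    label: str = ""

    def __post_init__(self) -> None:
        h2 = (self.h2_g0, self.h2_g1, self.h2_tau1)
        if any(h < 0 for h in h2) or sum(h2) > 1 + 1e-12:
            raise ValueError("variance fractions must be >= 0 and sum to <= 1")
        if abs(self.rho_ge) > 0.5 or abs(self.rho_re) > 0.5:
            raise ValueError("|rho_ge| and |rho_re| must be <= 0.5")
        if self.prevalence is not None and not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")


@dataclass
class PhenotypeVector:
    """Phenotype plus the retained generative components.

    ``components`` holds the four pre-standardization pieces (g0, gxe =
    g1*E, tau0, rxe = tau1*E) for diagnostics; for binary traits the
    continuous ``liability`` is kept alongside the 0/1 outcome.
    """

    y: np.ndarray
    components: dict[str, np.ndarray]
    liability: Optional[np.ndarray] = None
    prevalence_realized: Optional[float] = None

    @property
    def is_binary(self) -> bool:
        return self.liability is not None

    @property
    def n(self) -> int:
        return len(self.y)


def simulate_genotypes(
    n: int,
    m: int,
    ld_block_size: int = 50,
    within_block_r: float = 0.3,
    maf_bounds: tuple[float, float] = (0.01, 0.5),
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> GenotypeMatrix:
    """Draw 0/1/2 dosages with block-exchangeable LD.

    Each SNP j gets an allele frequency ``p_j ~ Uniform(maf_bounds)`` and
    per-individual dosages Binomial(2, p_j). Within a block the two allele
    draws of an individual share a latent Gaussian factor with pairwise
    correlation ``within_block_r`` (Gaussian copula thresholded at p_j), so
    realized LD decays to zero exactly at block boundaries. Deterministic
    given the seed; monomorphic columns are resampled a bounded number of
    times before failing.
    """
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 individuals and m >= 1 SNPs")
    if not 1 <= ld_block_size <= m:
        raise ValueError("require m >= ld_block_size >= 1")
    if not 0 <= within_block_r < 1:
        raise ValueError("within_block_r must lie in [0, 1)")
    lo, hi = maf_bounds
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_bounds must lie within (0, 0.5]")
    if rng is None:
        rng = np.random.default_rng(seed)

    p = rng.uniform(lo, hi, size=m)
    thresh = stats.norm.ppf(p)
    block_id = np.arange(m) // ld_block_size
    dosages = np.empty((n, m), dtype=np.int8)
    sr, sn = np.sqrt(within_block_r), np.sqrt(1.0 - within_block_r)

    for b in np.unique(block_id):
        cols = np.flatnonzero(block_id == b)
        block = np.zeros((n, cols.size), dtype=np.int8)
        factors = rng.standard_normal((n, 2))  # one shared factor per allele copy
        for c in range(2):
            z = sr * factors[:, [c]] + sn * rng.standard_normal((n, cols.size))
            block += (z < thresh[cols]).astype(np.int8)
        # resample monomorphic columns against the same shared factors,
        # preserving the block's LD structure
        for _ in range(_MAX_RESAMPLE):
            mono = np.flatnonzero(block.min(axis=0) == block.max(axis=0))
            if mono.size == 0:
                break
            for jj in mono:
                p[cols[jj]] = rng.uniform(lo, hi)
                thresh[cols[jj]] = stats.norm.ppf(p[cols[jj]])
                col = np.zeros(n, dtype=np.int8)
                for c in range(2):
                    z = sr * factors[:, c] + sn * rng.standard_normal(n)
                    col += (z < thresh[cols[jj]]).astype(np.int8)
                block[:, jj] = col
        else:
            raise RuntimeError("could not obtain polymorphic SNPs after resampling")
        dosages[:, cols] = block

    snp_ids = np.array([f"snp{j + 1}" for j in range(m)])
    return GenotypeMatrix(dosages, snp_ids, block_id, p)


def _base_noise(n: int, distribution: str, rng: np.random.Generator) -> np.ndarray:
    if distribution == "normal":
        e = rng.standard_normal(n)
    elif distribution == "t":
        # df=8 gives excess kurtosis 1.5 (kurtosis 4.5): visibly heavy-tailed
        # while all needed moments exist
        e = rng.standard_t(df=8, size=n)
    elif distribution == "uniform":
        e = rng.uniform(-1.0, 1.0, size=n)
    elif distribution == "binary":
        e = rng.integers(0, 2, size=n).astype(float)
    else:
        raise ValueError(f"unknown environment distribution: {distribution!r}")
    return _standardize(e)


def simulate_environment(
    n: int,
    distribution: str = "normal",
    rho_ge: float = 0.0,
    rho_re: float = 0.0,
    g0: Optional[np.ndarray] = None,
    tau0: Optional[np.ndarray] = None,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> EnvironmentVector:
    """Draw a standardized environment, optionally confounded.

    ``E = rho_ge * g0_std + rho_re * tau0_std + c * noise`` with the noise of
    the named distribution and ``c`` chosen so Var(E) = 1; E is then
    re-standardized. The realized corr(E, g0) tracks ``rho_ge`` up to
    sampling error (and likewise for tau0).
    """
    if rho_ge**2 + rho_re**2 >= 1:
        raise ValueError("rho_ge^2 + rho_re^2 must be < 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    noise = _base_noise(n, distribution, rng)
    e = np.sqrt(1.0 - rho_ge**2 - rho_re**2) * noise
    if rho_ge != 0.0:
        if g0 is None:
            raise ValueError("rho_ge != 0 requires g0")
        e = e + rho_ge * _standardize(g0)
    if rho_re != 0.0:
        if tau0 is None:
            raise ValueError("rho_re != 0 requires tau0")
        e = e + rho_re * _standardize(tau0)
    e = _standardize(e)
    return EnvironmentVector(e, distribution, sample_kurtosis(e))


def _draw_effects(
    config: SimulationConfig, X: GenotypeMatrix, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw the four generative pieces that do not yet involve E."""
    n, m = X.n, X.m
    Xs = X.standardized
    beta0 = rng.normal(0.0, np.sqrt(config.h2_g0 / m), size=m)
    beta1 = rng.normal(0.0, np.sqrt(config.h2_g1 / m), size=m)
    h2_tau0 = 1.0 - config.h2_g0 - config.h2_g1 - config.h2_tau1
    return {
        "g0": Xs @ beta0,
        "g1": Xs @ beta1,
        "tau0": rng.normal(0.0, np.sqrt(h2_tau0), size=n),
        "tau1": rng.normal(0.0, np.sqrt(config.h2_tau1), size=n),
    }


def _assemble_phenotype(
    effects: dict[str, np.ndarray], E: EnvironmentVector
) -> PhenotypeVector:
    e = E.values
    components = {
        "g0": effects["g0"],
        "gxe": effects["g1"] * e,
        "tau0": effects["tau0"],
        "rxe": effects["tau1"] * e,
    }
    raw = components["g0"] + components["gxe"] + components["tau0"] + components["rxe"]
    return PhenotypeVector(_standardize(raw), components)


def simulate_phenotype(
    config: SimulationConfig,
    X: GenotypeMatrix,
    E: EnvironmentVector,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> PhenotypeVector:
    """Generate a standardized continuous phenotype under the config.

    Per-SNP effects are i.i.d. normal with total variances h2_g0 (main) and
    h2_g1 (interaction); the per-individual RxE deviation tau1 has variance
    h2_tau1 and the stable residual tau0 fills the remaining budget. The
    final y is standardized to mean 0, variance 1 with all four components
    retained (their sum equals the pre-standardization phenotype).
    """
    if E.n != X.n:
        raise ValueError("genotype and environment sample sizes differ")
    if np.var(E.values) == 0:
        raise ValueError("environment has zero variance")
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    return _assemble_phenotype(_draw_effects(config, X, rng), E)


def dichotomize(liability: PhenotypeVector, prevalence: float) -> PhenotypeVector:
    """Threshold a standardized liability into 0/1 disease status.

    Case status is ``liability > Phi^-1(1 - prevalence)``; the continuous
    liability is retained and the realized case fraction recorded.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    if liability.is_binary:
        raise ValueError("phenotype is already binary")
    t = stats.norm.ppf(1.0 - prevalence)
    y = (liability.y > t).astype(float)
    realized = float(y.mean())
    if realized in (0.0, 1.0):
        warnings.warn(
            f"degenerate dichotomization: realized case fraction {realized}",
            stacklevel=2,
        )
    return PhenotypeVector(
        y, liability.components, liability=liability.y, prevalence_realized=realized
    )


def simulate_dataset(
    config: SimulationConfig,
    X: Optional[GenotypeMatrix] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[GenotypeMatrix, EnvironmentVector, PhenotypeVector]:
    """Full generative chain for one scenario replicate.

    Draws (or reuses) genotypes, draws the genetic/residual effects, builds
    the environment with the requested G-E and R-E correlations against the
    realized aggregate values, assembles the phenotype and, when the config
    has a prevalence, dichotomizes the liability.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if X is None:
        X = simulate_genotypes(
            config.n,
            config.m,
            config.ld_block_size,
            config.within_block_r,
            config.maf_bounds,
            rng=rng,
        )
    effects = _draw_effects(config, X, rng)
    E = simulate_environment(
        X.n,
        config.env_distribution,
        config.rho_ge,
        config.rho_re,
        g0=effects["g0"] if config.rho_ge else None,
        tau0=effects["tau0"] if config.rho_re else None,
        rng=rng,
    )
    pheno = _assemble_phenotype(effects, E)
    if config.prevalence is not None:
        pheno = dichotomize(pheno, config.prevalence)
    return X, E, pheno
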