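"""End-to-end harness: simulate -> pre-adjust -> scan -> fit.

This is the reproducibility layer behind the calibration experiments: it
chains the generator, the interaction GWAS and the LD score regression for
many replicates of a null (or non-null) scenario; each scenario's
replicates share one genotype panel and one LD-score table.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ldscore import LDScoreTable, estimate_ld_scores
from .regression import GxEEstimate, fit_gxesum, observed_to_liability
from .scan import CovariateMatrix, interaction_scan, preadjust_phenotype
from .simulate import (
    GenotypeMatrix,
    SimulationConfig,
    _draw_effects,
    _assemble_phenotype,
    dichotomize,
    simulate_environment,
    simulate_genotypes,
)

__all__ = [
    "continuous_null_scenarios",
    "binary_null_scenarios",
    "run_replicate",
    "run_type1_suite",
    "binomial_band",
]


def continuous_null_scenarios(
    n: int = 2500, m: int = 10000, **overrides
) -> list[SimulationConfig]:
    """The eight continuous-trait null scenarios: no GxE; RxE variance 0 or
    0.1 crossed with G-E and R-E correlations 0 or 0.1."""
    out = []
    for h2_tau1 in (0.0, 0.1):
        for rho_ge in (0.0, 0.1):
            for rho_re in (0.0, 0.1):
                label = (
                    f"var(RxE)={h2_tau1}, G-E corr={rho_ge}, R-E corr={rho_re}"
                )
                out.append(
                    SimulationConfig(
                        n=n,
                        m=m,
                        h2_g1=0.0,
                        h2_tau1=h2_tau1,
                        rho_ge=rho_ge,
                        rho_re=rho_re,
                        label=label,
                        **overrides,
                    )
                )
    return out


def binary_null_scenarios(
    n: int = 2500, m: int = 10000, **overrides
) -> list[SimulationConfig]:
    """The eight binary null scenarios: liability-scale RxE variance 0 or 0.1
    crossed with prevalence 0.025, 0.05, 0.1, 0.5."""
    out = []
    for h2_tau1 in (0.0, 0.1):
        for k in (0.025, 0.05, 0.1, 0.5):
            label = f"var(RxE)={h2_tau1} (liability), k={k}"
            out.append(
                SimulationConfig(
                    n=n,
                    m=m,
                    h2_g1=0.0,
                    h2_tau1=h2_tau1,
                    prevalence=k,
                    label=label,
                    **overrides,
                )
            )
    return out


def run_replicate(
    config: SimulationConfig,
    X: GenotypeMatrix,
    ldscores: LDScoreTable,
    rng: np.random.Generator,
    impute_missing: bool = False,
    liability_scale: bool = True,
    _scratch: Optional[dict] = None,
) -> GxEEstimate:
    """One full pipeline pass on a shared genotype panel.

    Draws fresh effects/environment/phenotype under ``config``, pre-adjusts
    the outcome for the main effect of E, runs the interaction scan, fits
    the LD score regression with the environment's realized kurtosis, and
    (for binary traits, when requested) transforms the estimate to the
    liability scale.
    """
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
    y_adj = preadjust_phenotype(
        pheno, CovariateMatrix.from_environment(E), impute_missing=impute_missing
    )
    sq = _scratch.get("X_sq") if _scratch is not None else None
    ss = interaction_scan(y_adj, X, E, _precomputed_sq=sq)
    est = fit_gxesum(ss, ldscores, kurtosis=E.kurtosis)
    if config.prevalence is not None and liability_scale:
        est = observed_to_liability(est, config.prevalence)
    return est


def binomial_band(alpha: float, replicates: int, level: float = 0.95) -> tuple[float, float]:
    """Two-sided normal-approximation band for an empirical rejection rate.

    At alpha=0.05 and 500 replicates this is 0.05 +/- 1.96*sqrt(0.05*0.95/500),
    i.e. the familiar printed 0.03/0.07 rule.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(alpha * (1.0 - alpha) / replicates)
    return alpha - half, alpha + half


def run_type1_suite(
    scenarios: Sequence[SimulationConfig],
    replicates: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    X: Optional[GenotypeMatrix] = None,
    ldscores: Optional[LDScoreTable] = None,
    ld_window: Optional[int] = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Empirical type-I-error rates over null scenarios.

    Every scenario must have ``h2_g1 = 0``. By default an independent
    genotype panel (and its LD-score table) is simulated per scenario and
    shared by that scenario's replicates; each replicate redraws effects,
    environment and phenotype. Pooling over scenarios then averages
    panel-level noise, so the binomial band is a fair yardstick for the
    pooled rate. Passing an explicit ``X``/``ldscores`` pins one panel for
    every scenario instead. Returns one row per scenario plus a pooled
    ``average`` row, each with the rejection rate at ``alpha`` and the
    binomial 95% band for the replicate count used.
    """
    bad = [c.label or i for i, c in enumerate(scenarios) if c.h2_g1 != 0]
    if bad:
        raise ValueError(f"non-null scenario(s) passed to the type I suite: {bad}")
    if not scenarios:
        raise ValueError("no scenarios given")
    rng = np.random.default_rng(seed)
    if X is None and ldscores is not None:
        raise ValueError("ldscores without the matching genotype panel")
    shared = (X, ldscores) if X is not None else None

    rows = []
    lo, hi = binomial_band(alpha, replicates)
    for config in scenarios:
        if shared is None:
            X = simulate_genotypes(
                config.n,
                config.m,
                config.ld_block_size,
                config.within_block_r,
                config.maf_bounds,
                rng=rng,
            )
            ldscores = None
        if ldscores is None:
            w = ld_window if ld_window is not None else 3 * config.ld_block_size
            ldscores = estimate_ld_scores(X, window=w, adjusted=True)
        scratch = {"X_sq": X.standardized**2}
        rejections = 0
        for r in range(replicates):
            est = run_replicate(config, X, ldscores, rng, _scratch=scratch)
            rejections += est.p_wald < alpha
            if progress and (r + 1) % 25 == 0:
                print(f"  {config.label}: {r + 1}/{replicates}", flush=True)
        rows.append(
            {
                "scenario": config.label,
                "replicates": replicates,
                "rejection_rate": rejections / replicates,
                "band_low": lo,
                "band_high": hi,
            }
        )
    pooled = float(np.mean([r["rejection_rate"] for r in rows]))
    total = replicates * len(scenarios)
    plo, phi = binomial_band(alpha, total)
    rows.append(
        {
            "scenario": "average",
            "replicates": total,
            "rejection_rate": pooled,
            "band_low": plo,
            "band_high": phi,
        }
    )
    return pd.DataFrame(rows)
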