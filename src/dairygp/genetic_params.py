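"""Posterior genetic parameters from retained marker-effect draws.

For every retained iteration k the genetic covariance between traits is
accumulated from the sampled marker effects,

    sigma_g^(k) = sum_i var(SNP_i) a_i^(k) a_i^(k)',

with var(SNP_i) the empirical dosage variance of marker i; the posterior
mean over retained iterations is the point estimate.  Heritabilities divide
the per-draw genetic variance by genetic + days-in-milk + residual variance
(the DIM term is a model term, so it belongs in the phenotypic total; a flag
drops it), and their standard errors are posterior standard deviations
across the retained draws.  Genetic correlations normalize each draw's
covariance by the square root of the product of the trait variances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import PhenotypeTable, TRAITS
from .draws import PosteriorDraws


@dataclass
class GeneticParams:
    trait_names: tuple
    h2: np.ndarray
    h2_se: np.ndarray
    genetic_corr: np.ndarray
    phenotypic_corr: np.ndarray
    sigma_g_mean: np.ndarray

    def __post_init__(self) -> None:
        if ((self.h2 < 0) | (self.h2 > 1)).any():
            raise ValueError("heritabilities must lie in [0, 1]")
        for C in (self.genetic_corr, self.phenotypic_corr):
            if not np.allclose(C, C.T, atol=1e-8, equal_nan=True):
                raise ValueError("correlation matrix must be symmetric")

    def to_table_csv(self, path) -> None:
        """Genetic correlations below the diagonal, phenotypic above,
        'h2 +/- SE' on the diagonal."""
        t = len(self.trait_names)
        cells = np.empty((t, t), dtype=object)
        for i in range(t):
            for j in range(t):
                if i == j:
                    cells[i, j] = f"{self.h2[i]:.4f} +/- {self.h2_se[i]:.4f}"
                elif i > j:
                    cells[i, j] = f"{self.genetic_corr[i, j]:.3f}"
                else:
                    cells[i, j] = f"{self.phenotypic_corr[i, j]:.3f}"
        pd.DataFrame(cells, index=self.trait_names, columns=self.trait_names).to_csv(
            path, index_label="trait"
        )

    def to_long_csv(self, path) -> None:
        rows = []
        for i, ti in enumerate(self.trait_names):
            rows.append({"trait_1": ti, "trait_2": ti, "quantity": "h2",
                         "value": self.h2[i], "se": self.h2_se[i]})
            for j, tj in enumerate(self.trait_names):
                if j >= i:
                    continue
                rows.append({"trait_1": ti, "trait_2": tj,
                             "quantity": "genetic_corr",
                             "value": self.genetic_corr[i, j], "se": np.nan})
                rows.append({"trait_1": ti, "trait_2": tj,
                             "quantity": "phenotypic_corr",
                             "value": self.phenotypic_corr[i, j], "se": np.nan})
        pd.DataFrame(rows).to_csv(path, index=False)


def genetic_covariance_draw(alpha_k: np.ndarray, snp_vars: np.ndarray) -> np.ndarray:
    """sum_i var(SNP_i) a_i a_i' for one iteration's (markers x traits) effects."""
    alpha_k = np.asarray(alpha_k, dtype=float)
    v = np.asarray(snp_vars, dtype=float)
    if alpha_k.shape[0] != v.shape[0]:
        raise ValueError("marker count mismatch between effects and snp_vars")
    if (v < 0).any():
        raise ValueError("snp_vars must be non-negative")
    return (alpha_k * v[:, None]).T @ alpha_k


def genetic_covariance(draws: PosteriorDraws, snp_vars: np.ndarray):
    """Posterior-mean genetic covariance and the per-draw series (k, t, t)."""
    if draws.n_draws == 0:
        raise ValueError("no retained draws")
    k, p, t = draws.alpha.shape
    series = np.empty((k, t, t))
    v = np.asarray(snp_vars, dtype=float)
    for i in range(k):
        series[i] = genetic_covariance_draw(draws.alpha[i], v)
    return series.mean(axis=0), series


def genetic_correlation(sigma_g_series: np.ndarray):
    """Per-draw normalized correlations and their posterior mean.

    Draws with a non-positive diagonal variance are skipped and counted.
    """
    series = np.asarray(sigma_g_series, dtype=float)
    k, t, _ = series.shape
    corrs = []
    n_skipped = 0
    for i in range(k):
        dg = np.diag(series[i])
        if (dg <= 0).any():
            n_skipped += 1
            continue
        denom = np.sqrt(np.outer(dg, dg))
        C = series[i] / denom
        np.fill_diagonal(C, 1.0)
        corrs.append(np.clip(C, -1.0, 1.0))
    if not corrs:
        raise ValueError("every draw had a zero genetic variance")
    corr_series = np.stack(corrs)
    return corr_series.mean(axis=0), corr_series, n_skipped


def heritability(
    draws: PosteriorDraws,
    sigma_g_series: np.ndarray,
    include_dim: bool = True,
):
    """Per-trait posterior mean h2 and its SE (posterior SD across draws)."""
    series = np.asarray(sigma_g_series, dtype=float)
    k, t, _ = series.shape
    gvar = series[:, np.arange(t), np.arange(t)]
    rvar = draws.R[:, np.arange(t), np.arange(t)]
    dvar = draws.sigma2_d if include_dim else np.zeros_like(draws.sigma2_d)
    h2_draws = gvar / (gvar + dvar + rvar)
    return h2_draws.mean(axis=0), h2_draws.std(axis=0), h2_draws


def phenotypic_correlation(pheno: PhenotypeTable, traits=TRAITS):
    """Pairwise-complete Pearson correlations of the raw trait values.

    Returns (corr matrix, p-value matrix); pairs with fewer than 3 complete
    observations are NaN.
    """
    t = len(traits)
    corr = np.full((t, t), np.nan)
    pval = np.full((t, t), np.nan)
    values = {tr: pheno.trait_values(tr) for tr in traits}
    for i in range(t):
        corr[i, i] = 1.0
        pval[i, i] = 0.0
        for j in range(i):
            x, y = values[traits[i]], values[traits[j]]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            corr[i, j] = corr[j, i] = r
            pval[i, j] = pval[j, i] = p
    return corr, pval


def summarize(
    draws: PosteriorDraws,
    snp_vars: np.ndarray,
    pheno: Optional[PhenotypeTable] = None,
    include_dim: bool = True,
) -> GeneticParams:
    """One-stop posterior summary: h2 +/- SE, genetic and phenotypic correlations."""
    sigma_g_mean, series = genetic_covariance(draws, snp_vars)
    gcorr, _, _ = genetic_correlation(series)
    h2, h2_se, _ = heritability(draws, series, include_dim=include_dim)
    if pheno is not None:
        pcorr, _ = phenotypic_correlation(pheno, traits=draws.trait_names)
    else:
        pcorr = np.full_like(gcorr, np.nan)
        np.fill_diagonal(pcorr, 1.0)
    return GeneticParams(
        trait_names=tuple(draws.trait_names),
        h2=h2,
        h2_se=h2_se,
        genetic_corr=gcorr,
        phenotypic_corr=pcorr,
        sigma_g_mean=sigma_g_mean,
    )
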