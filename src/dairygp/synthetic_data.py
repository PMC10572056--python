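"""Synthetic dairy-population generator with known truth.

Emulates a genotyped Holstein cow population recorded for five milk traits:
305-day milk yield (MY, kg) and fat / protein / lactose / dry-matter
percentages (MF, MP, ML, MDM).  Markers are independent biallelic loci with
uniformly drawn allele frequencies and binomial Hardy-Weinberg dosages; each
marker carries a t-variate additive effect drawn so the aggregate genetic
covariance matches the target heritabilities and genetic correlations on the
phenotypic scale.  Phenotypes add lactation-order and farm fixed effects, a
days-in-milk class effect and a multivariate normal residual.  Every dataset
ships with a :class:`TruthRecord` holding the simulated effects, genetic
values and realized parameters, which is what parameter-recovery tests
compare against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .data_io import GenotypeMatrix, PhenotypeTable, TRAITS

#: Genetic correlations of the default five-trait dairy regime
#: (order MY, MF, MP, ML, MDM): weakly negative between yield and the
#: component percentages, moderately positive between fat and dry matter.
DEFAULT_GENETIC_CORR = np.array(
    [
        [1.000, -0.104, -0.092, 0.001, -0.080],
        [-0.104, 1.000, 0.132, 0.017, 0.499],
        [-0.092, 0.132, 1.000, 0.021, 0.218],
        [0.001, 0.017, 0.021, 1.000, 0.041],
        [-0.080, 0.499, 0.218, 0.041, 1.000],
    ]
)


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults emulate a ~500-cow, 12-farm Holstein population with five milk
    traits of heritability 0.22-0.30; ``n_markers`` defaults to a desk-scale
    2,000-marker panel (use ~13,000 for a full-size chip emulation).
    """

    n_animals: int = 497
    n_markers: int = 2000
    maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.01
    traits: tuple = TRAITS
    h2_true: tuple = (0.24, 0.22, 0.30, 0.22, 0.24)
    genetic_corr_true: np.ndarray = field(
        default_factory=lambda: DEFAULT_GENETIC_CORR.copy()
    )
    trait_means: tuple = (6500.0, 4.1, 3.3, 4.8, 12.9)
    trait_sds: tuple = (1100.0, 0.45, 0.25, 0.20, 0.70)
    n_farms: int = 12
    n_lactation: int = 3
    farm_sd_frac: float = 0.15
    lactation_sd_frac: float = 0.10
    dim_variance_frac: float = 0.05
    dim_range: tuple = (5, 305)
    dim_bin_days: int = 30
    residual_corr: Optional[np.ndarray] = None
    ld_block_size: int = 1  # >1 turns on copula-correlated adjacent markers
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = len(self.traits)
        C = np.asarray(self.genetic_corr_true, dtype=float)
        if C.shape != (t, t) or not np.allclose(C, C.T):
            raise ValueError("genetic_corr_true must be a symmetric t x t matrix")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("genetic_corr_true must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("genetic_corr_true must be positive semidefinite")
        for h2 in self.h2_true:
            if not 0 <= h2 < 1:
                raise ValueError("h2_true entries must lie in [0, 1)")
            if h2 + self.dim_variance_frac >= 1:
                raise ValueError("h2 + dim_variance_frac must be < 1 per trait")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def n_traits(self) -> int:
        return len(self.traits)


@dataclass
class TruthRecord:
    """Simulated ground truth stored alongside every dataset."""

    effects: np.ndarray  # markers x traits
    genetic_values: np.ndarray  # animals x traits
    realized_h2: np.ndarray
    realized_genetic_corr: np.ndarray
    farm_effects: np.ndarray  # farms x traits
    lactation_effects: np.ndarray  # lactation levels x traits
    dim_effects: np.ndarray  # DIM classes x traits
    farm_assignment: np.ndarray
    lactation_assignment: np.ndarray
    dim_values: np.ndarray

    def to_json(self, path=None) -> str:
        payload = {
            k: np.asarray(getattr(self, k)).tolist()
            for k in (
                "effects",
                "genetic_values",
                "realized_h2",
                "realized_genetic_corr",
                "farm_effects",
                "lactation_effects",
                "dim_effects",
                "farm_assignment",
                "lactation_assignment",
                "dim_values",
            )
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _rng(config: SimConfig, rng=None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


def simulate_genotypes(config: SimConfig, rng=None) -> GenotypeMatrix:
    """Independent biallelic loci: p ~ U(maf_range), dosage ~ Binomial(2, p)."""
    rng = _rng(config, rng)
    n, p = config.n_animals, config.n_markers
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)
    if config.ld_block_size > 1 and config.ld_rho > 0:
        dosages = _ld_block_dosages(rng, n, p, freqs, config)
    else:
        dosages = rng.binomial(2, freqs[None, :], size=(n, p)).astype(float)
    if config.missing_rate > 0:
        mask = rng.random((n, p)) < config.missing_rate
        dosages[mask] = np.nan
    animal_ids = np.array([f"cow{i:04d}" for i in range(n)], dtype=object)
    marker_ids = np.array([f"snp{j:05d}" for j in range(p)], dtype=object)
    return GenotypeMatrix(animal_ids, marker_ids, dosages)


def _ld_block_dosages(rng, n, p, freqs, config):
    """Gaussian-copula blocks: adjacent markers within a block share latent
    correlation ld_rho; two latent allele draws per animal give the dosage."""
    b = config.ld_block_size
    dosages = np.empty((n, p))
    for start in range(0, p, b):
        stop = min(start + b, p)
        w = stop - start
        C = np.full((w, w), config.ld_rho) + (1 - config.ld_rho) * np.eye(w)
        L = np.linalg.cholesky(C)
        dose = np.zeros((n, w))
        for _ in range(2):
            z = rng.standard_normal((n, w)) @ L.T
            u = ndtr(z)  # standard normal CDF
            dose += (u < freqs[start:stop][None, :]).astype(float)
        dosages[:, start:stop] = dose
    return dosages


def simulate_effects(config: SimConfig, geno: GenotypeMatrix, rng=None) -> np.ndarray:
    """Per-marker t-variate effects scaled to the target genetic covariance.

    With independent loci the aggregate genetic covariance
    sum_i var(SNP_i) a_i a_i' has expectation V * Sigma_alpha where
    V = sum_i var(SNP_i), so Sigma_alpha = Sigma_g_target / V hits the
    target heritabilities and genetic correlations in expectation.
    """
    rng = _rng(config, rng)
    sds = np.asarray(config.trait_sds, dtype=float)
    h2 = np.asarray(config.h2_true, dtype=float)
    gvar = h2 * sds**2
    scale = np.sqrt(np.outer(gvar, gvar))
    sigma_g_target = np.asarray(config.genetic_corr_true) * scale
    sigma_g_target[gvar == 0, :] = 0.0
    sigma_g_target[:, gvar == 0] = 0.0

    v = np.nanvar(geno.dosages, axis=0)
    V = float(v.sum())
    if V <= 0:
        raise ValueError("degenerate genotypes: zero total marker variance")
    sigma_alpha = sigma_g_target / V

    evals, evecs = np.linalg.eigh(sigma_alpha)
    if evals.min() < -1e-12 * max(evals.max(), 1.0):
        raise ValueError("target effect covariance is not positive semidefinite")
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    z = rng.standard_normal((config.n_markers, config.n_traits))
    return z @ root.T


def simulate_phenotypes(
    config: SimConfig, geno: GenotypeMatrix, effects: np.ndarray, rng=None
):
    """Phenotypes = mean + lactation + farm + DIM class + M @ effects + residual."""
    rng = _rng(config, rng)
    n, t = config.n_animals, config.n_traits
    sds = np.asarray(config.trait_sds, dtype=float)
    h2 = np.asarray(config.h2_true, dtype=float)

    # centered marker matrix on mean-imputed dosages
    X = np.asarray(geno.dosages, dtype=float)
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean[None, :], X)
    M = X - X.mean(axis=0)
    g = M @ effects

    farm = rng.integers(1, config.n_farms + 1, size=n)
    lact = rng.integers(1, config.n_lactation + 1, size=n)
    dim = rng.integers(config.dim_range[0], config.dim_range[1] + 1, size=n).astype(float)
    dim_class = (dim // config.dim_bin_days).astype(int)
    n_dim_classes = dim_class.max() + 1

    farm_eff = rng.standard_normal((config.n_farms, t)) * (config.farm_sd_frac * sds)
    lact_eff = rng.standard_normal((config.n_lactation, t)) * (
        config.lactation_sd_frac * sds
    )
    dim_eff = rng.standard_normal((n_dim_classes, t)) * np.sqrt(
        config.dim_variance_frac
    ) * sds

    res_var = (1.0 - h2 - config.dim_variance_frac) * sds**2
    Rcorr = (
        np.eye(t)
        if config.residual_corr is None
        else np.asarray(config.residual_corr, dtype=float)
    )
    Rcov = Rcorr * np.sqrt(np.outer(res_var, res_var))
    Lr = np.linalg.cholesky(Rcov + 1e-12 * np.eye(t))
    resid = rng.standard_normal((n, t)) @ Lr.T

    y = (
        np.asarray(config.trait_means)[None, :]
        + lact_eff[lact - 1]
        + farm_eff[farm - 1]
        + dim_eff[dim_class]
        + g
        + resid
    )

    dvar = dim_eff[dim_class].var(axis=0)
    gvar = g.var(axis=0)
    realized_h2 = gvar / (gvar + dvar + resid.var(axis=0))
    v = np.nanvar(geno.dosages, axis=0)
    sigma_g_real = (effects * v[:, None]).T @ effects
    dg = np.sqrt(np.diag(sigma_g_real))
    with np.errstate(invalid="ignore", divide="ignore"):
        realized_corr = sigma_g_real / np.outer(dg, dg)
    np.fill_diagonal(realized_corr, 1.0)

    df = pd.DataFrame(
        {"animal_id": [str(a) for a in geno.animal_ids]}
        | {trait: y[:, k] for k, trait in enumerate(config.traits)}
        | {
            "lactation_order": lact,
            "farm": farm,
            "dim": dim,
        }
    )
    pheno = PhenotypeTable(df)
    truth = TruthRecord(
        effects=effects,
        genetic_values=g,
        realized_h2=realized_h2,
        realized_genetic_corr=realized_corr,
        farm_effects=farm_eff,
        lactation_effects=lact_eff,
        dim_effects=dim_eff,
        farm_assignment=farm,
        lactation_assignment=lact,
        dim_values=dim,
    )
    return pheno, truth


def simulate_dataset(config: SimConfig):
    """Genotypes, phenotypes and truth from a single seed stream."""
    rng = np.random.default_rng(config.seed)
    geno = simulate_genotypes(config, rng)
    effects = simulate_effects(config, geno, rng)
    pheno, truth = simulate_phenotypes(config, geno, effects, rng)
    return geno, pheno, truth
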