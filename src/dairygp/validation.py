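"""Hold-out validation: accuracy, dispersion bias and marker-effect rank correlations.

The protocol mirrors routine genomic-evaluation practice: a single random
train/test split of the post-QC animals, single-trait and multi-trait fits
on the training set, GEBVs for the held-out animals, then per trait and
method the Pearson accuracy r between observed phenotype and GEBV and the
dispersion bias b (slope of phenotype regressed on GEBV; b > 1 means GEBV
dispersion is understated).  Spearman rank correlations between per-marker
effect magnitudes (squared posterior means by default) quantify how much the
influential markers overlap between traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GenotypeMatrix, PhenotypeTable, TRAITS, align
from .draws import ChainConfig
from .genetic_params import GeneticParams, summarize
from .grm import center_markers, marker_variances
from .qc import run_qc
from .sampler_mt import build_mt_model_frame, fit_mt, gebv_mt
from .sampler_st import build_model_frame, fit_st, gebv

logger = logging.getLogger(__name__)


@dataclass
class ValidationResult:
    trait_names: tuple
    accuracy_mt: np.ndarray
    bias_mt: np.ndarray
    accuracy_st: np.ndarray
    bias_st: np.ndarray
    train_ids: np.ndarray
    test_ids: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")
        finite = self.accuracy_mt[np.isfinite(self.accuracy_mt)]
        if (np.abs(finite) > 1 + 1e-12).any():
            raise ValueError("|accuracy| must be <= 1")

    @property
    def accuracy_diff(self) -> np.ndarray:
        """MT minus ST accuracy, per trait."""
        return self.accuracy_mt - self.accuracy_st

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": list(self.trait_names),
                "MT_r": self.accuracy_mt,
                "MT_b": self.bias_mt,
                "ST_r": self.accuracy_st,
                "ST_b": self.bias_st,
                "accuracy_diff_MT_minus_ST": self.accuracy_diff,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class RankCorrMatrix:
    trait_names: tuple
    rho: np.ndarray
    pvalues: np.ndarray
    magnitude: str = "squared"

    def __post_init__(self) -> None:
        if not np.allclose(self.rho, self.rho.T, atol=1e-10):
            raise ValueError("rank-correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.rho), 1.0):
            raise ValueError("rank-correlation diagonal must be 1")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.rho, index=self.trait_names, columns=self.trait_names
        ).to_csv(path, index_label="trait")


def split_train_test(animal_ids, n_train: int, seed: int):
    """Uniform random split without replacement into (n_train, n - n_train)."""
    ids = np.asarray(animal_ids, dtype=object)
    n = len(ids)
    if n_train >= n:
        raise ValueError(f"n_train={n_train} must be smaller than n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return ids[np.sort(perm[:n_train])], ids[np.sort(perm[n_train:])]


def accuracy(y_obs_test: np.ndarray, gebv_test: np.ndarray) -> float:
    """Pearson correlation of observed phenotype and GEBV over the test set."""
    y = np.asarray(y_obs_test, dtype=float)
    g = np.asarray(gebv_test, dtype=float)
    ok = np.isfinite(y) & np.isfinite(g)
    if ok.sum() < 3:
        raise ValueError("accuracy needs at least 3 test animals with data")
    y, g = y[ok], g[ok]
    if np.var(y) == 0 or np.var(g) == 0:
        logger.warning("accuracy undefined: zero variance in a vector")
        return float("nan")
    return float(stats.pearsonr(y, g)[0])


def bias(y_obs_test: np.ndarray, gebv_test: np.ndarray) -> float:
    """OLS slope of observed phenotype on GEBV; b > 1 flags underdispersion."""
    y = np.asarray(y_obs_test, dtype=float)
    g = np.asarray(gebv_test, dtype=float)
    ok = np.isfinite(y) & np.isfinite(g)
    if ok.sum() < 3:
        raise ValueError("bias needs at least 3 test animals with data")
    y, g = y[ok], g[ok]
    vg = np.var(g)
    if vg == 0:
        logger.warning("bias undefined: zero GEBV variance")
        return float("nan")
    return float(np.cov(y, g, ddof=0)[0, 1] / vg)


def marker_rank_correlations(
    effects: np.ndarray,
    trait_names=TRAITS,
    magnitude: str = "squared",
) -> RankCorrMatrix:
    """Spearman rank correlations between per-marker effect magnitudes."""
    effects = np.asarray(effects, dtype=float)
    if effects.shape[0] < 3:
        raise ValueError("rank correlations need at least 3 markers")
    if magnitude == "squared":
        mags = effects**2
    elif magnitude == "absolute":
        mags = np.abs(effects)
    elif magnitude == "raw":
        mags = effects
    else:
        raise ValueError(f"unknown magnitude {magnitude!r}")
    t = mags.shape[1]
    rho = np.eye(t)
    pval = np.zeros((t, t))
    for i in range(t):
        for j in range(i):
            r, p = stats.spearmanr(mags[:, i], mags[:, j])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return RankCorrMatrix(tuple(trait_names), rho, pval, magnitude)


def _adjusted_phenotypes(frame_X, y, test_X):
    """Residualize test phenotypes on training-estimated fixed effects."""
    coef, *_ = np.linalg.lstsq(frame_X, y, rcond=None)
    return coef


def run_validation(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    config: ChainConfig,
    traits=TRAITS,
    n_train: int = 400,
    split_seed: int = 0,
    maf_threshold: float = 0.05,
    missing_threshold: float = 0.10,
    magnitude: str = "squared",
    adjusted: bool = False,
    include_dim_in_h2: bool = True,
    dim_bin_days: int = 30,
):
    """QC, split, fit ST per trait and MT jointly, predict and score the test set.

    Returns ``(ValidationResult, RankCorrMatrix, GeneticParams)``.  The rank
    correlations and genetic parameters are computed from the multi-trait fit,
    whose draws carry effects for every trait jointly.
    """
    traits = tuple(traits)
    clean, qc_report = run_qc(geno, maf_threshold, missing_threshold)
    clean, pheno_al = align(clean, pheno)
    M, freqs = center_markers(clean)
    snp_vars = marker_variances(clean)

    train_ids, test_ids = split_train_test(clean.animal_ids, n_train, split_seed)
    test_pos = {str(a): i for i, a in enumerate(clean.animal_ids)}
    test_idx = np.array([test_pos[str(a)] for a in test_ids])
    M_test = M[test_idx]
    pdf = pheno_al.df.set_index(pheno_al.df["animal_id"].astype(str))

    def observed(trait):
        return np.array([float(pdf.loc[str(a)][trait]) for a in test_ids])

    # --- single-trait fits
    acc_st = np.full(len(traits), np.nan)
    b_st = np.full(len(traits), np.nan)
    for k, trait in enumerate(traits):
        frame = build_model_frame(
            pheno_al, trait, M, clean.animal_ids, train_ids,
            marker_ids=clean.marker_ids, dim_bin_days=dim_bin_days,
        )
        st_cfg = _reseed(config, offset=1000 + k)
        draws = fit_st(frame, st_cfg)
        g_test = gebv(draws, M_test)
        y_test = observed(trait)
        if adjusted:
            coef = _adjusted_phenotypes(frame.X, frame.y, None)
            X_test = _test_design(frame, pdf, test_ids)
            y_test = y_test - X_test @ coef
        acc_st[k] = accuracy(y_test, g_test)
        b_st[k] = bias(y_test, g_test)

    # --- multi-trait fit
    mt_frame = build_mt_model_frame(
        pheno_al, traits, M, clean.animal_ids, train_ids,
        marker_ids=clean.marker_ids, dim_bin_days=dim_bin_days,
    )
    mt_cfg = _reseed(config, offset=2000)
    mt_draws = fit_mt(mt_frame, mt_cfg)
    G_test = gebv_mt(mt_draws, M_test)

    acc_mt = np.full(len(traits), np.nan)
    b_mt = np.full(len(traits), np.nan)
    for k, trait in enumerate(traits):
        y_test = observed(trait)
        if adjusted:
            yk = mt_frame.Y[:, k]
            coef = _adjusted_phenotypes(mt_frame.X, yk, None)
            X_test = _test_design(mt_frame, pdf, test_ids)
            y_test = y_test - X_test @ coef
        acc_mt[k] = accuracy(y_test, G_test[:, k])
        b_mt[k] = bias(y_test, G_test[:, k])

    result = ValidationResult(
        trait_names=traits,
        accuracy_mt=acc_mt,
        bias_mt=b_mt,
        accuracy_st=acc_st,
        bias_st=b_st,
        train_ids=train_ids,
        test_ids=test_ids,
        seed=split_seed,
    )
    rank = marker_rank_correlations(
        mt_draws.alpha_mean, trait_names=traits, magnitude=magnitude
    )
    params = summarize(
        mt_draws, snp_vars, pheno=pheno_al, include_dim=include_dim_in_h2
    )
    return result, rank, params


def _reseed(config: ChainConfig, offset: int) -> ChainConfig:
    """Derive a per-fit chain seed so the ST and MT chains do not share streams."""
    d = config.to_dict()
    d["seed"] = (int(d["seed"]) * 10_007 + offset) % (2**31 - 1)
    cfg = ChainConfig.from_dict(d)
    cfg.fix_Sigma_alpha = config.fix_Sigma_alpha
    cfg.fix_R = config.fix_R
    return cfg


def _test_design(frame, pdf, test_ids):
    """Rebuild the training design columns for the test animals."""
    cols = []
    for name in frame.x_columns:
        if name == "intercept":
            cols.append(np.ones(len(test_ids)))
        else:
            prefix, lev = name.rsplit("_", 1)
            col_name = "lactation_order" if prefix == "lactation" else "farm"
            vals = np.array([int(pdf.loc[str(a)][col_name]) for a in test_ids])
            cols.append((vals == int(lev)).astype(float))
    return np.column_stack(cols)
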