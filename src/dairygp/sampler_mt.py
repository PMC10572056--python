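"""Multi-trait Bayesian marker-effect model fitted by Gibbs sampling.

Each marker carries a t-variate effect vector a_j ~ N(0, Sigma_alpha) with an
unstructured covariance across traits, and residual rows are N(0, R).  The
stacked genetic values then have the Kronecker covariance Sigma (x) K with K
the marker-derived relationship matrix, i.e. the usual multi-trait GBLUP
structure, while the sampler itself works in marker space so per-iteration
marker effects are available for the genetic-covariance summaries.

Priors: inverse-Wishart with nu = t + 3 degrees of freedom for Sigma_alpha
and R, scale matrices set so the prior mode splits the phenotypic variance
30% genetic / 65% residual (diagonal), and scaled-inverse-chi-square for the
per-trait days-in-milk variances (diagonal across-trait DIM covariance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _gibbs
from .data_io import PhenotypeTable
from .draws import ChainConfig, PosteriorDraws
from .sampler_st import ModelFrame, _design_columns, dim_to_class

logger = logging.getLogger(__name__)


@dataclass
class MTModelFrame:
    """Design matrices shared across traits; Y holds complete cases only."""

    Y: np.ndarray
    X: np.ndarray
    dim_class: np.ndarray
    n_dim_classes: int
    M: np.ndarray
    animal_ids: np.ndarray
    trait_names: tuple
    x_columns: list = field(default_factory=list)
    dim_class_labels: list = field(default_factory=list)
    marker_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))

    def __post_init__(self) -> None:
        if np.isnan(self.Y).any():
            raise ValueError("MTModelFrame requires complete cases (no missing traits)")
        n = self.Y.shape[0]
        if not (self.X.shape[0] == n == self.M.shape[0]):
            raise ValueError("Y, X and M row counts disagree")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design X is rank deficient")


def build_mt_model_frame(
    pheno: PhenotypeTable,
    traits: Sequence[str],
    M: np.ndarray,
    geno_animal_ids: Sequence,
    train_ids: Sequence,
    marker_ids=None,
    dim_bin_days: int = 30,
    include_dim: bool = True,
) -> MTModelFrame:
    """Complete-case multi-trait frame: animals missing any trait are dropped."""
    traits = tuple(traits)
    geno_ids = [str(a) for a in geno_animal_ids]
    pos = {a: i for i, a in enumerate(geno_ids)}
    pdf = pheno.df.set_index(pheno.df["animal_id"].astype(str))

    kept_ids, rows = [], []
    n_dropped = 0
    for a in map(str, train_ids):
        if a not in pos or a not in pdf.index:
            n_dropped += 1
            continue
        rec = pdf.loc[a]
        vals = [float(rec[t]) for t in traits]
        if not all(np.isfinite(vals)) or not np.isfinite(float(rec["dim"])):
            n_dropped += 1
            continue
        kept_ids.append(a)
        rows.append(rec)
    if n_dropped:
        logger.warning("build_mt_model_frame: dropped %d incomplete animal(s)", n_dropped)
    if not kept_ids:
        raise ValueError("no complete-case training animals")

    Y = np.array([[float(r[t]) for t in traits] for r in rows])
    lact = np.array([int(r["lactation_order"]) for r in rows])
    farm = np.array([int(r["farm"]) for r in rows])
    dim = np.array([float(r["dim"]) for r in rows])

    cols = [np.ones(len(kept_ids))]
    names = ["intercept"]
    for vals, prefix in ((lact, "lactation"), (farm, "farm")):
        c, nm = _design_columns(vals, prefix)
        cols.extend(c)
        names.extend(nm)
    X = np.column_stack(cols)

    if include_dim:
        raw_class = dim_to_class(dim, dim_bin_days)
        labels = sorted(set(raw_class.tolist()))
        index = {lab: i for i, lab in enumerate(labels)}
        dim_class = np.array([index[c] for c in raw_class], dtype=np.int64)
        n_dim = len(labels)
    else:
        dim_class = np.empty(0, dtype=np.int64)
        labels = []
        n_dim = 0

    midx = np.array([pos[a] for a in kept_ids])
    return MTModelFrame(
        Y=Y,
        X=X,
        dim_class=dim_class,
        n_dim_classes=n_dim,
        M=np.ascontiguousarray(M[midx]),
        animal_ids=np.asarray(kept_ids, dtype=object),
        trait_names=traits,
        x_columns=names,
        dim_class_labels=labels,
        marker_ids=(
            np.asarray(marker_ids, dtype=object)
            if marker_ids is not None
            else np.array([f"m{j}" for j in range(M.shape[1])], dtype=object)
        ),
    )


def fit_mt(frame: MTModelFrame, config: ChainConfig) -> PosteriorDraws:
    """Run the multi-trait Gibbs chain and return the retained draws."""
    t = frame.Y.shape[1]
    var_y = frame.Y.var(axis=0)
    var_y = np.where(var_y > 0, var_y, 1.0)
    msx = float(frame.M.var(axis=0).sum())
    if msx <= 0:
        msx = 1.0

    nu_a = float(t + 3)
    nu_e = float(t + 3)
    # inverse-Wishart mode is S / (nu + t + 1)
    target_Sa = np.diag(config.genetic_frac * var_y / msx)
    target_R = np.diag(
        np.maximum(1.0 - config.genetic_frac - config.dim_frac, 1e-3) * var_y
    )
    S_a = target_Sa * (nu_a + t + 1.0)
    S_e = target_R * (nu_e + t + 1.0)
    td = config.dim_frac * var_y
    S_d_diag = np.maximum(td, 1e-12) * (config.nu_d + 2.0) / config.nu_d

    if config.fix_Sigma_alpha is not None:
        Sa0 = np.ascontiguousarray(config.fix_Sigma_alpha, dtype=float)
    else:
        Sa0 = target_Sa.copy()
    if config.fix_R is not None:
        R0 = np.ascontiguousarray(config.fix_R, dtype=float)
    else:
        R0 = target_R.copy()
    s2d0 = np.maximum(td, 1e-12).astype(float)
    if config.fix_sigma2_d is not None:
        s2d0 = np.full(t, float(config.fix_sigma2_d))

    Mt = np.ascontiguousarray(frame.M.T)
    out = _gibbs.mt_chain(
        np.ascontiguousarray(frame.Y, dtype=float),
        np.ascontiguousarray(frame.X, dtype=float),
        frame.dim_class,
        frame.n_dim_classes,
        Mt,
        config.n_iter,
        config.burn_in,
        config.thin,
        nu_a,
        np.ascontiguousarray(S_a),
        config.nu_d,
        np.ascontiguousarray(S_d_diag),
        nu_e,
        np.ascontiguousarray(S_e),
        Sa0,
        s2d0,
        R0,
        config.fix_Sigma_alpha is None,
        config.fix_sigma2_d is None,
        config.fix_R is None,
        int(config.seed),
    )
    alpha, b, d, Sa_draws, R_draws, s2d_draws, status, fail_iter = out
    if status != 0:
        reasons = {
            1: "non-finite variance state",
            2: "covariance draw not positive definite",
            3: "inverse-Wishart draw failed after jitter retry",
        }
        raise RuntimeError(
            f"multi-trait chain aborted at iteration {fail_iter} "
            f"({reasons.get(status, 'unknown')})"
        )
    return PosteriorDraws(
        model_tag="MT",
        alpha=alpha,
        b=b,
        d=d,
        Sigma_a=Sa_draws,
        R=R_draws,
        sigma2_d=s2d_draws,
        config=config,
        trait_names=frame.trait_names,
        marker_ids=frame.marker_ids,
    )


def gebv_mt(draws: PosteriorDraws, M: np.ndarray) -> np.ndarray:
    """Animals x traits GEBV matrix from posterior-mean marker effects."""
    if M.shape[1] != draws.alpha.shape[1]:
        raise ValueError(
            f"marker count mismatch: M has {M.shape[1]}, draws have "
            f"{draws.alpha.shape[1]}"
        )
    return M @ draws.alpha_mean
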