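"""Single-trait Bayesian ridge (SNP-BLUP) fitted by Gibbs sampling.

The model is ``y = X b + W d + M alpha + e`` with an intercept and
treatment-coded lactation-order and farm dummies in X, days-in-milk binned
into classes carrying i.i.d. N(0, sigma_d^2) effects in W, and i.i.d.
N(0, sigma_alpha^2) marker effects.  Because ``g = M alpha`` has covariance
(M M') sigma_alpha^2, this is the marker-space equivalent of GBLUP with a
VanRaden relationship matrix: K = M M' / c and sigma_a^2 = c sigma_alpha^2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _gibbs
from .data_io import PhenotypeTable
from .draws import ChainConfig, PosteriorDraws

logger = logging.getLogger(__name__)


@dataclass
class ModelFrame:
    """Aligned design matrices for one trait on the training animals."""

    y: np.ndarray
    X: np.ndarray
    dim_class: np.ndarray  # int class index per animal, or empty if no DIM term
    n_dim_classes: int
    M: np.ndarray
    animal_ids: np.ndarray
    trait: str
    x_columns: list = field(default_factory=list)
    dim_class_labels: list = field(default_factory=list)
    marker_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))

    def __post_init__(self) -> None:
        n = len(self.y)
        if not (self.X.shape[0] == n == self.M.shape[0]):
            raise ValueError("y, X and M row counts disagree")
        if self.n_dim_classes > 0 and len(self.dim_class) != n:
            raise ValueError("dim_class length disagrees with y")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design X is rank deficient")


def _design_columns(values: np.ndarray, prefix: str):
    """Treatment (reference-level) dummies for the observed levels."""
    levels = sorted(set(values.tolist()))
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((values == lev).astype(float))
        names.append(f"{prefix}_{lev}")
    return cols, names


def dim_to_class(dim: np.ndarray, bin_days: int = 30) -> np.ndarray:
    """Bin days-in-milk into 1-based classes of ``bin_days`` days."""
    return (np.asarray(dim, dtype=float) // bin_days).astype(int) + 1


def build_model_frame(
    pheno: PhenotypeTable,
    trait: str,
    M: np.ndarray,
    geno_animal_ids: Sequence,
    train_ids: Sequence,
    marker_ids=None,
    dim_bin_days: int = 30,
    include_dim: bool = True,
) -> ModelFrame:
    """Assemble y, X, W and the marker rows for the training animals.

    Animals missing the trait or a covariate are excluded with a warning.
    """
    geno_ids = [str(a) for a in geno_animal_ids]
    pos = {a: i for i, a in enumerate(geno_ids)}
    pdf = pheno.df.set_index(pheno.df["animal_id"].astype(str))

    rows, kept_ids, dropped = [], [], []
    for a in map(str, train_ids):
        if a not in pos or a not in pdf.index:
            dropped.append(a)
            continue
        rec = pdf.loc[a]
        if not np.isfinite(float(rec[trait])) or not np.isfinite(float(rec["dim"])):
            dropped.append(a)
            continue
        rows.append(rec)
        kept_ids.append(a)
    if dropped:
        logger.warning(
            "build_model_frame(%s): excluded %d animal(s) with missing data: %s",
            trait,
            len(dropped),
            dropped[:10],
        )
    if not kept_ids:
        raise ValueError(f"no usable training animals for trait {trait}")

    y = np.array([float(r[trait]) for r in rows])
    lact = np.array([int(r["lactation_order"]) for r in rows])
    farm = np.array([int(r["farm"]) for r in rows])
    dim = np.array([float(r["dim"]) for r in rows])

    cols = [np.ones(len(y))]
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
    return ModelFrame(
        y=y,
        X=X,
        dim_class=dim_class,
        n_dim_classes=n_dim,
        M=np.ascontiguousarray(M[midx]),
        animal_ids=np.asarray(kept_ids, dtype=object),
        trait=trait,
        x_columns=names,
        dim_class_labels=labels,
        marker_ids=(
            np.asarray(marker_ids, dtype=object)
            if marker_ids is not None
            else np.array([f"m{j}" for j in range(M.shape[1])], dtype=object)
        ),
    )


def _prior_scales(var_y: float, msx: float, config: ChainConfig):
    """Scaled-inverse-chi-square scales whose prior mode splits var(y)."""
    g, dfrac = config.genetic_frac, config.dim_frac
    tg = g * var_y / msx if msx > 0 else g * var_y
    td = dfrac * var_y
    te = max(1.0 - g - dfrac, 1e-3) * var_y
    # mode of scaled-inv-chi2(nu, s2) is nu s2 / (nu + 2)
    sa = tg * (config.nu_a + 2.0) / config.nu_a
    sd = td * (config.nu_d + 2.0) / config.nu_d
    se = te * (config.nu_e + 2.0) / config.nu_e
    return (tg, td, te), (sa, sd, se)


def fit_st(frame: ModelFrame, config: ChainConfig) -> PosteriorDraws:
    """Run the single-trait Gibbs chain and return the retained draws."""
    var_y = float(np.var(frame.y))
    if var_y == 0.0:
        var_y = 1.0
    msx = float(frame.M.var(axis=0).sum())
    (tg, td, te), (sa, sd, se) = _prior_scales(var_y, msx, config)

    s2a0 = config.fix_sigma2_alpha if config.fix_sigma2_alpha is not None else tg
    s2d0 = config.fix_sigma2_d if config.fix_sigma2_d is not None else max(td, 1e-12)
    s2e0 = config.fix_sigma2_e if config.fix_sigma2_e is not None else te

    Mt = np.ascontiguousarray(frame.M.T)
    out = _gibbs.st_chain(
        frame.y.astype(float),
        np.ascontiguousarray(frame.X, dtype=float),
        frame.dim_class,
        frame.n_dim_classes,
        Mt,
        config.n_iter,
        config.burn_in,
        config.thin,
        config.nu_a,
        sa,
        config.nu_d,
        sd,
        config.nu_e,
        se,
        float(s2a0),
        float(s2d0),
        float(s2e0),
        config.fix_sigma2_alpha is None,
        config.fix_sigma2_d is None,
        config.fix_sigma2_e is None,
        int(config.seed),
    )
    alpha, b, d, s2a, s2d_dr, s2e, status, fail_iter = out
    if status != 0:
        raise RuntimeError(
            f"single-trait chain aborted at iteration {fail_iter} "
            f"(status {status}: non-finite variance state)"
        )
    k = alpha.shape[0]
    return PosteriorDraws(
        model_tag="ST",
        alpha=alpha[:, :, None],
        b=b[:, :, None],
        d=d[:, :, None],
        Sigma_a=s2a.reshape(k, 1, 1),
        R=s2e.reshape(k, 1, 1),
        sigma2_d=s2d_dr.reshape(k, 1),
        config=config,
        trait_names=(frame.trait,),
        marker_ids=frame.marker_ids,
    )


def gebv(draws: PosteriorDraws, M: np.ndarray) -> np.ndarray:
    """Genomic breeding values M @ posterior-mean marker effects (1-D for ST)."""
    if M.shape[1] != draws.alpha.shape[1]:
        raise ValueError(
            f"marker count mismatch: M has {M.shape[1]}, draws have "
            f"{draws.alpha.shape[1]}"
        )
    g = M @ draws.alpha_mean
    return g[:, 0] if draws.model_tag == "ST" else g


def _ess(x: np.ndarray) -> float:
    """Initial-positive-sequence effective sample size for one chain."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, n // 2):
        pair = acf[2 * k - 1] + acf[2 * k] if 2 * k < n else 0.0
        if pair < 0:
            break
        s += pair
    return float(min(n, n / (1.0 + 2.0 * s)))


def fit_summary(draws: PosteriorDraws, path=None) -> dict:
    """Posterior means/SDs and effective sample sizes of the variance draws."""
    t = draws.n_traits
    summary = {
        "model_tag": draws.model_tag,
        "n_draws": int(draws.n_draws),
        "traits": list(draws.trait_names),
        "Sigma_a_mean": draws.Sigma_a.mean(axis=0).tolist(),
        "Sigma_a_sd": draws.Sigma_a.std(axis=0).tolist(),
        "R_mean": draws.R.mean(axis=0).tolist(),
        "R_sd": draws.R.std(axis=0).tolist(),
        "sigma2_d_mean": draws.sigma2_d.mean(axis=0).tolist(),
        "ess_Sigma_a_diag": [_ess(draws.Sigma_a[:, i, i]) for i in range(t)],
        "ess_R_diag": [_ess(draws.R[:, i, i]) for i in range(t)],
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(summary, fh, indent=2)
    return summary
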