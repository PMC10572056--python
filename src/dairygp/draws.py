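"""Chain configuration and retained-draw containers shared by both samplers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class ChainConfig:
    """Gibbs-chain settings.

    Defaults follow the production protocol (100,000 iterations with the
    first 20,000 discarded as burn-in); tests and the command line use
    shorter desk-scale chains.  ``nu_a`` / ``nu_d`` / ``nu_e`` are prior
    degrees of freedom for the genetic, days-in-milk and residual variance
    components; prior scales are derived from the phenotypic variance so that
    the prior mode splits it 30% genetic / 5% DIM / 65% residual.

    Setting ``fix_sigma2_alpha`` / ``fix_sigma2_e`` / ``fix_sigma2_d`` (or the
    matrix analogues ``fix_Sigma_alpha`` / ``fix_R`` for the multi-trait
    model) pins a variance component instead of sampling it, which is how the
    closed-form ridge/GBLUP cross-checks are run.
    """

    n_iter: int = 100_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 0
    nu_a: float = 5.0
    nu_d: float = 5.0
    nu_e: float = 5.0
    genetic_frac: float = 0.30
    dim_frac: float = 0.05
    fix_sigma2_alpha: Optional[float] = None
    fix_sigma2_d: Optional[float] = None
    fix_sigma2_e: Optional[float] = None
    fix_Sigma_alpha: Optional[np.ndarray] = None
    fix_R: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not (0 < self.burn_in < self.n_iter):
            raise ValueError("require 0 < burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    def to_dict(self) -> dict:
        d = {
            "n_iter": self.n_iter,
            "burn_in": self.burn_in,
            "thin": self.thin,
            "seed": self.seed,
            "nu_a": self.nu_a,
            "nu_d": self.nu_d,
            "nu_e": self.nu_e,
            "genetic_frac": self.genetic_frac,
            "dim_frac": self.dim_frac,
            "fix_sigma2_alpha": self.fix_sigma2_alpha,
            "fix_sigma2_d": self.fix_sigma2_d,
            "fix_sigma2_e": self.fix_sigma2_e,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChainConfig":
        kwargs = {}
        ints = {"n_iter", "burn_in", "thin", "seed"}
        for k, v in d.items():
            if v is None:
                kwargs[k] = None
            elif k in ints:
                kwargs[k] = int(v)
            else:
                kwargs[k] = float(v)
        return cls(**kwargs)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws from one model fit.

    Arrays use a unified layout for both the single-trait (t = 1) and
    multi-trait samplers:

    - ``alpha``: (n_draws, p, t) marker effects
    - ``b``: (n_draws, f, t) fixed effects
    - ``d``: (n_draws, n_dim_classes, t) days-in-milk class effects
    - ``Sigma_a``: (n_draws, t, t) marker-effect (co)variance
    - ``R``: (n_draws, t, t) residual (co)variance
    - ``sigma2_d``: (n_draws, t) DIM variance per trait
    """

    model_tag: str
    alpha: np.ndarray
    b: np.ndarray
    d: np.ndarray
    Sigma_a: np.ndarray
    R: np.ndarray
    sigma2_d: np.ndarray
    config: ChainConfig
    trait_names: tuple = ()
    marker_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))

    def __post_init__(self) -> None:
        if self.alpha.shape[0] != self.config.n_retained:
            raise ValueError(
                f"retained draw count {self.alpha.shape[0]} != "
                f"(n_iter - burn_in) // thin = {self.config.n_retained}"
            )

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_traits(self) -> int:
        return self.alpha.shape[2]

    @property
    def alpha_mean(self) -> np.ndarray:
        """Posterior-mean marker effects, (p, t)."""
        return self.alpha.mean(axis=0)
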