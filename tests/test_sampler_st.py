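import numpy as np
import pytest

from dairygp import ChainConfig, build_model_frame, fit_st, gebv
from dairygp.sampler_st import ModelFrame, dim_to_class
from helpers import make_pheno


def intercept_frame(y, M, n_dim=0, dim_class=None):
    return ModelFrame(
        y=y,
        X=np.ones((len(y), 1)),
        dim_class=dim_class if dim_class is not None else np.empty(0, dtype=np.int64),
        n_dim_classes=n_dim,
        M=M,
        animal_ids=np.arange(len(y)).astype(object),
        trait="T",
    )


class TestBuildModelFrame:
    def test_reference_coding_observed_levels_only(self):
        ids = [f"a{i}" for i in range(3)]
        pheno = make_pheno(
            ids,
            lactation_order=[1, 2, 2],
            farm=[1, 1, 2],
            dim=[10.0, 40.0, 350.0],
        )
        M = np.zeros((3, 4))
        frame = build_model_frame(pheno, "MY", M, ids, ids)
        # intercept + lactation level 2 dummy + farm level 2 dummy
        assert frame.x_columns == ["intercept", "lactation_2", "farm_2"]
        np.testing.assert_array_equal(frame.X[:, 1], [0, 1, 1])
        np.testing.assert_array_equal(frame.X[:, 2], [0, 0, 1])

    def test_single_farm_no_dummies(self):
        ids = [f"a{i}" for i in range(4)]
        pheno = make_pheno(ids, farm=[3, 3, 3, 3], lactation_order=[1, 1, 1, 1])
        frame = build_model_frame(pheno, "MF", np.zeros((4, 2)), ids, ids)
        assert frame.x_columns == ["intercept"]

    def test_dim_binning(self):
        assert dim_to_class(np.array([10.0, 40.0, 350.0]), 30).tolist() == [1, 2, 12]

    def test_missing_trait_excluded_with_warning(self, caplog):
        ids = [f"a{i}" for i in range(5)]
        my = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        pheno = make_pheno(
            ids, MY=my, farm=[1] * 5, lactation_order=[1] * 5
        )
        frame = build_model_frame(pheno, "MY", np.zeros((5, 2)), ids, ids)
        assert len(frame.y) == 4
        assert "a2" not in list(frame.animal_ids)


class TestFitST:
    def test_ridge_oracle_small(self, ridge_fixture):
        """Fixed variances, intercept only: posterior mean alpha ~ ridge solution."""
        f = ridge_fixture
        cfg = ChainConfig(
            n_iter=4000, burn_in=1000, thin=1, seed=11,
            fix_sigma2_alpha=f["s2a"], fix_sigma2_e=f["s2e"], fix_sigma2_d=1.0,
        )
        frame = intercept_frame(f["y"], f["M"])
        draws = fit_st(frame, cfg)
        lam = f["s2e"] / f["s2a"]
        M, y = f["M"], f["y"]
        bhat = y.mean()
        ridge = np.linalg.solve(M.T @ M + lam * np.eye(M.shape[1]), M.T @ (y - bhat))
        dev = np.abs(draws.alpha_mean[:, 0] - ridge).max()
        assert dev < 0.05  # MC error at 3k retained draws

    def test_zero_phenotype_gives_zero_effects(self, ridge_fixture):
        f = ridge_fixture
        cfg = ChainConfig(
            n_iter=2000, burn_in=500, thin=1, seed=3,
            fix_sigma2_alpha=f["s2a"], fix_sigma2_e=f["s2e"], fix_sigma2_d=1.0,
        )
        draws = fit_st(intercept_frame(np.zeros(30), f["M"]), cfg)
        assert np.abs(draws.alpha_mean).max() < 0.05

    def test_seeded_bit_reproducibility(self, ridge_fixture):
        f = ridge_fixture
        cfg = ChainConfig(n_iter=400, burn_in=100, thin=2, seed=99)
        d1 = fit_st(intercept_frame(f["y"], f["M"]), cfg)
        d2 = fit_st(intercept_frame(f["y"], f["M"]), cfg)
        np.testing.assert_array_equal(d1.alpha, d2.alpha)
        np.testing.assert_array_equal(d1.R, d2.R)

    def test_variance_draws_positive_and_count(self, ridge_fixture):
        f = ridge_fixture
        cfg = ChainConfig(n_iter=503, burn_in=100, thin=7, seed=1)
        draws = fit_st(intercept_frame(f["y"], f["M"]), cfg)
        assert draws.n_draws == (503 - 100) // 7
        assert (draws.Sigma_a[:, 0, 0] > 0).all()
        assert (draws.R[:, 0, 0] > 0).all()

    def test_dim_random_effect_runs(self, ridge_fixture):
        f = ridge_fixture
        dim_class = np.arange(30, dtype=np.int64) % 4
        frame = intercept_frame(f["y"], f["M"], n_dim=4, dim_class=dim_class)
        cfg = ChainConfig(n_iter=400, burn_in=100, thin=2, seed=2)
        draws = fit_st(frame, cfg)
        assert draws.d.shape == (150, 4, 1)
        assert (draws.sigma2_d > 0).all()


class TestGEBV:
    def test_linear_in_posterior_mean(self, ridge_fixture):
        f = ridge_fixture
        cfg = ChainConfig(n_iter=400, burn_in=100, thin=2, seed=4)
        draws = fit_st(intercept_frame(f["y"], f["M"]), cfg)
        g = gebv(draws, f["M"])
        np.testing.assert_allclose(g, f["M"] @ draws.alpha_mean[:, 0], atol=1e-12)

    def test_single_marker_centered_dosages(self):
        cfg = ChainConfig(n_iter=40, burn_in=10, thin=1, seed=0)
        k = cfg.n_retained
        from dairygp import PosteriorDraws

        draws = PosteriorDraws(
            model_tag="ST",
            alpha=np.full((k, 1, 1), 0.5),
            b=np.zeros((k, 1, 1)),
            d=np.zeros((k, 0, 1)),
            Sigma_a=np.ones((k, 1, 1)),
            R=np.ones((k, 1, 1)),
            sigma2_d=np.ones((k, 1)),
            config=cfg,
        )
        g = gebv(draws, np.array([[-1.0], [0.0], [1.0]]))
        np.testing.assert_allclose(g, [-0.5, 0.0, 0.5])

    def test_marker_mismatch_errors(self, ridge_fixture):
        f = ridge_fixture
        cfg = ChainConfig(n_iter=200, burn_in=50, thin=1, seed=5)
        draws = fit_st(intercept_frame(f["y"], f["M"]), cfg)
        with pytest.raises(ValueError, match="marker count mismatch"):
            gebv(draws, f["M"][:, :10])


def test_snp_blup_gblup_equivalence(ridge_fixture):
    """Posterior-mean GEBVs (fixed variances) match the direct mixed-model solve
    with K = MM'/c and sigma_a^2 = c sigma_alpha^2."""
    f = ridge_fixture
    M, y = f["M"], f["y"]
    cfg = ChainConfig(
        n_iter=4000, burn_in=1000, thin=1, seed=21,
        fix_sigma2_alpha=f["s2a"], fix_sigma2_e=f["s2e"], fix_sigma2_d=1.0,
    )
    draws = fit_st(intercept_frame(y, M), cfg)
    g_gibbs = gebv(draws, M)
    # animal-space GBLUP: g ~ N(0, c*s2a*K), K = MM'/c
    c = (M * M).sum()  # any positive c cancels below
    K = M @ M.T / c
    s2g = c * f["s2a"]
    yc = y - y.mean()
    g_mme = s2g * K @ np.linalg.solve(s2g * K + f["s2e"] * np.eye(len(y)), yc)
    r = np.corrcoef(g_gibbs, g_mme)[0, 1]
    assert r > 0.999
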