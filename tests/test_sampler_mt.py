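import numpy as np
import pytest

from dairygp import (
    ChainConfig,
    SimConfig,
    build_mt_model_frame,
    build_model_frame,
    center_markers,
    fit_mt,
    fit_st,
    gebv_mt,
    marker_variances,
    run_qc,
    simulate_dataset,
    split_train_test,
)
from dairygp.genetic_params import genetic_correlation, genetic_covariance
from dairygp.sampler_mt import MTModelFrame
from dairygp.sampler_st import ModelFrame


def mt_intercept_frame(Y, M, traits=None):
    n, t = Y.shape
    return MTModelFrame(
        Y=Y,
        X=np.ones((n, 1)),
        dim_class=np.empty(0, dtype=np.int64),
        n_dim_classes=0,
        M=M,
        animal_ids=np.arange(n).astype(object),
        trait_names=tuple(traits or [f"T{i}" for i in range(t)]),
    )


def test_t1_reduces_to_single_trait(ridge_fixture):
    """With one trait and fixed variances, fit_mt matches fit_st posterior means."""
    f = ridge_fixture
    cfg_mt = ChainConfig(
        n_iter=4000, burn_in=1000, thin=1, seed=31,
        fix_Sigma_alpha=np.array([[f["s2a"]]]),
        fix_R=np.array([[f["s2e"]]]),
        fix_sigma2_d=1.0,
    )
    cfg_st = ChainConfig(
        n_iter=4000, burn_in=1000, thin=1, seed=77,
        fix_sigma2_alpha=f["s2a"], fix_sigma2_e=f["s2e"], fix_sigma2_d=1.0,
    )
    mt = fit_mt(mt_intercept_frame(f["y"][:, None], f["M"]), cfg_mt)
    st = fit_st(
        ModelFrame(
            y=f["y"], X=np.ones((30, 1)),
            dim_class=np.empty(0, dtype=np.int64), n_dim_classes=0,
            M=f["M"], animal_ids=np.arange(30).astype(object), trait="T",
        ),
        cfg_st,
    )
    dev = np.abs(mt.alpha_mean[:, 0] - st.alpha_mean[:, 0]).max()
    assert dev < 0.05


def test_covariance_draws_positive_definite(small_dataset):
    _, geno, pheno, _ = small_dataset
    clean, _ = run_qc(geno)
    M, _ = center_markers(clean)
    frame = build_mt_model_frame(
        pheno, ("MY", "MF", "MP"), M, clean.animal_ids, clean.animal_ids
    )
    cfg = ChainConfig(n_iter=600, burn_in=200, thin=2, seed=41)
    draws = fit_mt(frame, cfg)
    for k in range(draws.n_draws):
        assert np.linalg.eigvalsh(draws.Sigma_a[k]).min() > 0
        assert np.linalg.eigvalsh(draws.R[k]).min() > 0
    # induced genetic correlations bounded in [-1, 1] for every draw
    v = marker_variances(clean)
    _, series = genetic_covariance(draws, v)
    _, corr_series, _ = genetic_correlation(series)
    assert (np.abs(corr_series) <= 1.0 + 1e-12).all()


def test_seeded_bit_reproducibility(small_dataset):
    _, geno, pheno, _ = small_dataset
    clean, _ = run_qc(geno)
    M, _ = center_markers(clean)
    frame = build_mt_model_frame(
        pheno, ("MY", "MF"), M, clean.animal_ids, clean.animal_ids
    )
    cfg = ChainConfig(n_iter=300, burn_in=100, thin=1, seed=55)
    d1 = fit_mt(frame, cfg)
    d2 = fit_mt(frame, cfg)
    np.testing.assert_array_equal(d1.alpha, d2.alpha)
    np.testing.assert_array_equal(d1.Sigma_a, d2.Sigma_a)


def test_zero_genetic_correlation_recovered():
    """Two uncorrelated traits: posterior-mean genetic correlation near zero."""
    corr = np.eye(5)
    cfg = SimConfig(
        n_markers=2000, seed=17, h2_true=(0.3, 0.3, 0.3, 0.3, 0.3),
        genetic_corr_true=corr,
    )
    geno, pheno, truth = simulate_dataset(cfg)
    clean, _ = run_qc(geno)
    M, _ = center_markers(clean)
    train, _ = split_train_test(clean.animal_ids, 400, seed=17)
    frame = build_mt_model_frame(pheno, ("MY", "MF"), M, clean.animal_ids, train)
    chain = ChainConfig(n_iter=3000, burn_in=1000, thin=2, seed=170)
    draws = fit_mt(frame, chain)
    v = marker_variances(clean)
    _, series = genetic_covariance(draws, v)
    corr_mean, _, _ = genetic_correlation(series)
    assert abs(corr_mean[0, 1]) < 0.15


def test_gebv_mt_examples_and_mismatch():
    cfg = ChainConfig(n_iter=40, burn_in=10, thin=1, seed=0)
    k = cfg.n_retained
    from dairygp import PosteriorDraws

    alpha = np.zeros((k, 3, 2))
    alpha[:, :, 0] = 0.5
    alpha[:, :, 1] = 0.5
    draws = PosteriorDraws(
        model_tag="MT", alpha=alpha, b=np.zeros((k, 1, 2)),
        d=np.zeros((k, 0, 2)), Sigma_a=np.stack([np.eye(2)] * k),
        R=np.stack([np.eye(2)] * k), sigma2_d=np.ones((k, 2)), config=cfg,
    )
    M = np.array([[1.0, 0.0, -1.0], [0.0, 2.0, 0.0]])
    G = gebv_mt(draws, M)
    np.testing.assert_allclose(G[:, 0], G[:, 1])  # identical effects -> identical GEBVs
    zero = PosteriorDraws(
        model_tag="MT", alpha=np.zeros((k, 3, 2)), b=np.zeros((k, 1, 2)),
        d=np.zeros((k, 0, 2)), Sigma_a=np.stack([np.eye(2)] * k),
        R=np.stack([np.eye(2)] * k), sigma2_d=np.ones((k, 2)), config=cfg,
    )
    np.testing.assert_array_equal(gebv_mt(zero, M), np.zeros((2, 2)))
    with pytest.raises(ValueError, match="marker count mismatch"):
        gebv_mt(draws, M[:, :2])


def test_mt_fixed_variance_matches_direct_solve():
    """Posterior-mean effects at fixed Sigma_alpha, R equal the stacked
    mixed-model solution with Kronecker covariance (independent oracle)."""
    rng = np.random.default_rng(99)
    n, p, t = 20, 40, 2
    freqs = rng.uniform(0.1, 0.5, p)
    X = rng.binomial(2, freqs[None, :], (n, p)).astype(float)
    M = X - X.mean(axis=0)
    V = X.var(axis=0).sum()
    Sa = np.array([[0.3, 0.12], [0.12, 0.25]]) / V
    R = np.array([[0.7, 0.1], [0.1, 0.8]])
    A_true = rng.standard_normal((p, t)) @ np.linalg.cholesky(Sa).T
    Y = M @ A_true + rng.standard_normal((n, t)) @ np.linalg.cholesky(R).T
    Yc = Y - Y.mean(axis=0)

    cfg = ChainConfig(
        n_iter=12000, burn_in=2000, thin=1, seed=7,
        fix_Sigma_alpha=Sa, fix_R=R, fix_sigma2_d=1.0,
    )
    draws = fit_mt(mt_intercept_frame(Y, M), cfg)

    Rinv = np.linalg.inv(R)
    Sainv = np.linalg.inv(Sa)
    C = np.kron(Rinv, M.T @ M) + np.kron(Sainv, np.eye(p))
    rhs = (M.T @ Yc @ Rinv).flatten(order="F")
    A_hat = np.linalg.solve(C, rhs).reshape((p, t), order="F")

    G_gibbs = gebv_mt(draws, M)
    G_direct = M @ A_hat
    for j in range(t):
        r = np.corrcoef(G_gibbs[:, j], G_direct[:, j])[0, 1]
        assert r > 0.99
    assert np.abs(draws.alpha_mean - A_hat).max() < 0.05


def test_trait_permutation_consistency(small_dataset):
    """Fitting (MY, MF) vs (MF, MY) gives consistent GEBVs up to MC error
    (exact draw equality is impossible with a single RNG stream)."""
    _, geno, pheno, _ = small_dataset
    clean, _ = run_qc(geno)
    M, _ = center_markers(clean)
    cfg = ChainConfig(n_iter=3000, burn_in=1000, thin=2, seed=13)
    f12 = build_mt_model_frame(pheno, ("MY", "MF"), M, clean.animal_ids, clean.animal_ids)
    f21 = build_mt_model_frame(pheno, ("MF", "MY"), M, clean.animal_ids, clean.animal_ids)
    d12 = fit_mt(f12, cfg)
    d21 = fit_mt(f21, cfg)
    G12 = gebv_mt(d12, M)
    G21 = gebv_mt(d21, M)
    assert np.corrcoef(G12[:, 0], G21[:, 1])[0, 1] > 0.9
    assert np.corrcoef(G12[:, 1], G21[:, 0])[0, 1] > 0.9
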