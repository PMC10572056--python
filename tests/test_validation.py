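import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dairygp import (
    ChainConfig,
    accuracy,
    bias,
    marker_rank_correlations,
    run_validation,
    split_train_test,
)


class TestSplit:
    def test_sizes_400_97(self):
        ids = [f"a{i}" for i in range(497)]
        train, test = split_train_test(ids, 400, seed=1)
        assert len(train) == 400 and len(test) == 97

    def test_deterministic_and_disjoint(self):
        ids = [f"a{i}" for i in range(50)]
        t1 = split_train_test(ids, 30, seed=9)
        t2 = split_train_test(ids, 30, seed=9)
        np.testing.assert_array_equal(t1[0], t2[0])
        assert set(t1[0]) | set(t1[1]) == set(ids)
        assert not set(t1[0]) & set(t1[1])

    def test_n_train_too_large(self):
        with pytest.raises(ValueError):
            split_train_test(["a", "b"], 2, seed=0)


class TestAccuracyBias:
    def test_perfect_and_inverted(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert accuracy(y, y) == pytest.approx(1.0)
        assert accuracy(y, -y) == pytest.approx(-1.0)
        assert bias(y, y) == pytest.approx(1.0)
        assert bias(2 * y, y) == pytest.approx(2.0)

    def test_five_point_oracles(self):
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        g = np.array([2.0, 2.0, 3.0, 0.0, 4.0])
        # least-squares slope oracle
        slope_hand = ((y - y.mean()) * (g - g.mean())).sum() / ((g - g.mean()) ** 2).sum()
        r_hand = ((y - y.mean()) * (g - g.mean())).sum() / np.sqrt(
            ((y - y.mean()) ** 2).sum() * ((g - g.mean()) ** 2).sum()
        )
        assert bias(y, g) == pytest.approx(slope_hand, abs=1e-12)
        assert accuracy(y, g) == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_flagged_nan(self):
        y = np.array([1.0, 2.0, 3.0])
        assert np.isnan(accuracy(y, np.ones(3)))
        assert np.isnan(bias(y, np.ones(3)))

    def test_shift_and_scale_invariances(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(20)
        g = 0.5 * y + rng.standard_normal(20)
        r0, b0 = accuracy(y, g), bias(y, g)
        # adding a constant to GEBVs changes neither
        assert accuracy(y, g + 7.0) == pytest.approx(r0)
        assert bias(y, g + 7.0) == pytest.approx(b0)
        # positive rescaling keeps r, scales b inversely
        assert accuracy(y, 3.0 * g) == pytest.approx(r0)
        assert bias(y, 3.0 * g) == pytest.approx(b0 / 3.0)


class TestRankCorrelations:
    def test_monotone_and_reversed(self):
        e = np.column_stack([np.arange(1, 7, dtype=float), 2 * np.arange(1, 7, dtype=float)])
        out = marker_rank_correlations(e, trait_names=("A", "B"))
        assert out.rho[0, 1] == pytest.approx(1.0)
        rev = np.column_stack([np.arange(1, 7, dtype=float), np.arange(6, 0, -1, dtype=float)])
        out = marker_rank_correlations(rev, trait_names=("A", "B"), magnitude="raw")
        assert out.rho[0, 1] == pytest.approx(-1.0)

    def test_ties_match_brute_force_average_ranks(self):
        a = np.array([1.0, 2.0, 2.0, 3.0, 1.0, 4.0])
        b = np.array([2.0, 1.0, 3.0, 3.0, 2.0, 5.0])
        out = marker_rank_correlations(
            np.column_stack([a, b]), trait_names=("A", "B"), magnitude="raw"
        )

        def avg_ranks(x):
            order = np.argsort(x, kind="stable")
            ranks = np.empty(len(x))
            i = 0
            while i < len(x):
                j = i
                while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
                    j += 1
                ranks[order[i: j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        ra, rb = avg_ranks(a), avg_ranks(b)
        rho_brute = np.corrcoef(ra, rb)[0, 1]
        assert out.rho[0, 1] == pytest.approx(rho_brute, abs=1e-12)

    def test_squared_magnitude_is_default(self):
        e = np.column_stack([np.array([-3.0, 1.0, 2.0]), np.array([3.0, -1.0, 2.0])])
        out = marker_rank_correlations(e, trait_names=("A", "B"))
        assert out.magnitude == "squared"
        assert out.rho[0, 1] == pytest.approx(1.0)  # squared magnitudes identical

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        e = rng.standard_normal((12, 2))
        base = marker_rank_correlations(e, trait_names=("A", "B"), magnitude="absolute")
        cubed = marker_rank_correlations(
            np.abs(e) ** 3, trait_names=("A", "B"), magnitude="raw"
        )
        assert base.rho[0, 1] == pytest.approx(cubed.rho[0, 1], abs=1e-12)

    def test_too_few_markers(self):
        with pytest.raises(ValueError, match="at least 3"):
            marker_rank_correlations(np.zeros((2, 2)))


class TestRunValidation:
    def test_end_to_end_deterministic(self, small_dataset):
        _, geno, pheno, _ = small_dataset
        cfg = ChainConfig(n_iter=400, burn_in=100, thin=2, seed=3)
        out1 = run_validation(geno, pheno, cfg, n_train=90, split_seed=5)
        out2 = run_validation(geno, pheno, cfg, n_train=90, split_seed=5)
        r1, _, _ = out1
        r2, _, _ = out2
        np.testing.assert_array_equal(r1.accuracy_mt, r2.accuracy_mt)
        np.testing.assert_array_equal(r1.accuracy_st, r2.accuracy_st)
        assert list(r1.train_ids) == list(r2.train_ids)

    def test_result_structure(self, small_dataset):
        _, geno, pheno, _ = small_dataset
        cfg = ChainConfig(n_iter=400, burn_in=100, thin=2, seed=3)
        result, rank, params = run_validation(geno, pheno, cfg, n_train=90, split_seed=5)
        assert len(result.test_ids) == geno.n_animals - 90 or len(result.test_ids) > 0
        assert result.accuracy_diff.shape == (5,)
        assert rank.rho.shape == (5, 5)
        assert np.all((params.h2 >= 0) & (params.h2 <= 1))
        df = result.to_frame()
        assert list(df.columns) == [
            "trait", "MT_r", "MT_b", "ST_r", "ST_b", "accuracy_diff_MT_minus_ST",
        ]
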