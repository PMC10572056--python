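import numpy as np
import pytest

from dairygp import GenotypeMatrix, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Seeded 120-animal, 300-marker dataset shared across fast tests."""
    cfg = SimConfig(n_animals=120, n_markers=300, seed=321)
    geno, pheno, truth = simulate_dataset(cfg)
    return cfg, geno, pheno, truth


@pytest.fixture
def tiny_geno():
    """2 animals x 3 markers, no missing."""
    return GenotypeMatrix(
        animal_ids=np.array(["a1", "a2"], dtype=object),
        marker_ids=np.array(["m1", "m2", "m3"], dtype=object),
        dosages=np.array([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0]]),
    )


@pytest.fixture
def ridge_fixture():
    """30 animals x 50 markers with a known marker-effect signal.

    Used by the fixed-variance sampler cross-checks (ridge closed form,
    GBLUP mixed-model equivalence, multi-trait degeneracy).
    """
    rng = np.random.default_rng(2024)
    n, p = 30, 50
    freqs = rng.uniform(0.1, 0.5, p)
    X = rng.binomial(2, freqs[None, :], (n, p)).astype(float)
    M = X - X.mean(axis=0)
    v = X.var(axis=0)
    V = v.sum()
    alpha_true = rng.normal(0.0, np.sqrt(0.4 / V), p)
    y = M @ alpha_true + rng.normal(0.0, np.sqrt(0.6), n)
    s2a, s2e = 0.4 / V, 0.6
    return dict(M=M, y=y, v=v, s2a=s2a, s2e=s2e, alpha_true=alpha_true)
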