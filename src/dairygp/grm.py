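"""Centered marker matrix and the genomic relationship matrix.

K follows VanRaden's first method: dosages are centered by twice the observed
ALT-allele frequency and the cross-product is scaled by a single constant
c = 2 * sum_j p_j (1 - p_j), so that with many markers the mean diagonal of K
approaches 1 for an unrelated, Hardy-Weinberg population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix


@dataclass
class RelationshipMatrix:
    animal_ids: np.ndarray
    K: np.ndarray
    allele_freqs: np.ndarray
    scaling_constant: float

    def __post_init__(self) -> None:
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K must be symmetric")

    def to_tsv(self, path) -> None:
        ids = [str(a) for a in self.animal_ids]
        pd.DataFrame(self.K, index=ids, columns=ids).to_csv(
            path, sep="\t", index_label="animal_id"
        )


def center_markers(geno: GenotypeMatrix):
    """Center each dosage column by 2p (observed ALT frequency).

    Returns the centered matrix M (n x p, float) and the per-marker
    frequencies p.  Requires a complete (post-QC, imputed) matrix.
    """
    X = np.asarray(geno.dosages, dtype=float)
    if np.isnan(X).any():
        raise ValueError("centering requires a complete matrix; run QC first")
    p = X.mean(axis=0) / 2.0
    return X - 2.0 * p, p


def compute_grm(M: np.ndarray, allele_freqs: np.ndarray, animal_ids=None,
                jitter: float = 0.0) -> RelationshipMatrix:
    """K = M M' / c with c = 2 * sum_j p_j (1 - p_j).

    ``jitter`` optionally adds eps * I for factorization stability; the
    default leaves K untouched.
    """
    p = np.asarray(allele_freqs, dtype=float)
    c = 2.0 * np.sum(p * (1.0 - p))
    if c <= 0:
        raise ValueError("degenerate marker panel: scaling constant is zero")
    K = (M @ M.T) / c
    K = 0.5 * (K + K.T)
    if jitter:
        K = K + jitter * np.eye(K.shape[0])
    if animal_ids is None:
        animal_ids = np.arange(K.shape[0]).astype(object)
    return RelationshipMatrix(
        animal_ids=np.asarray(animal_ids, dtype=object),
        K=K,
        allele_freqs=p,
        scaling_constant=float(c),
    )


def marker_variances(geno: GenotypeMatrix) -> np.ndarray:
    """Empirical variance of each dosage column (population denominator n)."""
    X = np.asarray(geno.dosages, dtype=float)
    if np.isnan(X).any():
        raise ValueError("marker variances require a complete matrix; run QC first")
    return X.var(axis=0)
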