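"""Shared builders for the test suite."""

import numpy as np
import pandas as pd

from dairygp import PhenotypeTable


def make_pheno(animal_ids, **overrides):
    """Phenotype table with plausible dairy values for the given animals."""
    n = len(animal_ids)
    rng = np.random.default_rng(0)
    data = {
        "animal_id": [str(a) for a in animal_ids],
        "MY": rng.normal(6500, 1000, n),
        "MF": rng.normal(4.1, 0.4, n),
        "MP": rng.normal(3.3, 0.2, n),
        "ML": rng.normal(4.8, 0.2, n),
        "MDM": rng.normal(12.9, 0.7, n),
        "lactation_order": rng.integers(1, 4, n),
        "farm": rng.integers(1, 13, n),
        "dim": rng.integers(5, 306, n).astype(float),
    }
    data.update(overrides)
    return PhenotypeTable(pd.DataFrame(data))
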