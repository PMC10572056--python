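"""Genotype quality control: missing-rate and MAF filters, mean imputation.

The filters mirror routine genomic-evaluation practice: animals whose
genotype missing rate exceeds the threshold are dropped first, minor allele
frequency is then recomputed on the retained animals and markers with MAF not
strictly above the threshold (including monomorphic markers) are removed, and
finally residual missing calls are replaced by the marker's mean dosage,
which preserves the observed allele frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data_io import GenotypeMatrix


@dataclass
class QCReport:
    maf_threshold: float
    missing_threshold: float
    n_markers_in: int
    n_markers_out: int
    n_animals_in: int
    n_animals_out: int
    removed_marker_ids: list = field(default_factory=list)
    removed_animal_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_markers_out == self.n_markers_in - len(self.removed_marker_ids)
        assert self.n_animals_out == self.n_animals_in - len(self.removed_animal_ids)

    def to_json(self, path=None) -> str:
        payload = {
            "maf_threshold": self.maf_threshold,
            "missing_threshold": self.missing_threshold,
            "n_markers_in": self.n_markers_in,
            "n_markers_out": self.n_markers_out,
            "n_animals_in": self.n_animals_in,
            "n_animals_out": self.n_animals_out,
            "removed_marker_ids": [str(m) for m in self.removed_marker_ids],
            "removed_animal_ids": [str(a) for a in self.removed_animal_ids],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def filter_animals(geno: GenotypeMatrix, missing_threshold: float = 0.10):
    """Drop animals whose fraction of missing genotype calls exceeds the threshold."""
    if not 0 <= missing_threshold <= 1:
        raise ValueError("missing_threshold must lie in [0, 1]")
    miss_rate = geno.missing_mask().mean(axis=1)
    keep = miss_rate <= missing_threshold
    if not keep.any():
        raise ValueError("animal missing-rate filter removed every animal")
    removed = [geno.animal_ids[i] for i in np.flatnonzero(~keep)]
    out = geno.subset(animal_idx=np.flatnonzero(keep))
    report = QCReport(
        maf_threshold=float("nan"),
        missing_threshold=missing_threshold,
        n_markers_in=geno.n_markers,
        n_markers_out=geno.n_markers,
        n_animals_in=geno.n_animals,
        n_animals_out=out.n_animals,
        removed_animal_ids=removed,
    )
    return out, report


def minor_allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """MAF per marker from non-missing dosages: p = mean(dosage)/2, MAF = min(p, 1-p)."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(geno.dosages, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def filter_markers(geno: GenotypeMatrix, maf_threshold: float = 0.05):
    """Keep markers with MAF strictly greater than the threshold.

    Monomorphic markers (MAF = 0) are always removed; fully-missing markers
    count as monomorphic.
    """
    if not 0 <= maf_threshold <= 0.5:
        raise ValueError("maf_threshold must lie in [0, 0.5]")
    maf = minor_allele_frequencies(geno)
    keep = np.nan_to_num(maf, nan=0.0) > maf_threshold
    if not keep.any():
        raise ValueError("MAF filter removed every marker")
    removed = [geno.marker_ids[j] for j in np.flatnonzero(~keep)]
    out = geno.subset(marker_idx=np.flatnonzero(keep))
    report = QCReport(
        maf_threshold=maf_threshold,
        missing_threshold=float("nan"),
        n_markers_in=geno.n_markers,
        n_markers_out=out.n_markers,
        n_animals_in=geno.n_animals,
        n_animals_out=geno.n_animals,
        removed_marker_ids=removed,
    )
    return out, report


def impute_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the marker's mean non-missing dosage."""
    mask = geno.missing_mask()
    if not mask.any():
        return geno
    if mask.all(axis=0).any():
        bad = geno.marker_ids[np.flatnonzero(mask.all(axis=0))]
        raise ValueError(f"fully-missing marker(s) {list(bad)}: filter before imputing")
    col_means = np.nanmean(geno.dosages, axis=0)
    dosages = np.where(mask, np.broadcast_to(col_means, geno.dosages.shape), geno.dosages)
    return GenotypeMatrix(geno.animal_ids, geno.marker_ids, dosages, imputed=True)


def run_qc(
    geno: GenotypeMatrix,
    maf_threshold: float = 0.05,
    missing_threshold: float = 0.10,
):
    """Animal filter, then MAF filter on the retained animals, then imputation."""
    by_animal, rep_a = filter_animals(geno, missing_threshold)
    by_marker, rep_m = filter_markers(by_animal, maf_threshold)
    clean = impute_missing(by_marker)
    report = QCReport(
        maf_threshold=maf_threshold,
        missing_threshold=missing_threshold,
        n_markers_in=geno.n_markers,
        n_markers_out=by_marker.n_markers,
        n_animals_in=geno.n_animals,
        n_animals_out=by_animal.n_animals,
        removed_marker_ids=rep_m.removed_marker_ids,
        removed_animal_ids=rep_a.removed_animal_ids,
    )
    return clean, report
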