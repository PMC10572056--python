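"""Readers and writers for genotype matrices, phenotype tables and posterior draws.

Genotypes travel as an animals x markers allele-dosage matrix with entries in
{0, 1, 2} and ``NaN`` marking a missing call.  The on-disk exchange format is a
self-describing TSV (first column ``animal_id``, remaining headers are marker
ids, cells ``0``/``1``/``2``/``NA``); biallelic VCF is also accepted and
converted to ALT-allele dosage counts.  Phenotypes are a CSV with one row per
animal carrying the five milk traits (MY, MF, MP, ML, MDM) plus the lactation
order, farm and days-in-milk covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical trait order used throughout the package.
TRAITS = ("MY", "MF", "MP", "ML", "MDM")

#: Required phenotype CSV header.
PHENO_COLUMNS = ("animal_id", *TRAITS, "lactation_order", "farm", "dim")

MISSING = np.nan


class DataFormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass
class GenotypeMatrix:
    """Animals x markers allele-dosage matrix.

    ``dosages`` is a float array; non-missing entries are exactly 0, 1 or 2
    and missing calls are ``NaN``.  After mean imputation (``imputed=True``)
    cells may be any real value in [0, 2].
    """

    animal_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray
    imputed: bool = False

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, p = self.dosages.shape
        if n != len(self.animal_ids) or p != len(self.marker_ids):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.marker_ids)} markers"
            )
        if len(set(self.animal_ids)) != n:
            raise ValueError("duplicate animal ids")
        if len(set(self.marker_ids)) != p:
            raise ValueError("duplicate marker ids")
        observed = self.dosages[~np.isnan(self.dosages)]
        if self.imputed:
            if observed.size and ((observed < 0) | (observed > 2)).any():
                raise ValueError("imputed dosages must lie in [0, 2]")
        elif observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))]
            raise ValueError(f"dosages must be 0/1/2/missing; found {bad[:5]}")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def subset(self, animal_idx=None, marker_idx=None) -> "GenotypeMatrix":
        a = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        m = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            animal_ids=self.animal_ids[a],
            marker_ids=self.marker_ids[m],
            dosages=self.dosages[np.ix_(a, m)],
            imputed=self.imputed,
        )


@dataclass
class PhenotypeTable:
    """Per-animal trait values and covariates, one row per animal."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [c for c in PHENO_COLUMNS if c not in self.df.columns]
        if missing_cols:
            raise DataFormatError(f"phenotype table missing column(s): {missing_cols}")
        if self.df["animal_id"].duplicated().any():
            dups = self.df.loc[self.df["animal_id"].duplicated(), "animal_id"].tolist()
            raise DataFormatError(f"duplicate animal_id(s): {dups}")
        self.df = self.df.reset_index(drop=True)
        for t in TRAITS:
            vals = self.df[t].to_numpy(dtype=float)
            if np.isinf(vals).any():
                raise DataFormatError(f"non-finite value in trait {t}")

    @property
    def animal_ids(self) -> np.ndarray:
        return self.df["animal_id"].to_numpy(dtype=object)

    def trait_values(self, trait: str) -> np.ndarray:
        return self.df[trait].to_numpy(dtype=float)

    def subset(self, idx) -> "PhenotypeTable":
        return PhenotypeTable(self.df.iloc[np.asarray(idx)].reset_index(drop=True))


# ---------------------------------------------------------------------------
# genotype IO


def read_genotypes(path, format: str = "dosage_tsv") -> GenotypeMatrix:
    """Read a genotype matrix from a dosage TSV or a biallelic VCF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "animal_id":
        raise DataFormatError(
            f"{path}: first column must be 'animal_id', found {df.columns[0]!r}"
        )
    marker_ids = df.columns[1:].to_numpy(dtype=object)
    animal_ids = df["animal_id"].to_numpy(dtype=object)
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    dosages = np.empty(raw.shape, dtype=float)
    allowed = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan, "": np.nan}
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell not in allowed:
                raise DataFormatError(
                    f"{path}: line {i + 2}, marker {marker_ids[j]!r}: "
                    f"invalid dosage {cell!r}"
                )
            dosages[i, j] = allowed[cell]
    return GenotypeMatrix(animal_ids, marker_ids, dosages)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    """Write the dosage TSV dialect (cells 0/1/2/NA)."""
    if geno.imputed:
        raise ValueError("the dosage TSV dialect stores raw 0/1/2/NA calls only")
    mask = np.isnan(geno.dosages)
    filled = np.where(mask, 0.0, geno.dosages)
    cells = np.where(mask, "NA", filled.astype(int).astype(str))
    df = pd.DataFrame(cells, columns=list(geno.marker_ids))
    df.insert(0, "animal_id", geno.animal_ids)
    df.to_csv(path, sep="\t", index=False)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    animal_ids = np.asarray(vcf.samples, dtype=object)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            logger.warning(
                "skipping non-biallelic site %s:%d", variant.CHROM, variant.POS
            )
            continue
        dose = np.empty(len(animal_ids), dtype=float)
        for i, gt in enumerate(variant.genotypes):
            a1, a2 = gt[0], gt[1]
            dose[i] = np.nan if (a1 < 0 or a2 < 0) else float(a1 + a2)
        marker_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        columns.append(dose)
    if n_skipped:
        logger.warning("skipped %d non-biallelic site(s) in %s", n_skipped, path)
    if not columns:
        raise DataFormatError(f"{path}: no usable biallelic sites")
    dosages = np.column_stack(columns)
    return GenotypeMatrix(animal_ids, np.asarray(marker_ids, dtype=object), dosages)


# ---------------------------------------------------------------------------
# phenotype IO


def read_phenotypes(path) -> PhenotypeTable:
    """Read the phenotype CSV; unparseable trait cells become missing."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing_cols = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataFormatError(f"{path}: missing required column(s): {missing_cols}")
    for t in TRAITS:
        df[t] = pd.to_numeric(df[t], errors="coerce")
    df["lactation_order"] = pd.to_numeric(df["lactation_order"]).astype(int)
    df["farm"] = pd.to_numeric(df["farm"]).astype(int)
    df["dim"] = pd.to_numeric(df["dim"]).astype(float)
    if (df["dim"] < 0).any():
        raise DataFormatError(f"{path}: negative days-in-milk")
    df["animal_id"] = df["animal_id"].astype(str)
    return PhenotypeTable(df[list(PHENO_COLUMNS)])


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# alignment


def align(geno: GenotypeMatrix, pheno: PhenotypeTable):
    """Restrict both inputs to their common animals, in genotype-file order."""
    pheno_ids = set(map(str, pheno.animal_ids))
    keep_idx = [i for i, a in enumerate(geno.animal_ids) if str(a) in pheno_ids]
    if not keep_idx:
        raise ValueError("no animals shared between genotypes and phenotypes")
    common_order = [str(geno.animal_ids[i]) for i in keep_idx]
    n_geno_dropped = geno.n_animals - len(keep_idx)
    n_pheno_dropped = len(pheno.df) - len(common_order)
    if n_geno_dropped or n_pheno_dropped:
        logger.info(
            "align: dropped %d genotyped and %d phenotyped animal(s)",
            n_geno_dropped,
            n_pheno_dropped,
        )
    geno_out = geno.subset(animal_idx=keep_idx)
    pheno_df = pheno.df.set_index(pheno.df["animal_id"].astype(str))
    pheno_out = PhenotypeTable(pheno_df.loc[common_order].reset_index(drop=True))
    return geno_out, pheno_out


# ---------------------------------------------------------------------------
# posterior-draw container (HDF5)

_DRAW_ARRAYS = ("alpha", "b", "d", "Sigma_a", "R", "sigma2_d")


def write_draws(draws, path) -> None:
    """Persist a :class:`~dairygp.draws.PosteriorDraws` to HDF5, losslessly."""
    import h5py

    with h5py.File(path, "w") as f:
        # track_times=False keeps same-seed reruns byte-identical
        for name in _DRAW_ARRAYS:
            f.create_dataset(name, data=getattr(draws, name), track_times=False)
        f.create_dataset(
            "trait_names", data=np.asarray(draws.trait_names, dtype="S"),
            track_times=False,
        )
        f.create_dataset(
            "marker_ids", data=np.asarray(draws.marker_ids, dtype="S"),
            track_times=False,
        )
        f.attrs["model_tag"] = draws.model_tag
        for k, v in draws.config.to_dict().items():
            f.attrs[f"config_{k}"] = v if v is not None else "__none__"


def read_draws(path):
    import h5py

    from .draws import ChainConfig, PosteriorDraws

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with h5py.File(path, "r") as f:
            arrays = {name: f[name][()] for name in _DRAW_ARRAYS}
            trait_names = tuple(s.decode() for s in f["trait_names"][()])
            marker_ids = np.asarray(
                [s.decode() for s in f["marker_ids"][()]], dtype=object
            )
            model_tag = f.attrs["model_tag"]
            cfg_items = {
                k[len("config_"):]: (None if isinstance(v, str) and v == "__none__" else v)
                for k, v in f.attrs.items()
                if k.startswith("config_")
            }
    except OSError as exc:  # pragma: no cover - corrupt container
        raise DataFormatError(f"{path}: unreadable draws container: {exc}") from exc
    config = ChainConfig.from_dict(cfg_items)
    return PosteriorDraws(
        model_tag=str(model_tag),
        trait_names=trait_names,
        marker_ids=marker_ids,
        config=config,
        **arrays,
    )
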