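"""In-memory containers shared across the pipeline.

The pipeline moves three sample-by-feature matrices around — additive
genotypes (0/1/2), methylation beta values in [0, 1] and log2 expression —
plus a feature-annotation table and an age/disease covariate table. Files
on disk are feature-major (the microarray convention); in memory everything
is samples x features so the regression code never transposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLE_GENOTYPE = "genotype"
ROLE_METHYLATION = "methylation-beta"
ROLE_EXPRESSION = "log2-expression"
ROLES = (ROLE_GENOTYPE, ROLE_METHYLATION, ROLE_EXPRESSION)

#: Relation of a CpG probe to the nearest CpG island. Shores are 0-2 kb from
#: an island, shelves 2-4 kb; N/S by chromosome arm orientation (p to q).
CPG_ISLAND_CATEGORIES = (
    "Island",
    "N_Shore",
    "S_Shore",
    "N_Shelf",
    "S_Shelf",
    "OpenSea",
)

#: Position of a CpG probe relative to gene structure (UCSC-style).
GENE_REGION_CATEGORIES = (
    "TSS1500",
    "TSS200",
    "5'UTR",
    "1stExon",
    "Body",
    "3'UTR",
    "Intergenic",
)

FEATURE_CLASSES = ("snp", "cpg", "transcript")

ANNOTATION_COLUMNS = [
    "feature_id",
    "feature_class",
    "chrom",
    "pos",
    "strand",
    "tss",
    "tes",
    "gene_symbol",
    "cpg_island_category",
    "gene_region_category",
]


class ValidationError(ValueError):
    """Raised when a matrix, annotation or covariate table violates its contract."""


@dataclass
class OmicsMatrix:
    """A samples x features numeric matrix with a role tag.

    Parameters
    ----------
    data
        DataFrame indexed by sample id, columns are feature ids.
    role
        One of ``genotype``, ``methylation-beta``, ``log2-expression``.
        Missing values (NaN) are permitted for genotypes only.
    """

    data: pd.DataFrame
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicated sample ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicated feature ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if self.role == ROLE_GENOTYPE:
            finite = values[~np.isnan(values)]
            if not np.isin(finite, (0.0, 1.0, 2.0)).all():
                raise ValidationError("genotype values must be 0, 1, 2 or missing")
        else:
            if np.isnan(values).any():
                bad = self.data.columns[np.isnan(values).any(axis=0)].tolist()
                raise ValidationError(
                    f"missing values only allowed for genotypes; offending features: {bad[:5]}"
                )
            if self.role == ROLE_METHYLATION and ((values < 0) | (values > 1)).any():
                bad = self.data.columns[
                    ((values < 0) | (values > 1)).any(axis=0)
                ].tolist()
                raise ValidationError(
                    f"methylation beta values outside [0, 1] for features: {bad[:5]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check a feature-annotation table against the shared contract.

    Coordinates are 1-based inclusive. Transcript rows carry ``tss``/``tes``
    with ``tss <= tes`` in genomic coordinates regardless of strand; point
    features (SNPs, CpGs) carry ``pos``.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValidationError(f"annotation missing columns: {missing}")
    if ann["feature_id"].duplicated().any():
        raise ValidationError("duplicated feature ids in annotation")
    bad_class = set(ann["feature_class"]) - set(FEATURE_CLASSES)
    if bad_class:
        raise ValidationError(f"unknown feature classes: {sorted(bad_class)}")
    points = ann[ann["feature_class"].isin(["snp", "cpg"])]
    if (points["pos"].astype(float) < 1).any():
        raise ValidationError("point-feature positions must be >= 1 (1-based)")
    tx = ann[ann["feature_class"] == "transcript"]
    if len(tx) and (tx["tss"].astype(float) > tx["tes"].astype(float)).any():
        raise ValidationError("transcript rows must satisfy tss <= tes")
    cpgs = ann[ann["feature_class"] == "cpg"]
    if len(cpgs):
        bad = set(cpgs["cpg_island_category"].dropna()) - set(CPG_ISLAND_CATEGORIES)
        if bad:
            raise ValidationError(f"unknown CpG island categories: {sorted(bad)}")
        bad = set(cpgs["gene_region_category"].dropna()) - set(GENE_REGION_CATEGORIES)
        if bad:
            raise ValidationError(f"unknown gene-region categories: {sorted(bad)}")
    return ann


def validate_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Check the sample covariate table (age in years, disease status 0/1)."""
    for col in ("sample_id", "age", "disease_status"):
        if col not in cov.columns:
            raise ValidationError(f"covariate table missing column {col!r}")
    if cov["sample_id"].duplicated().any():
        raise ValidationError("duplicated sample ids in covariates")
    if cov[["age", "disease_status"]].isna().any().any():
        raise ValidationError("covariates must not contain missing values")
    if not cov["disease_status"].astype(float).isin([0.0, 1.0]).all():
        raise ValidationError("disease_status must be 0 or 1")
    return cov
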