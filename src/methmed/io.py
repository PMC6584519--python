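"""Readers and writers for matrices, annotations, covariates and results.

Disk layout conventions:

* Matrix TSVs are feature-major (features as rows, first column
  ``feature_id``, header row of sample ids) — the shape microarray and
  genotype matrices ship in. ``read_matrix`` transposes to the in-memory
  samples x features contract and applies role-specific validation.
* Missing genotypes are written as ``NA``; other roles admit no missing
  values.
* Genotypes can alternatively be imported from a VCF (GT fields, biallelic
  records only) with additive ALT-allele coding.

Log lines (dropped samples, skipped records) go to standard error via the
``methmed`` logger.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    ANNOTATION_COLUMNS,
    OmicsMatrix,
    ROLE_GENOTYPE,
    ValidationError,
    validate_annotation,
    validate_covariates,
)

logger = logging.getLogger("methmed.io")

MISSING = "NA"


def read_matrix(path, role: str) -> OmicsMatrix:
    """Read a feature-major TSV into a validated samples x features matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OmicsMatrix(data=df.T.astype(float), role=role)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    """Write a matrix back to feature-major TSV (missing genotypes as NA)."""
    out = matrix.data.T
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep=MISSING)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "chrom": str})
    ann["gene_symbol"] = ann["gene_symbol"].fillna("")
    return validate_annotation(ann)


def write_annotation(ann: pd.DataFrame, path) -> None:
    validate_annotation(ann)
    ann.to_csv(path, sep="\t", index=False, columns=ANNOTATION_COLUMNS)


def read_covariates(path) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_covariates(cov)


def write_covariates(cov: pd.DataFrame, path) -> None:
    validate_covariates(cov)
    cov.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"snp_id": str, "cpg_id": str, "gene_id": str})


def write_truth_table(truth: pd.DataFrame, path) -> None:
    cols = ["snp_id", "cpg_id", "gene_id", "architecture", "beta_lg", "beta_gt", "beta_lt", "beta_tg"]
    truth.to_csv(path, sep="\t", index=False, columns=cols)


def import_vcf(path) -> OmicsMatrix:
    """Import genotypes from a VCF as an additive (ALT-allele count) matrix.

    Multiallelic records are skipped with a logged warning; missing GT
    fields become NaN. Feature ids are the VCF ID column, falling back to
    ``chrom:pos`` when the ID is absent.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning(
                "skipping multiallelic record %s:%s (%d ALT alleles)",
                variant.CHROM,
                variant.POS,
                len(variant.ALT),
            )
            continue
        # gts012: 0/1/2 = ALT count, 3 = unknown
        g = variant.gt_types.astype(float)
        g[g == 3] = np.nan
        vid = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        ids.append(vid)
        rows.append(g)
    data = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(samples), 0)),
        index=samples,
        columns=ids,
    )
    return OmicsMatrix(data=data, role=ROLE_GENOTYPE)


def align_samples(*matrices: OmicsMatrix, covariates: pd.DataFrame):
    """Subset and reorder all inputs to their common samples.

    The common sample set keeps the order of the first matrix. Returns the
    aligned matrices (same order as given) followed by the aligned
    covariate table. Raises if the intersection is empty.
    """
    if len(matrices) < 1:
        raise ValueError("need at least one matrix")
    validate_covariates(covariates)
    common = [s for s in matrices[0].sample_ids if all(
        s in m.data.index for m in matrices[1:]
    ) and s in set(covariates["sample_id"])]
    if not common:
        raise ValidationError("no samples shared across inputs")
    dropped = sum(m.n_samples - len(common) for m in matrices)
    if dropped:
        logger.info("align_samples: dropped %d sample rows outside the intersection", dropped)
    aligned = [OmicsMatrix(data=m.data.loc[common], role=m.role) for m in matrices]
    cov = (
        covariates.set_index("sample_id")
        .loc[common]
        .reset_index()
    )
    return (*aligned, cov)


def write_assoc_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)


def read_assoc_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"a_id": str, "b_id": str})


def write_summary(summary: dict, path) -> None:
    """Write a scan/CIT summary as a two-column key-value TSV."""
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for key, value in summary.items():
            fh.write(f"{key}\t{value}\n")
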