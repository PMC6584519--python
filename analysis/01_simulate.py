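#!/usr/bin/env python
"""Generate the study cohort: a synthetic multi-omics dataset with planted trios.

Emulates a PBMC multi-omics design — genotypes with block LD, methylation
betas and log2 expression with age/disease covariate effects — at n=500
(stable trio-level statistics) with 32 planted trios across the four
causal architectures. Writes the matrices, annotation, covariates and
ground truth under results/sim/ for the downstream steps.
"""

from pathlib import Path

import methmed as mm
from methmed import io

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"

CONFIG = mm.SimConfig(
    seed=20,
    n_samples=500,
    n_snps=300,
    n_cpgs=150,
    n_genes=60,
    trio_specs=(
        mm.TrioSpec("mediation", 12),
        mm.TrioSpec("common_cause", 8),
        mm.TrioSpec("reverse", 6),
        mm.TrioSpec("null", 6),
    ),
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    data = mm.simulate_dataset(CONFIG)
    io.write_matrix(data.genotypes, OUT / "genotypes.tsv")
    io.write_matrix(data.methylation, OUT / "methylation.tsv")
    io.write_matrix(data.expression, OUT / "expression.tsv")
    io.write_annotation(data.annotation, OUT / "annotation.tsv")
    io.write_covariates(data.covariates, OUT / "covariates.tsv")
    io.write_truth_table(data.truth, OUT / "truth.tsv")
    arch = data.truth.architecture.value_counts().to_dict()
    print(f"cohort: {CONFIG.n_samples} samples, {CONFIG.n_snps} SNPs, "
          f"{CONFIG.n_cpgs} CpGs, {CONFIG.n_genes} transcripts")
    print(f"planted trios by architecture: {arch}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
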