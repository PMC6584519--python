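#!/usr/bin/env python
"""Run the three cis QTL scans (meQTL, eQTM, eQTL) and characterize the output.

Each scan regresses the response on the predictor adjusting for age and
disease status within a 1 Mb cis window and controls FDR at 5% by
Benjamini-Hochberg. The meQTL scan output is additionally characterized:
CpG island/gene-region category breakdown, signed SNP-CpG distance
profile, and QQ diagnostics. Writes tables under results/scans/.
"""

import json
from pathlib import Path

import methmed as mm
from methmed import io
from methmed.containers import ROLE_EXPRESSION, ROLE_GENOTYPE, ROLE_METHYLATION
from methmed.network import (
    category_breakdown,
    distance_profile,
    plot_distance_hist,
    plot_qq,
    qq_data,
)
from methmed.qtl import ScanConfig, run_scan, significant_pairs

ROOT = Path(__file__).resolve().parents[1] / "results"
SIM, OUT = ROOT / "sim", ROOT / "scans"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    geno = io.read_matrix(SIM / "genotypes.tsv", ROLE_GENOTYPE)
    meth = io.read_matrix(SIM / "methylation.tsv", ROLE_METHYLATION)
    expr = io.read_matrix(SIM / "expression.tsv", ROLE_EXPRESSION)
    ann = io.read_annotation(SIM / "annotation.tsv")
    cov = io.read_covariates(SIM / "covariates.tsv")
    geno, meth, expr, cov = io.align_samples(geno, meth, expr, covariates=cov)

    layers = {
        "meqtl": ("snp", "cpg", geno, meth),
        "eqtm": ("cpg", "transcript", meth, expr),
        "eqtl": ("snp", "transcript", geno, expr),
    }
    results = {}
    for ptype, (pc, rc, pred, resp) in layers.items():
        res, summary = run_scan(
            pred, resp, ann[ann.feature_class == pc], ann[ann.feature_class == rc],
            cov, ScanConfig(ptype),
        )
        io.write_assoc_results(res, OUT / f"{ptype}.tsv")
        io.write_summary(summary, OUT / f"{ptype}.summary.tsv")
        results[ptype] = res
        print(f"{ptype}: {summary['n_tests']} cis tests, "
              f"{summary['n_significant']} significant pairs (FDR 5%), "
              f"{summary['n_unique_predictors']} unique predictors / "
              f"{summary['n_unique_responses']} unique responses")

    sig = significant_pairs(results["meqtl"])
    breakdown = category_breakdown(sig, ann, "cpg_island_category")
    print(f"meQTL CpG-region roll-up: {breakdown.rollup_count}/{breakdown.denominator} "
          f"pairs ({breakdown.rollup_percent}%); per category: {breakdown.percents}")
    profile = distance_profile(sig)
    profile["table"].to_csv(OUT / "meqtl.distance.tsv", sep="\t", index=False)
    print(f"fraction of significant meQTL pairs within 100 kb: "
          f"{profile['fraction_within_100kb']:.2f}")
    with open(OUT / "meqtl.characterize.json", "w") as fh:
        json.dump(
            {
                "island_percents": breakdown.percents,
                "cpg_region_rollup_percent": breakdown.rollup_percent,
                "fraction_within_100kb": profile["fraction_within_100kb"],
            },
            fh,
            indent=2,
        )
    plot_qq(results["meqtl"]["p_value"].to_numpy(), OUT / "meqtl.qq.png")
    plot_distance_hist(profile, OUT / "meqtl.distance.png")
    expected, observed = qq_data(results["meqtl"]["p_value"].to_numpy())
    print(f"QQ: top observed -log10 p = {observed[0]:.1f} vs expected {expected[0]:.1f} "
          "(planted signal lifts the tail off the diagonal)")


if __name__ == "__main__":
    main()
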