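"""Descriptive characterization of scan output and regulatory-network export.

Covers the standard post-scan summaries — CpG island/gene-region category
breakdowns of significant pairs, signed predictor-response distance
profiles, QQ data for p-value inflation diagnostics — and assembles the
signed tripartite SNP -> methylation -> mRNA network from significant
mediation trios, exportable as SIF, GraphML or an edge TSV (all readable
by Cytoscape).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("methmed.network")

#: island-relation categories that make up the aggregate "CpG region"
CPG_REGION_MEMBERS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf")


def percent(count: int, denominator: int) -> float:
    """Percentage rounded half-up to 2 decimals (report-style rounding)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    frac = Decimal(count) * 100 / Decimal(denominator)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class CategoryBreakdown:
    """Per-category counts and percents over a significant pair set."""

    attribute: str
    denominator: int
    counts: dict
    percents: dict
    rollup_count: int | None = None
    rollup_percent: float | None = None


def category_breakdown(
    sig_pairs: pd.DataFrame, annotation: pd.DataFrame, attribute: str
) -> CategoryBreakdown:
    """Count significant pairs per annotation category of their CpG member.

    ``attribute`` is ``cpg_island_category`` or ``gene_region_category``.
    The denominator is the total number of significant pairs. For island
    categories an aggregate "CpG region" roll-up (island + shores +
    shelves) is included.
    """
    if attribute not in ("cpg_island_category", "gene_region_category"):
        raise ValueError(f"unsupported attribute {attribute!r}")
    if attribute not in annotation.columns:
        raise ValueError(f"annotation lacks column {attribute!r}")
    lookup = (
        annotation[annotation["feature_class"] == "cpg"]
        .set_index("feature_id")[attribute]
    )
    # the CpG member may be predictor (eQTM) or response (meQTL)
    cats = sig_pairs["b_id"].map(lookup)
    if cats.isna().all():
        cats = sig_pairs["a_id"].map(lookup)
    denom = int(len(sig_pairs))
    counts = cats.value_counts().to_dict()
    percents = {c: percent(k, denom) for c, k in counts.items()} if denom else {}
    rollup_count = rollup_percent = None
    if attribute == "cpg_island_category" and denom:
        rollup_count = int(sum(counts.get(c, 0) for c in CPG_REGION_MEMBERS))
        rollup_percent = percent(rollup_count, denom)
    return CategoryBreakdown(
        attribute=attribute,
        denominator=denom,
        counts=counts,
        percents=percents,
        rollup_count=rollup_count,
        rollup_percent=rollup_percent,
    )


def distance_profile(
    sig_pairs: pd.DataFrame, window_bp: int = 1_000_000, bin_bp: int = 50_000
) -> dict:
    """Signed-distance histogram and significance-vs-distance table.

    Returns the histogram (bin edges partitioning exactly +-window), the
    per-pair (distance_bp, neg_log10_p) table, and the fraction of
    significant pairs within +-100 kb.
    """
    d = sig_pairs["distance_bp"].to_numpy(dtype=float)
    edges = np.arange(-window_bp, window_bp + bin_bp, bin_bp)
    hist, _ = np.histogram(d, bins=edges)
    with np.errstate(divide="ignore"):
        neg_log_p = -np.log10(
            np.maximum(sig_pairs["p_value"].to_numpy(dtype=float), np.finfo(float).tiny)
        )
    table = pd.DataFrame({"distance_bp": d.astype(int), "neg_log10_p": neg_log_p})
    frac_100kb = float(np.mean(np.abs(d) <= 100_000)) if len(d) else float("nan")
    return {
        "bin_edges": edges,
        "bin_counts": hist,
        "table": table,
        "fraction_within_100kb": frac_100kb,
    }


def qq_data(p_values) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed -log10 p for a QQ plot.

    Observed values are sorted descending; expected_i = -log10((i-0.5)/m)
    matches them rank for rank. Zero p-values are clamped to the smallest
    positive float with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (p == 0).any():
        warnings.warn("p-values of 0 clamped to the smallest positive float")
        p = np.maximum(p, np.finfo(float).tiny)
    m = len(p)
    observed = -np.log10(np.sort(p))  # ascending p = descending -log10
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    return expected, observed


def build_network(cit_results: pd.DataFrame, alpha: float = 0.05) -> nx.DiGraph:
    """Assemble the signed tripartite network from significant trios.

    Each trio with p_cit < alpha contributes a snp -> methylation edge
    signed by the meQTL slope and a methylation -> mrna edge signed by the
    eQTM slope; shared nodes merge. A duplicate edge observed with a
    conflicting sign keeps its first sign and is flagged
    ``sign_conflict``.
    """
    net = nx.DiGraph()
    if not len(cit_results):
        return net
    sig = cit_results[cit_results["p_cit"] < alpha]
    for _, trio in sig.iterrows():
        net.add_node(trio["snp_id"], kind="snp")
        net.add_node(trio["cpg_id"], kind="methylation")
        net.add_node(trio["gene_id"], kind="mrna", gene_symbol=trio.get("gene_symbol", ""))
        for src, dst, sign in (
            (trio["snp_id"], trio["cpg_id"], int(trio["sign_lg"])),
            (trio["cpg_id"], trio["gene_id"], int(trio["sign_gt"])),
        ):
            if net.has_edge(src, dst):
                if net.edges[src, dst]["sign"] != sign:
                    net.edges[src, dst]["sign_conflict"] = True
                    logger.warning("conflicting sign for edge %s -> %s", src, dst)
            else:
                net.add_edge(src, dst, sign=sign, p_cit=float(trio["p_cit"]), sign_conflict=False)
    return net


_SIGN_TOKEN = {1: "pos_reg", -1: "neg_reg", 0: "pos_reg"}


def export_network(net: nx.DiGraph, path, format: str = "sif") -> None:
    """Write the network as SIF, GraphML or an edge TSV (deterministic order)."""
    edges = sorted(net.edges(data=True))
    if format == "sif":
        with open(path, "w") as fh:
            for src, dst, attrs in edges:
                fh.write(f"{src}\t{_SIGN_TOKEN[attrs['sign']]}\t{dst}\n")
    elif format == "graphml":
        out = nx.DiGraph()
        for node in sorted(net.nodes):
            out.add_node(node, **net.nodes[node])
        for src, dst, attrs in edges:
            out.add_edge(src, dst, **attrs)
        nx.write_graphml(out, path)
    elif format == "edge_tsv":
        rows = [
            {
                "source": src,
                "target": dst,
                "sign": "+" if attrs["sign"] >= 0 else "-",
                "p_cit": attrs.get("p_cit", float("nan")),
            }
            for src, dst, attrs in edges
        ]
        pd.DataFrame(rows, columns=["source", "target", "sign", "p_cit"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def network_summary(net: nx.DiGraph) -> dict:
    """Node/edge counts by kind plus connected-component count."""
    kinds = nx.get_node_attributes(net, "kind")
    return {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "n_snps": sum(1 for k in kinds.values() if k == "snp"),
        "n_methylation": sum(1 for k in kinds.values() if k == "methylation"),
        "n_mrna": sum(1 for k in kinds.values() if k == "mrna"),
        "n_components": nx.number_weakly_connected_components(net)
        if net.number_of_nodes()
        else 0,
    }


def plot_qq(p_values, path) -> None:
    """Save a QQ plot of -log10 p-values (diagnostic figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    expected, observed = qq_data(p_values)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(expected, observed, ".", ms=3)
    lim = max(expected.max(), observed.max())
    ax.plot([0, lim], [0, lim], "r-", lw=1)
    ax.set_xlabel("expected -log10(p)")
    ax.set_ylabel("observed -log10(p)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_distance_hist(profile: dict, path) -> None:
    """Save the signed-distance histogram of significant pairs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges = profile["bin_edges"]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(edges[:-1] / 1e3, profile["bin_counts"], width=np.diff(edges) / 1e3, align="edge")
    ax.set_xlabel("predictor - response distance (kb)")
    ax.set_ylabel("significant pairs")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
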