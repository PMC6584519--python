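#!/usr/bin/env python
"""Export the signed SNP -> methylation -> mRNA regulatory network.

Every CIT-significant trio contributes a SNP->CpG edge signed by its
meQTL slope and a CpG->transcript edge signed by its eQTM slope; shared
nodes merge into connected components. Writes SIF, GraphML and edge-TSV
files (Cytoscape-ingestible) under results/network/.
"""

from pathlib import Path

import networkx as nx
import pandas as pd

from methmed.network import build_network, export_network, network_summary

ROOT = Path(__file__).resolve().parents[1] / "results"
CIT, OUT = ROOT / "cit", ROOT / "network"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cit = pd.read_csv(CIT / "cit_results.tsv", sep="\t")
    net = build_network(cit, alpha=0.05)
    for fmt, name in (("sif", "network.sif"), ("graphml", "network.graphml"),
                      ("edge_tsv", "network.edges.tsv")):
        export_network(net, OUT / name, format=fmt)
    s = network_summary(net)
    print(f"network: {s['n_nodes']} nodes ({s['n_snps']} SNPs, "
          f"{s['n_methylation']} methylation sites, {s['n_mrna']} mRNAs), "
          f"{s['n_edges']} signed edges, {s['n_components']} connected components")
    negative = sum(1 for _, _, a in net.edges(data=True) if a["sign"] < 0)
    print(f"{negative} negative-regulation edges of {s['n_edges']}")
    comps = sorted(nx.weakly_connected_components(net), key=len, reverse=True)
    if comps:
        kinds = nx.get_node_attributes(net, "kind")
        big = comps[0]
        n_snp = sum(1 for x in big if kinds[x] == "snp")
        print(f"largest component: {len(big)} nodes, {n_snp} SNPs — multiple SNPs "
              "converging on shared methylation sites and targets")


if __name__ == "__main__":
    main()
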