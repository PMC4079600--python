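#!/usr/bin/env python
"""Assemble the integrative signalling network and rank genes by betweenness.

Restricts the regulatory edge list to mutated SMP genes, computes
betweenness and clustering coefficients, forms nested top-k betweenness
groups, and contrasts each group against the zero-betweenness controls on
cancer-gene fraction, damaging fraction and conservation.
"""

import argparse
from pathlib import Path

import pandas as pd

from mutpath import (
    build_network,
    compute_centrality,
    group_enrichment,
    node_metrics_table,
    rank_groups,
)
from mutpath.annotations import read_gene_list
from mutpath.network import read_edges

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results-dir", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    edges = read_edges(args.results_dir / "data" / "edges.tsv")
    smp = read_gene_list(args.results_dir / "smp_genes.txt")

    network = build_network(edges, smp)
    compute_centrality(network)
    print(f"network: {len(network.nodes)} mutated genes, {network.n_edges} edges")

    groups = rank_groups(network)
    node_metrics_table(network, groups).to_csv(
        args.results_dir / "node_metrics.tsv", sep="\t", index=False
    )
    print(
        f"{len(network.nodes) - len(groups.controls)} genes with nonzero betweenness; "
        f"{len(groups.controls)} zero-betweenness controls"
    )

    annotations = pd.read_csv(
        args.results_dir / "gene_annotations.tsv", sep="\t", index_col="gene"
    )
    enrich = group_enrichment(groups, annotations.loc[sorted(network.nodes)])
    enrich.to_csv(args.results_dir / "group_enrichment.tsv", sep="\t", index=False)
    print("\ntop-k betweenness groups vs zero-betweenness controls:")
    print(
        enrich[["k", "n_group", "cancer_p", "damaging_p", "conservation_p"]]
        .to_string(index=False)
    )


if __name__ == "__main__":
    main()
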