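#!/usr/bin/env python
"""Identify significantly mutated pathways (SMPs).

Runs the coverage permutation test and the hypergeometric model over the
integrated profile, adjusts both with Benjamini-Hochberg, compares the two
methods' calls and mean sample coverage, and writes the SMP gene union for
the downstream network and gene-property analyses.
"""

import argparse
from pathlib import Path

from mutpath import (
    MutationProfile,
    mean_coverage,
    pathway_matrix,
    read_gmt,
    score_pathways,
    significant_pathways,
    smp_gene_union,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results-dir", type=Path, default=ROOT / "results")
    parser.add_argument("--n-sims", type=int, default=2000)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--fdr", type=float, default=0.05)
    args = parser.parse_args()

    profile = MutationProfile.read_tsv(args.results_dir / "profile.tsv")
    catalog = read_gmt(args.results_dir / "data" / "pathways.gmt")

    results = score_pathways(
        profile, catalog, n_sims=args.n_sims, seed=args.seed, fdr=args.fdr
    )
    results.to_csv(args.results_dir / "pathway_results.tsv", sep="\t", index=False)

    matrix = pathway_matrix(profile, catalog)
    sig_perm = significant_pathways(results.rename(columns={"q_perm": "q"}), args.fdr)
    sig_hyper = significant_pathways(results.rename(columns={"q_hyper": "q"}), args.fdr)
    both = set(sig_perm) & set(sig_hyper)

    print(f"coverage permutation: {len(sig_perm)} significant pathways at FDR {args.fdr}")
    print(f"hypergeometric model: {len(sig_hyper)} significant pathways")
    print(f"called by both methods: {len(both)}")
    if sig_perm:
        print(
            f"mean sample coverage of permutation SMPs: "
            f"{100 * mean_coverage(sig_perm, matrix):.1f}%"
        )
    if sig_hyper:
        print(
            f"mean sample coverage of hypergeometric SMPs: "
            f"{100 * mean_coverage(sig_hyper, matrix):.1f}%"
        )

    smp = smp_gene_union(catalog, sig_perm, profile)
    (args.results_dir / "smp_genes.txt").write_text("\n".join(sorted(smp)) + "\n")
    non_smp = profile.mutated_genes() - smp
    (args.results_dir / "non_smp_genes.txt").write_text(
        "\n".join(sorted(non_smp)) + "\n"
    )
    print(
        f"{len(smp)} mutated genes in SMPs vs {len(non_smp)} outside "
        f"-> smp_genes.txt / non_smp_genes.txt"
    )


if __name__ == "__main__":
    main()
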