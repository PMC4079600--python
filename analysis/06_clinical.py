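#!/usr/bin/env python
"""Screen mutation status against clinical features and overall survival.

Gene-level units are the recurrently mutated genes; pathway-level units
are the significantly mutated pathways (permutation test).  Binary
features use the chi-square(Yates)/Fisher selection rule; survival uses
the log-rank test with a univariate Cox hazard ratio and Kaplan-Meier
medians per arm.
"""

import argparse
from pathlib import Path

import pandas as pd

from mutpath import (
    ClinicalTable,
    MutationProfile,
    association_screen,
    pathway_matrix,
    pathway_status,
    read_gmt,
    recurrent_genes,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results-dir", type=Path, default=ROOT / "results")
    parser.add_argument("--min-samples", type=int, default=10)
    parser.add_argument("--alpha", type=float, default=0.05)
    parser.add_argument("--survival-alpha", type=float, default=0.1)
    args = parser.parse_args()

    profile = MutationProfile.read_tsv(args.results_dir / "profile.tsv")
    clinical = ClinicalTable.read_tsv(args.results_dir / "data" / "clinical.tsv")
    clinical = ClinicalTable(clinical.data.loc[profile.sample_labels])

    gi = profile.gene_index()
    gene_units = {
        g: profile.X[gi[g]].astype(bool)
        for g, _ in recurrent_genes(profile, args.min_samples)
    }
    gene_screen = association_screen(
        gene_units, clinical, alpha=args.alpha, survival_alpha=args.survival_alpha
    )
    gene_screen.to_csv(args.results_dir / "gene_associations.tsv", sep="\t", index=False)

    results = pd.read_csv(args.results_dir / "pathway_results.tsv", sep="\t")
    sig = results[results["significant_perm"]]["pathway_id"].tolist()
    catalog = read_gmt(args.results_dir / "data" / "pathways.gmt")
    matrix = pathway_matrix(profile, catalog)
    pathway_units = {pid: pathway_status(matrix, pid) for pid in sig}
    pathway_screen = association_screen(
        pathway_units, clinical, alpha=args.alpha, survival_alpha=args.survival_alpha
    )
    pathway_screen.to_csv(
        args.results_dir / "pathway_associations.tsv", sep="\t", index=False
    )

    for label, screen in [("gene", gene_screen), ("pathway", pathway_screen)]:
        hits = screen[screen["significant"]]
        print(
            f"{label}-level: {len(hits)}/{len(screen)} associations flagged "
            f"(alpha={args.alpha}, survival alpha={args.survival_alpha})"
        )
        for _, row in hits.iterrows():
            if row["feature"] == "overall_survival":
                print(
                    f"  {row['unit_id']} x survival: p={row['p']:.3g}, "
                    f"HR={row['hazard_ratio']:.2f}, median OS "
                    f"{row['median_os_mutated']:.0f} vs {row['median_os_unmutated']:.0f} months"
                )
            else:
                print(
                    f"  {row['unit_id']} x {row['feature']}: "
                    f"{100 * row['rate_positive']:.0f}% vs {100 * row['rate_negative']:.0f}% "
                    f"({row['test_used']}, p={row['p']:.3g})"
                )


if __name__ == "__main__":
    main()
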