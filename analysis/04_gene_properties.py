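#!/usr/bin/env python
"""Contrast SMP-gene properties against the remaining mutated genes.

Derives per-gene damaging flags and mean conservation scores from the
variant calls, joins the known-cancer list, and tests whether genes inside
significantly mutated pathways are enriched for cancer genes and damaging
mutations and carry higher conservation.
"""

import argparse
from pathlib import Path

from mutpath import (
    annotate_genes,
    compare_proportions,
    filter_functional,
    read_variant_table,
    t_test,
)
from mutpath.annotations import read_gene_list

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results-dir", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    data = args.results_dir / "data"
    records = []
    for path in sorted(data.glob("variants_*.tsv")):
        cid = path.stem.removeprefix("variants_")
        records += filter_functional(read_variant_table(path, cohort_id=cid))

    smp = read_gene_list(args.results_dir / "smp_genes.txt")
    non_smp = read_gene_list(args.results_dir / "non_smp_genes.txt")
    cancer = read_gene_list(data / "cancer_genes.txt")

    annotations = annotate_genes(smp | non_smp, records, cancer)
    annotations.to_csv(args.results_dir / "gene_annotations.tsv", sep="\t")

    rows = []
    for flag, label in [
        ("is_known_cancer", "known cancer genes"),
        ("is_damaging", "damaging genes"),
    ]:
        p, r_smp, r_non = compare_proportions(smp, non_smp, annotations[flag].to_dict())
        rows.append((flag, p, r_smp, r_non))
        print(
            f"{label}: {100 * r_smp:.1f}% in SMP vs {100 * r_non:.1f}% outside "
            f"(Fisher p = {p:.3g})"
        )

    cons = annotations["conservation"]
    cons_smp = cons.loc[sorted(smp)].dropna()
    cons_non = cons.loc[sorted(non_smp)].dropna()
    p = t_test(cons_smp.to_numpy(), cons_non.to_numpy())
    rows.append(("conservation", p, cons_smp.mean(), cons_non.mean()))
    print(
        f"conservation: mean {cons_smp.mean():.2f} in SMP vs {cons_non.mean():.2f} "
        f"outside (t-test p = {p:.3g})"
    )

    import pandas as pd

    pd.DataFrame(
        rows, columns=["property", "p", "smp_value", "non_smp_value"]
    ).to_csv(args.results_dir / "smp_comparison.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
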