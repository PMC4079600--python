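#!/usr/bin/env python
"""Build per-cohort binary mutation profiles and integrate them.

Reads the variant tables written by 01_simulate.py, applies the
functional-mutation filter (drops synonymous/noncoding calls), builds one
binary gene x sample profile per cohort, pools them, and summarises the
pairwise overlap of the cohorts' mutated-gene sets — the classic
small-vs-large cohort comparison.
"""

import argparse
from pathlib import Path

import pandas as pd

from mutpath import (
    build_profile,
    filter_functional,
    integrate,
    overlap,
    read_variant_table,
    recurrent_genes,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results")
    parser.add_argument("--min-recurrent", type=int, default=10)
    args = parser.parse_args()

    variant_files = sorted(args.data_dir.glob("variants_*.tsv"))
    profiles = {}
    for path in variant_files:
        cohort_id = path.stem.removeprefix("variants_")
        records = filter_functional(read_variant_table(path, cohort_id=cohort_id))
        profiles[cohort_id] = build_profile(records)
        print(
            f"{cohort_id}: {profiles[cohort_id].n_genes} mutated genes "
            f"in {profiles[cohort_id].n_samples} mutated samples"
        )

    merged = integrate(list(profiles.values()))
    merged.write_tsv(args.out_dir / "profile.tsv")
    print(
        f"integrated profile: {merged.n_genes} genes x {merged.n_samples} samples "
        f"-> {args.out_dir / 'profile.tsv'}"
    )

    # pairwise overlap of mutated-gene sets, as overlap/longer (upper) and
    # overlap/shorter (lower) fractions
    ids = list(profiles)
    table = pd.DataFrame(index=ids, columns=ids, dtype=object)
    for i, a in enumerate(ids):
        table.loc[a, a] = profiles[a].n_genes
        for b in ids[i + 1 :]:
            st = overlap(profiles[a].mutated_genes(), profiles[b].mutated_genes())
            table.loc[a, b] = round(st.frac_of_longer, 2)
            table.loc[b, a] = round(st.frac_of_shorter, 2)
    table.index.name = "cohort"
    table.to_csv(args.out_dir / "cohort_gene_overlap.tsv", sep="\t")
    print("\nmutated-gene overlap (diagonal = set size; above diag = /longer, below = /shorter):")
    print(table.to_string())

    rec = recurrent_genes(merged, args.min_recurrent)
    pd.DataFrame(rec, columns=["gene", "n_samples"]).to_csv(
        args.out_dir / "recurrent_genes.tsv", sep="\t", index=False
    )
    print(
        f"\n{len(rec)} genes mutated in >= {args.min_recurrent} samples "
        f"-> {args.out_dir / 'recurrent_genes.tsv'}"
    )


if __name__ == "__main__":
    main()
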