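"""End-to-end orchestration: profile → pathway tests → gene properties →
network ranking → clinical associations.

The analysis drivers, the command-line interface and the reproducibility
checks all run through :func:`run_pipeline`, so the full chain of
computation is a single importable call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotations as ann
from . import clinical as clin
from . import network as net
from . import pathways as pw
from .simulate import SyntheticDataset
from .variants import MutationProfile, filter_functional, recurrent_genes


@dataclass
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    profile: MutationProfile
    pathway_results: pd.DataFrame
    pathway_mat: pw.PathwayMutationMatrix
    significant_perm: list[str]
    significant_hyper: list[str]
    smp_genes: set[str]
    non_smp_genes: set[str]
    gene_annotations: pd.DataFrame
    smp_comparison: pd.DataFrame
    network: net.SignalingNetwork
    groups: net.CentralityGroups
    node_metrics: pd.DataFrame
    group_enrichment: pd.DataFrame
    gene_screen: pd.DataFrame
    pathway_screen: pd.DataFrame


def run_pipeline(
    dataset: SyntheticDataset,
    n_sims: int = 10_000,
    seed: int | None = None,
    fdr: float = 0.05,
    alpha: float = 0.05,
    survival_alpha: float = 0.1,
    recurrent_min: int = 10,
    pseudocount: bool = False,
    include_splice: bool = False,
) -> PipelineResult:
    """Run every analysis stage on a (synthetic or loaded) dataset.

    ``seed`` drives only the coverage permutation null; every other stage
    is deterministic.  Gene-level clinical screening uses recurrently
    mutated genes (>= ``recurrent_min`` samples); pathway-level screening
    uses the significantly mutated pathways from the permutation test.
    """
    profile = dataset.profile
    all_records = [r for recs in dataset.cohorts.values() for r in recs]
    functional = filter_functional(all_records, include_splice=include_splice)

    # pathway significance (both tests, BH-adjusted)
    results = pw.score_pathways(
        profile,
        dataset.catalog,
        n_sims=n_sims,
        seed=seed,
        fdr=fdr,
        pseudocount=pseudocount,
    )
    sig_perm = pw.significant_pathways(
        results.rename(columns={"q_perm": "q"}), fdr=fdr
    )
    sig_hyper = pw.significant_pathways(
        results.rename(columns={"q_hyper": "q"}), fdr=fdr
    )
    matrix = pw.pathway_matrix(profile, dataset.catalog)

    # gene-property contrasts: SMP vs non-SMP mutated genes
    smp_genes = pw.smp_gene_union(dataset.catalog, sig_perm, profile)
    non_smp = profile.mutated_genes() - smp_genes
    annotations = ann.annotate_genes(
        profile.mutated_genes(), functional, dataset.truth.cancer_genes
    )
    smp_comparison = _smp_comparison(smp_genes, non_smp, annotations)

    # signalling network over SMP mutated genes
    network = net.build_network(dataset.edges, smp_genes)
    net.compute_centrality(network)
    groups = net.rank_groups(network)
    node_metrics = net.node_metrics_table(network, groups)
    if groups.controls and any(groups.groups.values()):
        enrichment = net.group_enrichment(
            groups, annotations.loc[sorted(network.nodes)]
        )
    else:
        enrichment = pd.DataFrame()

    # clinical associations: recurrent genes and significant pathways
    sample_order = profile.sample_labels
    clin_table = clin.ClinicalTable(
        dataset.clinical.data.drop(columns=["_carrier"], errors="ignore").loc[
            sample_order
        ]
    )
    gi = profile.gene_index()
    gene_units = {
        g: profile.X[gi[g]].astype(bool)
        for g, _ in recurrent_genes(profile, recurrent_min)
    }
    gene_screen = clin.association_screen(
        gene_units, clin_table, alpha=alpha, survival_alpha=survival_alpha
    )
    pathway_units = {
        pid: clin.pathway_status(matrix, pid) for pid in sig_perm
    }
    pathway_screen = clin.association_screen(
        pathway_units, clin_table, alpha=alpha, survival_alpha=survival_alpha
    )

    return PipelineResult(
        profile=profile,
        pathway_results=results,
        pathway_mat=matrix,
        significant_perm=sig_perm,
        significant_hyper=sig_hyper,
        smp_genes=smp_genes,
        non_smp_genes=non_smp,
        gene_annotations=annotations,
        smp_comparison=smp_comparison,
        network=network,
        groups=groups,
        node_metrics=node_metrics,
        group_enrichment=enrichment,
        gene_screen=gene_screen,
        pathway_screen=pathway_screen,
    )


def _smp_comparison(
    smp_genes: set[str], non_smp: set[str], annotations: pd.DataFrame
) -> pd.DataFrame:
    """Known-cancer / damaging / conservation contrasts of SMP vs non-SMP."""
    if not smp_genes or not non_smp:
        return pd.DataFrame()
    rows = []
    for flag in ("is_known_cancer", "is_damaging"):
        p, rate_a, rate_b = ann.compare_proportions(
            smp_genes, non_smp, annotations[flag].to_dict()
        )
        rows.append(
            {
                "property": flag,
                "test": "fisher",
                "p": p,
                "smp_value": rate_a,
                "non_smp_value": rate_b,
            }
        )
    cons = annotations["conservation"]
    cons_smp = cons.loc[sorted(smp_genes)].dropna()
    cons_non = cons.loc[sorted(non_smp)].dropna()
    if len(cons_smp) >= 2 and len(cons_non) >= 2:
        rows.append(
            {
                "property": "conservation",
                "test": "t",
                "p": ann.t_test(cons_smp.to_numpy(), cons_non.to_numpy()),
                "smp_value": float(cons_smp.mean()),
                "non_smp_value": float(cons_non.mean()),
            }
        )
    return pd.DataFrame(rows)


def write_results(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write the standard result TSVs; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    def _save(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index)
        paths.append(path)

    result.profile.write_tsv(out / "profile.tsv")
    paths.append(out / "profile.tsv")
    _save(result.pathway_results, "pathway_results.tsv")
    _save(result.smp_comparison, "smp_comparison.tsv")
    _save(result.node_metrics, "node_metrics.tsv")
    _save(result.group_enrichment, "group_enrichment.tsv")
    _save(result.gene_screen, "gene_associations.tsv")
    _save(result.pathway_screen, "pathway_associations.tsv")
    return paths
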