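"""Signal-transduction network assembly and betweenness-based gene ranking.

Regulatory edges harvested from pathway diagrams are restricted to the
mutated genes of significantly mutated pathways, giving an integrative
directed network.  Genes are ranked by (unnormalised) shortest-path
betweenness; genes with zero betweenness serve as the control group
against which nested top-k groups are contrasted on annotation enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import annotations as ann

#: Named regulatory relation types; ``other`` absorbs unlisted types.
RELATION_TYPES = (
    "activation",
    "inhibition",
    "expression",
    "repression",
    "phosphorylation",
    "dephosphorylation",
    "methylation",
    "ubiquitination",
    "other",
)


@dataclass(frozen=True)
class RegulatoryEdge:
    source: str
    target: str
    relation: str
    pathway_id: str = ""

    def __post_init__(self) -> None:
        if self.relation not in RELATION_TYPES:
            raise ValueError(f"unknown relation type: {self.relation!r}")


def read_edges(path: str | Path) -> list[RegulatoryEdge]:
    """Edge-list TSV with columns source, target, relation, pathway_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source", "target", "relation"):
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    pid = df["pathway_id"] if "pathway_id" in df.columns else [""] * len(df)
    return [
        RegulatoryEdge(s, t, r if r in RELATION_TYPES else "other", p or "")
        for s, t, r, p in zip(df["source"], df["target"], df["relation"], pid)
    ]


def write_edges(edges: Sequence[RegulatoryEdge], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "source": e.source,
                "target": e.target,
                "relation": e.relation,
                "pathway_id": e.pathway_id,
            }
            for e in edges
        ]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class SignalingNetwork:
    """Directed network over a restricted gene set with node centralities.

    ``graph`` is a simple DiGraph; parallel regulatory edges between the
    same ordered pair are collapsed, with the relation multiset kept as the
    edge attribute ``relations``.
    """

    graph: nx.DiGraph
    betweenness: dict[str, float] = field(default_factory=dict)
    clustering: dict[str, float] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    edges: Iterable[RegulatoryEdge], restrict_to: Iterable[str]
) -> SignalingNetwork:
    """Induce the network on ``restrict_to``.

    Edges with either endpoint outside the restriction set are dropped, as
    are self-loops; duplicate ordered pairs collapse into one edge carrying
    the multiset of relations.  Genes left without any surviving edge do
    not become nodes.
    """
    allowed = set(restrict_to)
    g = nx.DiGraph()
    for e in edges:
        if e.source == e.target:
            continue
        if e.source not in allowed or e.target not in allowed:
            continue
        if g.has_edge(e.source, e.target):
            g[e.source][e.target]["relations"].append(e.relation)
        else:
            g.add_edge(e.source, e.target, relations=[e.relation])
    return SignalingNetwork(graph=g)


def compute_centrality(
    network: SignalingNetwork, directed: bool = True
) -> SignalingNetwork:
    """Fill in per-node betweenness and clustering coefficients.

    Betweenness is unnormalised shortest-path betweenness on the directed
    graph (raw pair counts; normalisation would not change the ranking).
    The clustering coefficient is computed on the undirected projection.
    ``directed=False`` computes betweenness on the projection instead.
    """
    g = network.graph if directed else network.graph.to_undirected()
    network.betweenness = {
        n: float(b) for n, b in nx.betweenness_centrality(g, normalized=False).items()
    }
    network.clustering = {
        n: float(c) for n, c in nx.clustering(network.graph.to_undirected()).items()
    }
    return network


@dataclass
class CentralityGroups:
    """Nested top-k betweenness groups and the zero-betweenness controls."""

    groups: dict[int, list[str]]
    controls: set[str]


def rank_groups(
    network: SignalingNetwork, ks: Sequence[int] = (50, 100, 150, 200, 250)
) -> CentralityGroups:
    """Form nested top-k groups by betweenness; zero-betweenness = control.

    Sorting is by betweenness descending, ties broken by total degree
    descending then lexicographically, so the ranking is deterministic.
    Controls never enter a group: when k exceeds the number of
    nonzero-betweenness genes the group truncates.
    """
    if list(ks) != sorted(ks):
        raise ValueError("ks must be ascending")
    if not network.betweenness:
        raise ValueError("call compute_centrality first")
    btw = network.betweenness
    deg = dict(network.graph.degree())
    ranked = sorted(btw, key=lambda g: (-btw[g], -deg.get(g, 0), g))
    nonzero = [g for g in ranked if btw[g] > 0]
    controls = {g for g in ranked if btw[g] == 0}
    groups = {k: nonzero[:k] for k in ks}
    return CentralityGroups(groups=groups, controls=controls)


def group_enrichment(
    groups: CentralityGroups, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Contrast each top-k group against the controls on three annotations.

    Fisher exact p for the known-cancer and damaging fractions; Student
    t-test p for conservation (genes without a conservation score are
    dropped from that comparison only).  ``annotations`` is indexed by gene
    with columns ``is_known_cancer``, ``is_damaging``, ``conservation`` and
    must cover every network gene.  Empty groups are omitted with a
    warning; empty controls are an error.
    """
    if not groups.controls:
        raise ValueError("no control (zero-betweenness) genes")
    controls = sorted(groups.controls)
    missing = (set(controls) | set().union(*map(set, groups.groups.values()))) - set(
        annotations.index
    )
    if missing:
        raise ValueError(f"annotations missing for {len(missing)} network genes")
    cancer = annotations["is_known_cancer"].to_dict()
    damaging = annotations["is_damaging"].to_dict()
    cons = annotations["conservation"]

    rows = []
    for k, group in groups.groups.items():
        if not group:
            warnings.warn(f"top-{k} group is empty; row omitted", stacklevel=2)
            continue
        p_cancer, rc_g, rc_c = ann.compare_proportions(group, controls, cancer)
        p_dam, rd_g, rd_c = ann.compare_proportions(group, controls, damaging)
        cons_g = cons.loc[list(group)].dropna()
        cons_c = cons.loc[controls].dropna()
        try:
            p_cons = ann.t_test(cons_g.to_numpy(), cons_c.to_numpy())
        except ValueError as exc:
            warnings.warn(f"top-{k} conservation t-test skipped: {exc}", stacklevel=2)
            p_cons = np.nan
        rows.append(
            {
                "k": k,
                "n_group": len(group),
                "cancer_p": p_cancer,
                "cancer_rate_group": rc_g,
                "cancer_rate_control": rc_c,
                "damaging_p": p_dam,
                "damaging_rate_group": rd_g,
                "damaging_rate_control": rd_c,
                "conservation_p": p_cons,
            }
        )
    return pd.DataFrame(rows)


def node_metrics_table(
    network: SignalingNetwork, groups: CentralityGroups | None = None
) -> pd.DataFrame:
    """Per-gene metrics table: betweenness, clustering, rank, group flags."""
    btw = network.betweenness
    deg = dict(network.graph.degree())
    ranked = sorted(btw, key=lambda g: (-btw[g], -deg.get(g, 0), g))
    df = pd.DataFrame(
        {
            "gene": ranked,
            "betweenness": [btw[g] for g in ranked],
            "clustering": [network.clustering.get(g, np.nan) for g in ranked],
            "degree": [deg.get(g, 0) for g in ranked],
            "rank": np.arange(1, len(ranked) + 1),
        }
    )
    if groups is not None:
        df["is_control"] = df["gene"].isin(groups.controls)
        smallest = {}
        for k in sorted(groups.groups, reverse=True):
            for g in groups.groups[k]:
                smallest[g] = k
        df["group"] = df["gene"].map(smallest).astype("Int64")
    return df
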