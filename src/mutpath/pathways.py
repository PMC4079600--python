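"""Pathway-level mutation significance: coverage permutation test and
hypergeometric enrichment, with Benjamini–Hochberg FDR control.

Two complementary definitions of a significantly mutated pathway (SMP) are
implemented:

* **Coverage permutation test** — a pathway with *v* genes covering *k* of
  the tumor samples (a sample is covered if it mutates at least one pathway
  gene) is compared against an empirical null in which *v* genes are drawn
  uniformly without replacement from a gene universe; the p-value is the
  fraction of draws whose coverage Z reaches at least *k*.  This conditions
  on pathway size, since larger gene sets trivially cover more samples.

* **Hypergeometric model** — a pathway with *M* annotated genes of which
  *k* are mutated is scored by the upper-tail probability of drawing at
  least *k* mutated genes when the *n* mutated genes in the pathway
  universe are allocated at random among all *N* genes.

Both p-value lists are adjusted with the Benjamini–Hochberg step-up
procedure and thresholded at a strict q < FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .variants import MutationProfile

#: The five adopted pathway classes (disease/drug catalogues, being
#: assembled meta-pathways, are excluded upstream).
PATHWAY_CLASSES = (
    "metabolism",
    "genetic information processing",
    "environmental information processing",
    "cellular processes",
    "organismal systems",
)


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    klass: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.klass not in PATHWAY_CLASSES:
            raise ValueError(f"unknown pathway class: {self.klass!r}")
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id} has an empty gene set")


@dataclass
class PathwayCatalog:
    """Named gene sets with class labels."""

    pathways: list[Pathway]

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pathway ids")
        self._by_id = {p.pathway_id: p for p in self.pathways}

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self._by_id[pathway_id]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.genes
        return out


def read_gmt(path: str | Path) -> PathwayCatalog:
    """Read a GMT catalogue; the description field carries ``class=<name>``.

    Lines are ``pathway_id<TAB>description<TAB>gene1<TAB>gene2...``; the
    description is ``name|class=<class>`` (a bare ``class=...`` leaves the
    name equal to the id).
    """
    pathways = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            pid, desc, genes = fields[0], fields[1], fields[2:]
            name, klass = pid, None
            for part in desc.split("|"):
                if part.startswith("class="):
                    klass = part[len("class=") :]
                elif part:
                    name = part
            if klass is None:
                raise ValueError(f"pathway {pid}: description lacks class=<name>")
            pathways.append(Pathway(pid, name, klass, frozenset(genes)))
    return PathwayCatalog(pathways)


def write_gmt(catalog: PathwayCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in catalog:
            desc = f"{p.name}|class={p.klass}"
            fh.write("\t".join([p.pathway_id, desc, *sorted(p.genes)]) + "\n")


@dataclass
class PathwayMutationMatrix:
    """Binary pathway × sample coverage matrix Y.

    ``Y[i, j] = 1`` iff sample *j* carries a mutation in at least one gene
    of pathway *i*.
    """

    pathway_ids: list[str]
    samples: list
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.int8)
        if self.Y.shape != (len(self.pathway_ids), len(self.samples)):
            raise ValueError("Y shape does not match labels")
        self._idx = {p: i for i, p in enumerate(self.pathway_ids)}

    def row(self, pathway_id: str) -> np.ndarray:
        if pathway_id not in self._idx:
            raise KeyError(f"unknown pathway: {pathway_id}")
        return self.Y[self._idx[pathway_id]]

    def coverage(self) -> pd.Series:
        """Fraction of samples covered, per pathway."""
        return pd.Series(
            self.Y.mean(axis=1), index=self.pathway_ids, name="coverage"
        )


def pathway_matrix(
    profile: MutationProfile, catalog: PathwayCatalog
) -> PathwayMutationMatrix:
    """Project a gene-level mutation profile to pathway-level coverage.

    Pathway genes absent from the profile contribute nothing (they were not
    observed mutated in any sample).
    """
    gi = profile.gene_index()
    Y = np.zeros((len(catalog), profile.n_samples), dtype=np.int8)
    for i, p in enumerate(catalog):
        rows = [gi[g] for g in p.genes if g in gi]
        if rows:
            Y[i] = profile.X[rows].any(axis=0)
    return PathwayMutationMatrix(
        [p.pathway_id for p in catalog], list(profile.samples), Y
    )


@dataclass(frozen=True)
class CoverageTestResult:
    pathway_id: str
    v: int
    k: int
    coverage: float
    p_perm: float
    n_sims: int
    seed: int | None = None
    q: float | None = None


@dataclass(frozen=True)
class HypergeomTestResult:
    pathway_id: str
    M: int
    k: int
    N: int
    n: int
    p: float
    q: float | None = None


class PermutationEngine:
    """Vectorised empirical null for pathway sample-coverage.

    The profile is reduced to a bit-packed boolean matrix over the gene
    universe (genes outside the profile are all-zero rows).  A null draw of
    *v* genes is scored by OR-ing its packed rows and popcounting, giving
    the number of covered samples per draw without materialising the full
    boolean cube.
    """

    def __init__(self, profile: MutationProfile, universe: Iterable[str]):
        self.universe = sorted(set(universe))
        missing = set(profile.genes) - set(self.universe)
        if missing:
            raise ValueError(
                f"universe must contain every profile gene; missing {len(missing)}"
            )
        self._uidx = {g: i for i, g in enumerate(self.universe)}
        self.n_samples = profile.n_samples
        bits = np.zeros((len(self.universe), profile.n_samples), dtype=np.uint8)
        gi = profile.gene_index()
        for g, i in self._uidx.items():
            if g in gi:
                bits[i] = profile.X[gi[g]]
        self._packed = np.packbits(bits, axis=1)
        self._mutated = bits.any(axis=1)

    @property
    def size(self) -> int:
        return len(self.universe)

    def observed_coverage(self, genes: Iterable[str]) -> int:
        """Number of samples covered by the given gene set (k)."""
        rows = [self._uidx[g] for g in genes if g in self._uidx]
        if not rows:
            return 0
        merged = np.bitwise_or.reduce(self._packed[rows], axis=0)
        return int(np.bitwise_count(merged).sum())

    def null_coverages(
        self, v: int, n_sims: int, rng: np.random.Generator, batch: int = 512
    ) -> np.ndarray:
        """Coverage Z of ``n_sims`` uniform draws of ``v`` universe genes."""
        if v > self.size:
            raise ValueError(f"pathway size {v} exceeds universe size {self.size}")
        if n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        out = np.empty(n_sims, dtype=np.int64)
        done = 0
        while done < n_sims:
            b = min(batch, n_sims - done)
            # uniform v-subsets via random-key partial sort
            keys = rng.random((b, self.size))
            idx = np.argpartition(keys, v - 1, axis=1)[:, :v]
            merged = np.bitwise_or.reduce(self._packed[idx], axis=1)
            out[done : done + b] = np.bitwise_count(merged).sum(axis=1)
            done += b
        return out


def coverage_permutation_test(
    profile: MutationProfile,
    pathway_genes: Iterable[str],
    universe: Iterable[str],
    n_sims: int = 10_000,
    seed: int | np.random.Generator | None = None,
    pseudocount: bool = False,
    pathway_id: str = "",
    engine: PermutationEngine | None = None,
) -> CoverageTestResult:
    """Empirical significance of a pathway's sample coverage.

    Draws ``n_sims`` gene sets of the pathway's size uniformly without
    replacement from ``universe`` and computes each draw's sample coverage
    against the profile; ``p = #{Z >= k} / n_sims`` (or ``(c+1)/(n+1)``
    with ``pseudocount=True``, which avoids exact zeros).  Reproducible for
    a fixed integer seed.
    """
    genes = set(pathway_genes)
    if not genes:
        raise ValueError("empty pathway gene set")
    if engine is None:
        engine = PermutationEngine(profile, universe)
    if not genes <= set(engine.universe):
        raise ValueError("pathway genes must be harmonised into the universe")
    v = len(genes)
    k = engine.observed_coverage(genes)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    z = engine.null_coverages(v, n_sims, rng)
    hits = int((z >= k).sum())
    p = (hits + 1) / (n_sims + 1) if pseudocount else hits / n_sims
    return CoverageTestResult(
        pathway_id=pathway_id,
        v=v,
        k=k,
        coverage=k / engine.n_samples,
        p_perm=float(p),
        n_sims=n_sims,
        seed=seed if isinstance(seed, int) else None,
    )


def hypergeometric_test(M: int, k: int, N: int, n: int) -> float:
    """Upper-tail inclusive hypergeometric probability P(K >= k).

    Of ``N`` genes, ``M`` belong to the pathway; ``n`` genes are mutated.
    Returns the probability that a uniform allocation places at least ``k``
    mutated genes inside the pathway.  Evaluated via the survival function
    of the hypergeometric distribution (stable log-space internals).
    """
    if not (0 <= k <= min(M, n)) or M > N or n > N or min(M, k, N, n) < 0:
        raise ValueError(f"inconsistent counts M={M}, k={k}, N={N}, n={n}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, M, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_pathways(results: pd.DataFrame, fdr: float = 0.05) -> list[str]:
    """Pathway ids with q strictly below ``fdr``.

    Ordered by q ascending, ties broken by coverage descending then id.
    Expects columns ``pathway_id``, ``q`` and ``coverage``.
    """
    hits = results[results["q"] < fdr].copy()
    hits = hits.sort_values(
        ["q", "coverage", "pathway_id"], ascending=[True, False, True]
    )
    return hits["pathway_id"].tolist()


def mean_coverage(
    pathway_ids: Sequence[str], matrix: PathwayMutationMatrix
) -> float:
    """Unweighted mean coverage fraction over the given pathways."""
    if len(pathway_ids) == 0:
        raise ValueError("mean_coverage of an empty pathway list")
    cov = matrix.coverage()
    return float(cov.loc[list(pathway_ids)].mean())


def smp_gene_union(
    catalog: PathwayCatalog,
    significant_ids: Sequence[str],
    profile: MutationProfile,
) -> set[str]:
    """Mutated genes belonging to at least one significant pathway.

    The complement (mutated genes in no significant pathway) is simply
    ``profile.mutated_genes() - smp_gene_union(...)``.
    """
    mutated = profile.mutated_genes()
    union: set[str] = set()
    for pid in significant_ids:
        union |= catalog[pid].genes
    return union & mutated


def score_pathways(
    profile: MutationProfile,
    catalog: PathwayCatalog,
    universe: Iterable[str] | None = None,
    n_sims: int = 10_000,
    seed: int | None = None,
    fdr: float = 0.05,
    pseudocount: bool = False,
) -> pd.DataFrame:
    """Run both SMP tests over a catalogue and BH-adjust each p-value list.

    A single seeded generator is shared across pathways in catalogue order,
    so results are reproducible but depend on that order.  The default
    permutation universe is the union of catalogue and profile genes (the
    choice changes the null and is overridable).

    Returns one row per pathway with columns ``pathway_id, name, class, v,
    k, coverage, p_perm, q_perm, M, k_genes, p_hyper, q_hyper,
    significant_perm, significant_hyper``.
    """
    if universe is None:
        universe_set = catalog.all_genes() | set(profile.genes)
    else:
        universe_set = set(universe) | set(profile.genes)
    engine = PermutationEngine(profile, universe_set)
    rng = np.random.default_rng(seed)

    mutated = profile.mutated_genes()
    catalog_genes = catalog.all_genes()
    N = len(universe_set)
    n_mut = len(mutated & catalog_genes)

    rows = []
    for p in catalog:
        cov = coverage_permutation_test(
            profile,
            p.genes,
            universe_set,
            n_sims=n_sims,
            seed=rng,
            pseudocount=pseudocount,
            pathway_id=p.pathway_id,
            engine=engine,
        )
        M = len(p.genes)
        k_genes = len(p.genes & mutated)
        p_hyper = hypergeometric_test(M, k_genes, N, n_mut)
        rows.append(
            {
                "pathway_id": p.pathway_id,
                "name": p.name,
                "class": p.klass,
                "v": cov.v,
                "k": cov.k,
                "coverage": cov.coverage,
                "p_perm": cov.p_perm,
                "M": M,
                "k_genes": k_genes,
                "p_hyper": p_hyper,
            }
        )
    df = pd.DataFrame(rows)
    df["q_perm"] = bh_adjust(df["p_perm"])
    df["q_hyper"] = bh_adjust(df["p_hyper"])
    df["significant_perm"] = df["q_perm"] < fdr
    df["significant_hyper"] = df["q_hyper"] < fdr
    return df[
        [
            "pathway_id",
            "name",
            "class",
            "v",
            "k",
            "coverage",
            "p_perm",
            "q_perm",
            "M",
            "k_genes",
            "p_hyper",
            "q_hyper",
            "significant_perm",
            "significant_hyper",
        ]
    ]
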