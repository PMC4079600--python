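"""Pathway significance: coverage permutation, hypergeometric, BH, SMP sets.

The oracles here are independent of the implementation: exhaustive subset
enumeration for the permutation null, combinatorial enumeration for the
hypergeometric tail, and a direct step-up computation for BH.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mutpath import (
    MutationProfile,
    Pathway,
    PathwayCatalog,
    bh_adjust,
    coverage_permutation_test,
    hypergeometric_test,
    mean_coverage,
    pathway_matrix,
    read_gmt,
    significant_pathways,
    smp_gene_union,
    score_pathways,
    write_gmt,
)


def exact_coverage_tail(profile, universe, v, k):
    """P(Z >= k) by enumerating every v-subset of the universe."""
    gi = profile.gene_index()
    hits = 0
    total = 0
    for subset in itertools.combinations(sorted(universe), v):
        rows = [gi[g] for g in subset if g in gi]
        z = int(profile.X[rows].any(axis=0).sum()) if rows else 0
        hits += z >= k
        total += 1
    return hits / total


def hypergeom_tail_by_enumeration(M, k, N, n):
    """P(at least k of the n mutated genes fall in the M-gene pathway)."""
    total = math.comb(N, n)
    favourable = sum(
        math.comb(M, j) * math.comb(N - M, n - j)
        for j in range(k, min(M, n) + 1)
    )
    return favourable / total


def step_up_bh(p):
    """Textbook BH step-up, computed directly from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


class TestPathwayMatrix:
    def test_rows_match_definition(self, tiny_profile):
        catalog = PathwayCatalog(
            [
                Pathway("p1", "p1", "metabolism", frozenset({"gA", "gB"})),
                Pathway("p2", "p2", "cellular processes", frozenset({"gE"})),
                Pathway("p3", "p3", "organismal systems", frozenset({"zz"})),
            ]
        )
        mat = pathway_matrix(tiny_profile, catalog)
        assert mat.row("p1").tolist() == [1, 1, 0]
        # gE is never mutated; zz is absent from the profile
        assert mat.row("p2").tolist() == [0, 0, 0]
        assert mat.row("p3").tolist() == [0, 0, 0]
        assert mat.coverage()["p1"] == pytest.approx(2 / 3)

    def test_all_genes_pathway_marks_any_mutated_sample(self, tiny_profile):
        catalog = PathwayCatalog(
            [Pathway("all", "all", "metabolism", frozenset(tiny_profile.genes))]
        )
        mat = pathway_matrix(tiny_profile, catalog)
        expected = tiny_profile.X.any(axis=0).astype(int)
        assert mat.row("all").tolist() == expected.tolist()

    def test_superset_never_loses_coverage(self, tiny_profile):
        base = {"gA"}
        for extra in ["gB", "gC", "gD", "gE"]:
            catalog = PathwayCatalog(
                [
                    Pathway("s", "s", "metabolism", frozenset(base)),
                    Pathway("l", "l", "metabolism", frozenset(base | {extra})),
                ]
            )
            cov = pathway_matrix(tiny_profile, catalog).coverage()
            assert cov["l"] >= cov["s"]


class TestCoveragePermutation:
    def test_k_zero_gives_p_one(self, tiny_profile):
        res = coverage_permutation_test(
            tiny_profile, {"gE"}, tiny_profile.genes, n_sims=200, seed=0
        )
        assert res.k == 0
        assert res.p_perm == 1.0

    def test_pathway_equal_to_universe_gives_p_one(self, tiny_profile):
        res = coverage_permutation_test(
            tiny_profile, set(tiny_profile.genes), tiny_profile.genes, n_sims=50, seed=0
        )
        assert res.p_perm == 1.0

    @pytest.mark.parametrize(
        "pathway,expected_k",
        [
            ({"gD", "gE"}, 1),  # covers s3 only
            ({"gA", "gD"}, 2),  # covers s1, s3
            ({"gB", "gD"}, 3),  # covers s1, s2, s3
        ],
    )
    def test_matches_exhaustive_enumeration(self, tiny_profile, pathway, expected_k):
        """Permutation estimate within 3 binomial SE of the exact tail
        obtained by enumerating all C(5,2)=10 subsets."""
        universe = tiny_profile.genes
        n_sims = 10_000
        res = coverage_permutation_test(
            tiny_profile, pathway, universe, n_sims=n_sims, seed=123
        )
        assert res.k == expected_k
        exact = exact_coverage_tail(tiny_profile, universe, v=2, k=res.k)
        se = math.sqrt(exact * (1 - exact) / n_sims)
        assert abs(res.p_perm - exact) <= 3 * se + 1e-12

    def test_monotone_in_k_on_exhaustive_null(self, tiny_profile):
        tails = [
            exact_coverage_tail(tiny_profile, tiny_profile.genes, v=2, k=k)
            for k in range(0, 5)
        ]
        assert all(a >= b for a, b in zip(tails, tails[1:]))
        assert tails[0] == 1.0

    def test_seed_reproducibility(self, tiny_profile):
        kw = dict(
            pathway_genes={"gA", "gB"},
            universe=tiny_profile.genes,
            n_sims=500,
            seed=42,
        )
        r1 = coverage_permutation_test(tiny_profile, **kw)
        r2 = coverage_permutation_test(tiny_profile, **kw)
        assert r1 == r2

    def test_pseudocount_mode_never_zero(self, tiny_profile):
        res = coverage_permutation_test(
            tiny_profile,
            {"gA", "gB"},
            tiny_profile.genes,
            n_sims=100,
            seed=1,
            pseudocount=True,
        )
        assert res.p_perm > 0

    def test_oversized_pathway_is_error(self, tiny_profile):
        with pytest.raises(ValueError):
            coverage_permutation_test(
                tiny_profile, {"gA", "zz"}, tiny_profile.genes, n_sims=10, seed=0
            )


class TestHypergeometric:
    @pytest.mark.parametrize(
        "M,k,N,n,expected",
        [
            (5, 0, 10, 4, 1.0),
            (5, 2, 10, 4, 155 / 210),
            (3, 3, 6, 3, 1 / 20),
        ],
    )
    def test_known_tails(self, M, k, N, n, expected):
        assert hypergeometric_test(M, k, N, n) == pytest.approx(expected, abs=1e-12)
        assert hypergeom_tail_by_enumeration(M, k, N, n) == pytest.approx(expected)

    def test_inconsistent_counts_are_errors(self):
        for M, k, N, n in [(5, 6, 10, 8), (11, 1, 10, 4), (5, 1, 10, 11), (-1, 0, 10, 4)]:
            with pytest.raises(ValueError):
                hypergeometric_test(M, k, N, n)


class TestBH:
    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_constant_and_singleton(self):
        assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3)
        assert bh_adjust([0.17]).tolist() == [0.17]

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_agrees_with_direct_step_up_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            q = bh_adjust(p)
            assert np.allclose(q, step_up_bh(p), atol=1e-12)
            assert (q >= p - 1e-15).all()
            assert (q <= 1 + 1e-15).all()


class TestSignificantSelection:
    def test_strict_threshold_and_ordering(self):
        df = pd.DataFrame(
            {
                "pathway_id": ["a", "b", "c", "d"],
                "q": [0.01, 0.05, 0.01, 1.0],
                "coverage": [0.2, 0.9, 0.8, 0.5],
            }
        )
        # strict q < 0.05: "b" (q == fdr) excluded; ties broken by coverage
        assert significant_pathways(df, fdr=0.05) == ["c", "a"]

    def test_all_null(self):
        df = pd.DataFrame({"pathway_id": ["a"], "q": [1.0], "coverage": [0.1]})
        assert significant_pathways(df) == []


class TestMeanCoverageAndUnion:
    def test_mean_coverage(self, tiny_profile):
        catalog = PathwayCatalog(
            [
                Pathway("p1", "p1", "metabolism", frozenset({"gA"})),  # cov 1/3
                Pathway("p2", "p2", "metabolism", frozenset({"gB"})),  # cov 2/3
            ]
        )
        mat = pathway_matrix(tiny_profile, catalog)
        assert mean_coverage(["p1", "p2"], mat) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            mean_coverage([], mat)

    def test_smp_union_counts_mutated_genes_once(self, tiny_profile):
        catalog = PathwayCatalog(
            [
                Pathway("p1", "p1", "metabolism", frozenset({"gA", "gB", "gE"})),
                Pathway("p2", "p2", "metabolism", frozenset({"gB", "gC"})),
            ]
        )
        union = smp_gene_union(catalog, ["p1", "p2"], tiny_profile)
        # gE is never mutated and must not appear
        assert union == {"gA", "gB", "gC"}
        assert smp_gene_union(catalog, [], tiny_profile) == set()


class TestCatalogIO:
    def test_gmt_roundtrip(self, tmp_path, small_dataset):
        path = tmp_path / "catalog.gmt"
        write_gmt(small_dataset.catalog, path)
        back = read_gmt(path)
        assert len(back) == len(small_dataset.catalog)
        for p in small_dataset.catalog:
            q = back[p.pathway_id]
            assert q.genes == p.genes
            assert q.klass == p.klass


class TestTestPathways:
    def test_full_table_consistency(self, small_dataset):
        df = score_pathways(
            small_dataset.profile, small_dataset.catalog, n_sims=300, seed=3
        )
        assert len(df) == len(small_dataset.catalog)
        assert ((df["q_perm"] >= df["p_perm"] - 1e-12).all())
        assert ((df["q_hyper"] >= df["p_hyper"] - 1e-12).all())
        assert (df["k_genes"] <= df["M"]).all()
        # coverage recomputed from the pathway matrix must agree
        mat = pathway_matrix(small_dataset.profile, small_dataset.catalog)
        assert np.allclose(df["coverage"], mat.coverage().loc[df["pathway_id"]])
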