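"""Per-gene annotation (damaging status, conservation, known-cancer flags)
and the two-group comparisons used to contrast gene sets.

A gene is *damaging* if at least one of its mutations was called damaging
by an upstream effect predictor; its conservation is an aggregate of the
per-position constraint scores of its mutated positions.  Known-cancer
status comes from a reference gene list supplied as input.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import VariantRecord


def damaging_flags(records: Iterable[VariantRecord]) -> dict[str, bool]:
    """Gene flag = OR of its records' damaging calls (missing = not damaging)."""
    flags: dict[str, bool] = {}
    for r in records:
        flags[r.gene] = flags.get(r.gene, False) or bool(r.damaging_call)
    return flags


def gene_conservation(
    records: Iterable[VariantRecord], aggregator: str = "mean"
) -> dict[str, float]:
    """Aggregate per-position conservation scores to a per-gene value.

    Genes with no scored position are omitted.  ``aggregator`` is ``mean``
    (default) or ``max``.
    """
    if aggregator not in ("mean", "max"):
        raise ValueError("aggregator must be 'mean' or 'max'")
    scores: dict[str, list[float]] = {}
    for r in records:
        if r.conservation_score is not None:
            scores.setdefault(r.gene, []).append(r.conservation_score)
    agg = np.mean if aggregator == "mean" else np.max
    return {g: float(agg(v)) for g, v in scores.items()}


def read_gene_list(path: str | Path) -> set[str]:
    """One symbol per line; blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def annotate_genes(
    genes: Iterable[str],
    records: Iterable[VariantRecord],
    cancer_genes: Iterable[str],
) -> pd.DataFrame:
    """Join damaging/conservation/known-cancer annotation onto a gene list.

    Genes absent from the cancer-gene list count as non-cancer; genes with
    no damaging call count as non-damaging; conservation is NaN when no
    mutated position of the gene was scored.
    """
    records = list(records)
    damaging = damaging_flags(records)
    conservation = gene_conservation(records)
    cancer = set(cancer_genes)
    rows = [
        {
            "gene": g,
            "is_known_cancer": g in cancer,
            "is_damaging": damaging.get(g, False),
            "conservation": conservation.get(g, np.nan),
        }
        for g in sorted(set(genes))
    ]
    return pd.DataFrame(rows).set_index("gene")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities (fixed margins) of all tables at most
    as probable as the observed one.  All four margins must be positive.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be nonnegative integers")
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("fisher_exact_2x2 requires all margins > 0")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def compare_proportions(
    group_a: Iterable[str],
    group_b: Iterable[str],
    flags: Mapping[str, bool],
) -> tuple[float, float, float]:
    """Fisher-compare the flagged fraction between two disjoint gene groups.

    Returns ``(p, rate_a, rate_b)``.  A degenerate margin (all genes
    flagged, or none) yields p = 1 with a warning — there is no contrast to
    test.
    """
    ga, gb = set(group_a), set(group_b)
    if not ga or not gb:
        raise ValueError("both groups must be nonempty")
    if ga & gb:
        raise ValueError("groups must be disjoint")
    fa = sum(bool(flags.get(g, False)) for g in ga)
    fb = sum(bool(flags.get(g, False)) for g in gb)
    rate_a, rate_b = fa / len(ga), fb / len(gb)
    a, b = fa, len(ga) - fa
    c, d = fb, len(gb) - fb
    if min(a + c, b + d) == 0:  # flag margin degenerate
        warnings.warn(
            "degenerate 2x2 margin (flags constant across both groups); p = 1",
            stacklevel=2,
        )
        return 1.0, rate_a, rate_b
    return fisher_exact_2x2(a, b, c, d), rate_a, rate_b


def t_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    variant: str = "pooled",
) -> float:
    """Two-sided two-sample t-test p-value.

    ``pooled`` is the classical equal-variance Student test; ``welch``
    drops the equal-variance assumption.  Degenerate (zero) variance is an
    error — the statistic is undefined.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        raise ValueError("degenerate variance: all observations identical")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.pvalue)
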