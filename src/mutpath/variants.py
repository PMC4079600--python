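"""Variant call parsing, filtering and binary mutation profiles.

The unit of analysis downstream is the binary mutation profile X: a
gene × sample incidence matrix with ``X[i, j] = 1`` iff gene *i* carries at
least one retained somatic mutation in tumor sample *j*.  Samples are
identified by ``(cohort_id, sample_id)`` pairs so that profiles from
independent sequencing cohorts can be pooled without identifier collisions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical variant classes.  ``other`` absorbs anything unrecognised.
VARIANT_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift_indel",
        "inframe_indel",
        "splice_site",
        "synonymous",
        "noncoding",
        "other",
    }
)

#: Classes retained as functional (protein-altering) mutations.
FUNCTIONAL_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift_indel", "inframe_indel"}
)

#: Mapping from MAF ``Variant_Classification`` strings to canonical classes.
MAF_CLASS_MAP: Mapping[str, str] = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Nonstop_Mutation": "missense",
    "Frame_Shift_Del": "frameshift_indel",
    "Frame_Shift_Ins": "frameshift_indel",
    "In_Frame_Del": "inframe_indel",
    "In_Frame_Ins": "inframe_indel",
    "Splice_Site": "splice_site",
    "Splice_Region": "splice_site",
    "Silent": "synonymous",
    "3'UTR": "noncoding",
    "5'UTR": "noncoding",
    "3'Flank": "noncoding",
    "5'Flank": "noncoding",
    "Intron": "noncoding",
    "IGR": "noncoding",
    "RNA": "noncoding",
    "lincRNA": "noncoding",
}

#: Default column names for MAF-compatible variant tables.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "gene": "Hugo_Symbol",
    "sample": "Tumor_Sample_Barcode",
    "variant_class": "Variant_Classification",
    "damaging": "Damaging",
    "conservation": "ConservationScore",
    "position": "Position",
}


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """A single somatic mutation call.

    ``position`` is used only as a key for per-position conservation scores;
    ``damaging_call`` is the verdict of an upstream effect predictor and
    ``conservation_score`` an upstream per-position constraint value (both
    optional; this package never computes them itself).
    """

    cohort_id: str
    sample_id: str
    gene: str
    variant_class: str
    position: int | None = None
    damaging_call: bool | None = None
    conservation_score: float | None = None

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class: {self.variant_class!r}")
        if self.conservation_score is not None and not np.isfinite(
            self.conservation_score
        ):
            raise ValueError("conservation_score must be finite when present")


def _canonical_class(raw: str) -> str:
    raw = raw.strip()
    if raw in VARIANT_CLASSES:
        return raw
    if raw in MAF_CLASS_MAP:
        return MAF_CLASS_MAP[raw]
    return "other"


def read_variant_table(
    path: str | Path,
    cohort_id: str,
    column_map: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Read a tab-delimited, MAF-compatible variant table.

    Parameters
    ----------
    path:
        Tab-delimited file with a header row.
    cohort_id:
        Label attached to every record (cohorts are namespaced at
        integration time).
    column_map:
        Overrides for the default MAF column names, keyed by the logical
        names ``gene``, ``sample``, ``variant_class``, ``damaging``,
        ``conservation``, ``position``.

    Unrecognised variant-class strings are mapped to ``other`` with a
    warning; an empty data section yields an empty list with a warning.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for logical in ("gene", "sample", "variant_class"):
        if cols[logical] not in df.columns:
            raise ValueError(f"missing column: {logical}")
    if df.empty:
        warnings.warn(f"variant table {path} has no data rows", stacklevel=2)
        return []

    has_damaging = cols["damaging"] in df.columns
    has_cons = cols["conservation"] in df.columns
    has_pos = cols["position"] in df.columns

    records: list[VariantRecord] = []
    n_other = 0
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        raw_class = row_d[cols["variant_class"]]
        vclass = _canonical_class(raw_class)
        if vclass == "other" and raw_class.strip() != "other":
            n_other += 1
        damaging = None
        if has_damaging and not _is_missing(row_d[cols["damaging"]]):
            damaging = str(row_d[cols["damaging"]]).strip().lower() in {
                "1",
                "true",
                "yes",
                "damaging",
            }
        conservation = None
        if has_cons and not _is_missing(row_d[cols["conservation"]]):
            conservation = float(row_d[cols["conservation"]])
        position = None
        if has_pos and not _is_missing(row_d[cols["position"]]):
            position = int(float(row_d[cols["position"]]))
        records.append(
            VariantRecord(
                cohort_id=cohort_id,
                sample_id=str(row_d[cols["sample"]]),
                gene=str(row_d[cols["gene"]]),
                variant_class=vclass,
                position=position,
                damaging_call=damaging,
                conservation_score=conservation,
            )
        )
    if n_other:
        warnings.warn(
            f"{n_other} records with unrecognised variant class mapped to 'other'",
            stacklevel=2,
        )
    return records


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or (
        isinstance(value, str) and value.strip() == ""
    )


def filter_functional(
    records: Iterable[VariantRecord], include_splice: bool = False
) -> list[VariantRecord]:
    """Retain protein-altering mutations.

    Keeps missense, nonsense, frameshift and in-frame indels; drops
    synonymous and noncoding calls, mirroring the standard pre-processing
    for mutation-profile construction.  Splice-site calls are excluded by
    default (``include_splice=True`` retains them); ``other`` is always
    dropped, with a warning the first time.
    """
    keep = set(FUNCTIONAL_CLASSES)
    if include_splice:
        keep.add("splice_site")
    out = []
    n_other = 0
    for r in records:
        if r.variant_class in keep:
            out.append(r)
        elif r.variant_class == "other":
            n_other += 1
    if n_other:
        warnings.warn(
            f"dropped {n_other} records with variant class 'other'", stacklevel=2
        )
    return out


Sample = tuple[str, str]


@dataclass
class MutationProfile:
    """Binary gene × sample mutation incidence matrix.

    ``samples`` are ``(cohort_id, sample_id)`` pairs; ``X`` holds 0/1 int8
    entries with one row per gene and one column per sample.
    """

    genes: list[str]
    samples: list[Sample]
    X: np.ndarray
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int8)
        if self.X.shape != (len(self.genes), len(self.samples)):
            raise ValueError("matrix shape does not match gene/sample labels")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene labels")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample labels")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("profile entries must be 0 or 1")
        if not self.provenance:
            self.provenance = {_label(s): s[0] for s in self.samples}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_labels(self) -> list[str]:
        """Samples as ``cohort:sample`` strings."""
        return [_label(s) for s in self.samples]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def gene_counts(self) -> pd.Series:
        """Number of mutated samples per gene."""
        return pd.Series(self.X.sum(axis=1), index=self.genes, name="n_samples")

    def mutated_genes(self) -> set[str]:
        return {g for g, c in zip(self.genes, self.X.sum(axis=1)) if c > 0}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.genes, columns=self.sample_labels)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MutationProfile":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        samples = [_parse_label(c) for c in df.columns]
        return cls(list(df.index), samples, df.to_numpy(dtype=np.int8))


def _label(sample: Sample) -> str:
    return f"{sample[0]}:{sample[1]}"


def _parse_label(label: str) -> Sample:
    cohort, _, sample = label.partition(":")
    return (cohort, sample)


def build_profile(
    records: Sequence[VariantRecord],
    all_samples: Sequence[Sample] | None = None,
) -> MutationProfile:
    """Build a binary mutation profile from (already filtered) records.

    Duplicate records for the same (gene, sample) collapse to a single 1.
    ``all_samples`` fixes the column set so that mutation-free samples keep
    an all-zero column; it must contain every sample seen in the records.
    """
    seen_samples = {(r.cohort_id, r.sample_id) for r in records}
    if all_samples is None:
        samples = sorted(seen_samples)
    else:
        samples = list(all_samples)
        missing = seen_samples - set(samples)
        if missing:
            raise ValueError(f"records reference samples not in all_samples: {missing}")
    genes = sorted({r.gene for r in records})
    gi = {g: i for i, g in enumerate(genes)}
    si = {s: j for j, s in enumerate(samples)}
    X = np.zeros((len(genes), len(samples)), dtype=np.int8)
    for r in records:
        X[gi[r.gene], si[(r.cohort_id, r.sample_id)]] = 1
    return MutationProfile(genes, samples, X)


def integrate(profiles: Sequence[MutationProfile]) -> MutationProfile:
    """Pool cohort profiles: union of genes, disjoint union of samples.

    Entries for genes absent from a cohort are 0.  Duplicate
    ``(cohort_id, sample_id)`` pairs across inputs are a hard error — the
    cohort label is what namespaces otherwise independent sample IDs.
    """
    if not profiles:
        raise ValueError("no profiles to integrate")
    all_samples: list[Sample] = []
    for p in profiles:
        all_samples.extend(p.samples)
    if len(set(all_samples)) != len(all_samples):
        dupes = pd.Series(all_samples).value_counts()
        dupes = dupes[dupes > 1].index.tolist()
        raise ValueError(f"duplicate (cohort, sample) pairs across profiles: {dupes}")
    genes = sorted(set().union(*(p.genes for p in profiles)))
    gi = {g: i for i, g in enumerate(genes)}
    X = np.zeros((len(genes), len(all_samples)), dtype=np.int8)
    col = 0
    for p in profiles:
        rows = [gi[g] for g in p.genes]
        X[np.asarray(rows, dtype=int), col : col + p.n_samples] = p.X
        col += p.n_samples
    return MutationProfile(genes, all_samples, X)


def recurrent_genes(
    profile: MutationProfile, min_samples: int
) -> list[tuple[str, int]]:
    """Genes mutated in at least ``min_samples`` samples.

    Sorted by count descending, ties broken lexicographically.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    counts = profile.gene_counts()
    hits = counts[counts >= min_samples]
    return sorted(hits.items(), key=lambda gc: (-gc[1], gc[0]))


@dataclass(frozen=True)
class OverlapStats:
    """Overlap of two gene (or pathway-id) sets.

    Fractions are the overlap divided by the size of the longer and the
    shorter set respectively, the standard asymmetric overlap summary for
    unequal catalogues.
    """

    n_a: int
    n_b: int
    n_overlap: int
    frac_of_longer: float
    frac_of_shorter: float


def overlap(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapStats:
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("overlap requires two nonempty sets")
    n_ov = len(a & b)
    longer, shorter = max(len(a), len(b)), min(len(a), len(b))
    return OverlapStats(
        n_a=len(a),
        n_b=len(b),
        n_overlap=n_ov,
        frac_of_longer=n_ov / longer,
        frac_of_shorter=n_ov / shorter,
    )
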