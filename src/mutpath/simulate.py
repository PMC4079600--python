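"""Synthetic multi-cohort somatic-mutation benchmark with known truth.

Emulates the study conditions of a multi-cohort hepatocellular-carcinoma
mutation integration: four exome cohorts of 99, 88, 10 and 10 tumors, a
five-class pathway catalogue with regulatory edges, per-gene annotation
(known-cancer flags, damaging calls, conservation scores) and a clinical
table with binary features and overall survival.

The mutation model is per-gene Bernoulli — each gene mutates independently
in each sample at a background rate, elevated for planted driver genes —
because every downstream statistic operates on the binary gene × sample
profile; base-level realism would add nothing testable.  Driver identity
is coupled to the annotation structure (higher damaging probability and
conservation mean, higher known-cancer rate) and to the clinical model
(feature odds ratio and survival hazard for driver-pathway carriers), so
each analysis stage has planted signal with a known direction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .clinical import BINARY_FEATURES, ClinicalTable
from .network import RELATION_TYPES, RegulatoryEdge, write_edges
from .pathways import PATHWAY_CLASSES, Pathway, PathwayCatalog, write_gmt
from .variants import (
    MutationProfile,
    VariantRecord,
    build_profile,
    filter_functional,
    integrate,
)

#: Variant classes carrying a non-null damaging verdict from an upstream
#: effect predictor (synonymous/noncoding calls are never "damaging").
_PREDICTABLE = {"missense", "nonsense", "frameshift_indel", "inframe_indel", "splice_site"}

_DEFAULT_CLASS_MIX = {
    "missense": 0.55,
    "nonsense": 0.05,
    "frameshift_indel": 0.06,
    "inframe_indel": 0.02,
    "splice_site": 0.02,
    "synonymous": 0.20,
    "noncoding": 0.10,
}

_DEFAULT_FEATURE_RATES = {
    "differentiation_poor": 0.35,
    "metastasis": 0.25,
    "cirrhosis": 0.60,
    "hbsag_positive": 0.70,
}


@dataclass
class SyntheticConfig:
    """Tunable study conditions; defaults are the emulated cohort design."""

    seed: int = 0
    n_genes: int = 5000
    n_pathways: int = 150
    pathway_size_range: tuple[int, int] = (10, 100)
    cohort_sizes: tuple[int, ...] = (99, 88, 10, 10)
    background_rate: float = 0.01
    n_driver_pathways: int = 5
    driver_gene_fraction: float = 0.3
    driver_rate: float = 0.08
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_MIX)
    )
    damaging_prob_driver: float = 0.6
    damaging_prob_passenger: float = 0.2
    conservation_mean_driver: float = 3.0
    conservation_mean_passenger: float = 1.0
    conservation_sd: float = 1.0
    cancer_gene_rate_driver: float = 0.4
    cancer_gene_rate_passenger: float = 0.05
    edge_density: float = 1.5
    hub_bias: float = 1.0
    driver_edge_bias: float = 3.0
    clinical_odds_ratio: float = 3.0
    survival_hazard_ratio: float = 2.5
    feature_base_rates: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FEATURE_RATES)
    )
    baseline_median_os: float = 36.0
    censoring_rate: float = 0.3
    missing_rate: float = 0.1

    def __post_init__(self) -> None:
        probs = [
            self.background_rate,
            self.driver_rate,
            self.damaging_prob_driver,
            self.damaging_prob_passenger,
            self.cancer_gene_rate_driver,
            self.cancer_gene_rate_passenger,
            self.censoring_rate,
            self.missing_rate,
            *self.feature_base_rates.values(),
            *self.class_mix.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if not self.cohort_sizes:
            raise ValueError("cohort_sizes must be nonempty")
        if self.n_driver_pathways > self.n_pathways:
            raise ValueError("more driver pathways than pathways")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ValueError("invalid pathway_size_range")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if not (0.0 < self.driver_gene_fraction <= 1.0):
            raise ValueError("driver_gene_fraction must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("pathway_size_range", "cohort_sizes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """What was planted, for recovery tests.

    ``clinical_pathway_id`` names the driver pathway whose per-sample
    coverage status carries the planted clinical odds ratio and survival
    hazard; it is chosen (coverage nearest 1/2, for a balanced contrast)
    when the clinical table is generated and is ``None`` until then or
    when no driver pathways exist.
    """

    driver_pathway_ids: list[str]
    driver_genes: set[str]
    cancer_genes: set[str]
    clinical_effects: dict[str, float]  # feature -> odds ratio
    survival_hazard_ratio: float
    clinical_pathway_id: str | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "driver_pathway_ids": sorted(self.driver_pathway_ids),
            "driver_genes": sorted(self.driver_genes),
            "cancer_genes": sorted(self.cancer_genes),
            "clinical_effects": self.clinical_effects,
            "survival_hazard_ratio": self.survival_hazard_ratio,
            "clinical_pathway_id": self.clinical_pathway_id,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"GENE{i:0{width}d}" for i in range(1, n + 1)]


def generate_catalog(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[PathwayCatalog, list[RegulatoryEdge], GroundTruth]:
    """Pathway catalogue, regulatory edges and planted truth.

    Pathway sizes are uniform over the configured range; genes are sampled
    without replacement within a pathway but pathways overlap freely, as
    curated catalogues do.  Classes rotate round-robin over the five
    adopted classes.  Driver pathways are chosen at random and a fraction
    of their genes marked as drivers.  Each pathway receives an expected
    ``size * edge_density`` directed edges whose endpoints are sampled
    preferentially by current degree (``hub_bias``) and driver status
    (``driver_edge_bias``), planting annotation-coupled hubs.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    lo, hi = config.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_pathways)
    width = len(str(config.n_pathways))
    pathway_genes = [
        rng.choice(config.n_genes, size=int(s), replace=False) for s in sizes
    ]
    driver_idx = set(
        rng.choice(config.n_pathways, size=config.n_driver_pathways, replace=False)
    )

    driver_genes: set[str] = set()
    pathways = []
    for i, gidx in enumerate(pathway_genes):
        pid = f"PW{i + 1:0{width}d}"
        klass = PATHWAY_CLASSES[i % len(PATHWAY_CLASSES)]
        pw_genes = frozenset(genes[j] for j in gidx)
        pathways.append(Pathway(pid, f"synthetic pathway {i + 1}", klass, pw_genes))
        if i in driver_idx:
            n_drv = max(1, round(config.driver_gene_fraction * len(gidx)))
            chosen = rng.choice(gidx, size=n_drv, replace=False)
            driver_genes |= {genes[j] for j in chosen}
    catalog = PathwayCatalog(pathways)
    driver_ids = sorted(catalog.pathways[i].pathway_id for i in driver_idx)

    # known-cancer flags, coupled to driver status
    is_driver = np.array([g in driver_genes for g in genes])
    rates = np.where(
        is_driver, config.cancer_gene_rate_driver, config.cancer_gene_rate_passenger
    )
    cancer_mask = rng.random(config.n_genes) < rates
    cancer_genes = {g for g, m in zip(genes, cancer_mask) if m}

    edges = _generate_edges(config, catalog, driver_genes, rng)
    truth = GroundTruth(
        driver_pathway_ids=driver_ids,
        driver_genes=driver_genes,
        cancer_genes=cancer_genes,
        clinical_effects={f: config.clinical_odds_ratio for f in BINARY_FEATURES},
        survival_hazard_ratio=config.survival_hazard_ratio,
    )
    return catalog, edges, truth


def _generate_edges(
    config: SyntheticConfig,
    catalog: PathwayCatalog,
    driver_genes: set[str],
    rng: np.random.Generator,
) -> list[RegulatoryEdge]:
    degree: dict[str, int] = {}
    named_relations = [r for r in RELATION_TYPES if r != "other"]
    edges: list[RegulatoryEdge] = []
    for p in catalog:
        pw_genes = sorted(p.genes)
        n_edges = round(len(pw_genes) * config.edge_density)
        if n_edges == 0 or len(pw_genes) < 2:
            continue
        drv = np.array([g in driver_genes for g in pw_genes])
        for _ in range(n_edges):
            deg = np.array([degree.get(g, 0) for g in pw_genes], dtype=float)
            w = (deg + 1.0) ** config.hub_bias
            w *= np.where(drv, config.driver_edge_bias, 1.0)
            w /= w.sum()
            src = rng.choice(len(pw_genes), p=w)
            # resample target until distinct (self-loops are not meaningful)
            while True:
                tgt = rng.choice(len(pw_genes), p=w)
                if tgt != src:
                    break
            rel = named_relations[rng.integers(len(named_relations))]
            edges.append(
                RegulatoryEdge(pw_genes[src], pw_genes[tgt], rel, p.pathway_id)
            )
            degree[pw_genes[src]] = degree.get(pw_genes[src], 0) + 1
            degree[pw_genes[tgt]] = degree.get(pw_genes[tgt], 0) + 1
    return edges


def generate_cohorts(
    config: SyntheticConfig,
    catalog: PathwayCatalog,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> dict[str, list[VariantRecord]]:
    """Per-cohort variant call lists.

    Every gene mutates independently per sample (driver rate for planted
    driver genes, background rate otherwise).  Each mutation draws a
    variant class from the configured mixture — including synonymous and
    noncoding calls, so downstream filters are exercised — plus a damaging
    verdict (driver-coupled, never for silent/noncoding calls) and a
    conservation score from the driver or passenger normal distribution.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    genes = _gene_names(config.n_genes)
    is_driver = np.array([g in truth.driver_genes for g in genes])
    rates = np.where(is_driver, config.driver_rate, config.background_rate)
    classes = list(config.class_mix)
    class_p = np.array([config.class_mix[c] for c in classes])

    cohorts: dict[str, list[VariantRecord]] = {}
    for ci, size in enumerate(config.cohort_sizes):
        cohort_id = f"cohort{ci + 1}"
        swidth = len(str(size))
        hit = rng.random((config.n_genes, size)) < rates[:, None]
        gene_idx, sample_idx = np.nonzero(hit)
        n_mut = len(gene_idx)
        vclasses = rng.choice(classes, size=n_mut, p=class_p)
        dam_p = np.where(
            is_driver[gene_idx],
            config.damaging_prob_driver,
            config.damaging_prob_passenger,
        )
        damaging = rng.random(n_mut) < dam_p
        cons_mean = np.where(
            is_driver[gene_idx],
            config.conservation_mean_driver,
            config.conservation_mean_passenger,
        )
        cons = rng.normal(cons_mean, config.conservation_sd)
        positions = rng.integers(1, 100_000, size=n_mut)
        records = [
            VariantRecord(
                cohort_id=cohort_id,
                sample_id=f"S{sample_idx[m] + 1:0{swidth}d}",
                gene=genes[gene_idx[m]],
                variant_class=str(vclasses[m]),
                position=int(positions[m]),
                damaging_call=(
                    bool(damaging[m]) if vclasses[m] in _PREDICTABLE else False
                ),
                conservation_score=float(cons[m]),
            )
            for m in range(n_mut)
        ]
        cohorts[cohort_id] = records
    return cohorts


def cohort_sample_lists(
    config: SyntheticConfig,
) -> dict[str, list[tuple[str, str]]]:
    """Full (cohort, sample) rosters, including mutation-free samples."""
    out = {}
    for ci, size in enumerate(config.cohort_sizes):
        cohort_id = f"cohort{ci + 1}"
        swidth = len(str(size))
        out[cohort_id] = [
            (cohort_id, f"S{j + 1:0{swidth}d}") for j in range(size)
        ]
    return out


def generate_clinical(
    config: SyntheticConfig,
    profile: MutationProfile,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    catalog: PathwayCatalog | None = None,
) -> ClinicalTable:
    """Clinical table with driver-pathway-coupled features and survival.

    The planted effect attaches to the coverage status of one driver
    pathway: among the planted driver pathways the one whose observed
    coverage is nearest 1/2 is selected (a balanced carrier split carries
    the most information), recorded in ``truth.clinical_pathway_id``, and
    its per-sample status *s* drives the clinical model.  Each binary
    feature is Bernoulli with ``logit(base_rate) + s * log(odds_ratio)``;
    survival is exponential with hazard ``h0 * HR^s`` (``h0`` set by the
    baseline median OS) under independent uniform censoring whose window
    is calibrated to censor a ``censoring_rate`` fraction of samples at
    the baseline hazard.  Missing values are injected per feature at
    ``missing_rate``.  Without driver pathways (or
    without ``catalog``) the table is a pure null.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    gi = profile.gene_index()
    carrier = np.zeros(profile.n_samples, dtype=bool)
    if catalog is not None and truth.driver_pathway_ids:
        best = None
        for pid in truth.driver_pathway_ids:
            rows = [gi[g] for g in catalog[pid].genes if g in gi]
            status = (
                profile.X[rows].any(axis=0)
                if rows
                else np.zeros(profile.n_samples, dtype=bool)
            )
            cov = status.mean()
            if best is None or abs(cov - 0.5) < abs(best[0] - 0.5):
                best = (cov, pid, status)
        _, pid, carrier = best
        truth.clinical_pathway_id = pid

    n = profile.n_samples
    df = pd.DataFrame(index=pd.Index(profile.sample_labels, name="sample_id"))
    log_or = math.log(config.clinical_odds_ratio)
    for feat in BINARY_FEATURES:
        base = config.feature_base_rates[feat]
        logit = math.log(base / (1 - base)) + carrier * log_or
        p = 1.0 / (1.0 + np.exp(-logit))
        vals = rng.random(n) < p
        col = pd.array(vals, dtype="boolean")
        miss = rng.random(n) < config.missing_rate
        col[miss] = pd.NA
        df[feat] = col

    h0 = math.log(2) / config.baseline_median_os
    hazard = h0 * config.survival_hazard_ratio**carrier.astype(float)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        # independent Uniform(0, c_max) censoring; c_max calibrated so that
        # P(C < T) = censoring_rate under the baseline hazard:
        # (1 - exp(-h0 c)) / (h0 c) = rate
        x = brentq(
            lambda x: (1 - math.exp(-x)) / x - config.censoring_rate, 1e-9, 1e4
        )
        censor_time = rng.uniform(0.0, x / h0, size=n)
    else:
        censor_time = np.full(n, np.inf)
    censored = censor_time < event_time
    os_months = np.where(censored, censor_time, event_time)
    df["os_months"] = np.round(os_months, 3)
    df["os_event"] = (~censored).astype(float)
    miss = rng.random(n) < config.missing_rate
    df.loc[miss, ["os_months", "os_event"]] = np.nan
    table = ClinicalTable(df)
    table.data["_carrier"] = carrier  # not serialised; kept for truth checks
    return table


@dataclass
class SyntheticDataset:
    """One fully generated study: inputs for every pipeline stage."""

    config: SyntheticConfig
    catalog: PathwayCatalog
    edges: list[RegulatoryEdge]
    truth: GroundTruth
    cohorts: dict[str, list[VariantRecord]]
    clinical: ClinicalTable
    profile: MutationProfile  # integrated, functional mutations only


def simulate_dataset(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> SyntheticDataset:
    """Generate a complete synthetic study (deterministic for a seed).

    Child generators for the catalogue, cohorts and clinical table are
    spawned from one seed sequence, so the stages are independently
    reproducible.
    """
    if config is None:
        config = SyntheticConfig()
    if seed is not None:
        config = SyntheticConfig(**{**asdict(config), "seed": seed})
    ss = np.random.SeedSequence(config.seed)
    rng_cat, rng_coh, rng_clin = (np.random.default_rng(s) for s in ss.spawn(3))
    catalog, edges, truth = generate_catalog(config, rng_cat)
    cohorts = generate_cohorts(config, catalog, truth, rng_coh)
    rosters = cohort_sample_lists(config)
    profiles = [
        build_profile(filter_functional(records), all_samples=rosters[cid])
        for cid, records in cohorts.items()
    ]
    profile = integrate(profiles)
    clinical = generate_clinical(config, profile, truth, rng_clin, catalog=catalog)
    return SyntheticDataset(config, catalog, edges, truth, cohorts, clinical, profile)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write every input file the pipeline readers consume.

    Per-cohort variant TSVs (MAF column names), catalogue GMT, edge TSV,
    known-cancer gene list, clinical TSV and the truth JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cohort_id, records in dataset.cohorts.items():
        rows = [
            {
                "Hugo_Symbol": r.gene,
                "Tumor_Sample_Barcode": r.sample_id,
                "Variant_Classification": r.variant_class,
                "Position": r.position,
                "Damaging": int(bool(r.damaging_call)),
                "ConservationScore": (
                    "" if r.conservation_score is None else round(r.conservation_score, 4)
                ),
            }
            for r in records
        ]
        pd.DataFrame(rows).to_csv(out / f"variants_{cohort_id}.tsv", sep="\t", index=False)
    write_gmt(dataset.catalog, out / "pathways.gmt")
    write_edges(dataset.edges, out / "edges.tsv")
    (out / "cancer_genes.txt").write_text(
        "\n".join(sorted(dataset.truth.cancer_genes)) + "\n"
    )
    clinical = ClinicalTable(dataset.clinical.data.drop(columns=["_carrier"], errors="ignore"))
    clinical.write_tsv(out / "clinical.tsv")
    dataset.truth.to_json(out / "truth.json")
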