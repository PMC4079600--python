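# mutpath

Integrative pathway-level analysis of somatic mutations pooled across
tumor-sequencing cohorts — with a synthetic multi-cohort benchmark that
plants known signal at every stage.

Individual tumors of the same cancer type rarely share mutated genes, but
they do share mutated *pathways*.  `mutpath` implements the standard
workflow for exploiting that: pool variant calls from several cohorts into
one binary mutation profile, identify significantly mutated pathways
(SMPs) by two complementary tests, characterise the genes those pathways
collect, rank them by network centrality, and screen mutation status
against clinical features and survival.  It is written for
bioinformaticians analysing cohort-level somatic variant calls
(MAF-compatible tables) with pathway gene sets (GMT) and regulatory edge
lists.

## The statistics at the core

Let `X ∈ {0,1}^{genes × samples}` with `X_ij = 1` iff gene *i* carries a
retained (protein-altering) mutation in sample *j*, and
`Y_pj = 1` iff sample *j* mutates any gene of pathway *p*.

- **Coverage permutation test** — pathway *p* with *v* genes covers
  `k = Σ_j Y_pj` samples.  Null: draw *v* genes uniformly without
  replacement from the gene universe, recompute coverage `Z`;
  `p = #{Z ≥ k} / n_sims` over 10,000 draws.  This conditions on pathway
  size, which coverage alone does not.
- **Hypergeometric model** — with *N* genes overall, *n* of them mutated
  and annotated in the catalogue, a pathway of *M* genes containing *k*
  mutated ones scores `P(K ≥ k)` for `K ~ Hypergeom(N, M, n)`.
- Both p-value lists are Benjamini–Hochberg adjusted; SMPs are pathways
  with `q < 0.05`.
- Downstream: Fisher exact / Student t contrasts of gene properties,
  unnormalised directed betweenness with zero-betweenness genes as
  controls, and the classical chi-square(Yates)-or-Fisher rule plus
  log-rank/Cox for clinical associations.

## Worked example

Run the analysis chain on a freshly simulated default study (four cohorts
of 99/88/10/10 samples, 5,000 genes, 150 pathways, 5 planted driver
pathways):

```sh
python analysis/01_simulate.py        # writes results/data/
python analysis/02_build_profiles.py
python analysis/03_pathway_tests.py
python analysis/04_gene_properties.py
python analysis/05_network.py
python analysis/06_clinical.py
```

Selected output (seed 7):

```
integrated profile: 3858 genes x 207 samples -> results/profile.tsv
66 genes mutated in >= 10 samples -> results/recurrent_genes.tsv

coverage permutation: 5 significant pathways at FDR 0.05
hypergeometric model: 52 significant pathways
called by both methods: 4
mean sample coverage of permutation SMPs: 72.2%
mean sample coverage of hypergeometric SMPs: 48.5%
262 mutated genes in SMPs vs 3596 outside

known cancer genes: 19.1% in SMP vs 4.5% outside (Fisher p = 4.36e-16)
damaging genes: 59.2% in SMP vs 32.5% outside (Fisher p = 2.14e-17)
conservation: mean 1.73 in SMP vs 0.99 outside (t-test p = 5.82e-41)

network: 151 mutated genes, 498 edges
  k  n_group  cancer_p  damaging_p  conservation_p
 50       50  0.031416    0.000004    8.004345e-10

pathway-level: 4/25 associations flagged
  PW017 x metastasis: 76% vs 38% (chisq_yates, p=1.02e-06)
  PW017 x survival: p=5.4e-09, HR=2.64, median OS 13 vs 37 months
```

Reading this: the permutation test recovers exactly the 5 planted driver
pathways, and they cover far more tumors on average (72%) than the much
larger set called by the gene-level hypergeometric model (48%) — the
characteristic disagreement between the two definitions of "significantly
mutated".  SMP genes are enriched for known cancer genes and damaging
mutations and sit at higher conservation, the top-50 betweenness genes are
enriched over the zero-betweenness controls, and the clinical screen
singles out `PW017` — which is precisely the pathway the generator linked
to the clinical features and survival (planted odds ratio 3, hazard ratio
2.5).

The same stages are available as a CLI (`mutpath simulate|profile|
overlap|test-pathways|compare-genes|network|clinical`) and as library
functions (`mutpath.simulate_dataset`, `mutpath.run_pipeline`, ...).

## Layout

```
src/mutpath/        library: variants, pathways, annotations, network,
                    clinical, simulate, pipeline, cli
analysis/           numbered narrative drivers over the library
tests/              pytest suite (unit, property and oracle tests)
scripts/acceptance.py
docs/methods.md     model, assumptions, parameter defaults, limitations
```
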