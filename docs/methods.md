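# Methods

`mutpath` re-implements, as a tested pipeline, an integrative pathway-level
analysis of somatic mutations pooled across several tumor-sequencing
cohorts, together with a synthetic multi-cohort generator that plants known
signal at every stage so the whole chain can be validated without access to
controlled-access mutation data.

## Mutation profiles

Variant calls arrive as MAF-compatible tab-delimited tables (gene symbol,
sample barcode, variant classification, optional damaging verdict,
conservation score and position).  Calls are reduced to protein-altering
classes — missense, nonsense, frameshift and in-frame indels — dropping
synonymous and noncoding calls.  Splice-site calls are excluded by default
(`include_splice=True` retains them): the filter is a strict reading of
"non-synonymous coding change", and splice effects are not unambiguously
protein-altering without transcript context.

The unit of all downstream analysis is the binary profile
`X[i, j] = 1` iff gene *i* carries at least one retained mutation in sample
*j*.  Cohorts are integrated by taking the union of genes and the disjoint
union of samples, with samples namespaced as `cohort:sample`; a duplicated
(cohort, sample) pair is a hard error rather than a merge, since the source
cohorts have independent identifier schemes and true inter-cohort duplicate
patients cannot be detected from these inputs.  Genes never observed
mutated are not materialised as all-zero rows; the permutation-test
universe (below) is what represents "all genes".

## Pathway significance

A pathway catalogue is a GMT file whose description field carries one of
the five adopted pathway classes (metabolism, genetic information
processing, environmental information processing, cellular processes,
organismal systems); disease and drug "pathways" are assembled
meta-entries and are excluded upstream.  The pathway mutation matrix is
`Y[i, j] = 1` iff sample *j* mutates at least one gene of pathway *i*, and
a pathway's coverage is the fraction of samples it covers.

**Coverage permutation test.**  Because coverage grows mechanically with
pathway size, a pathway with *v* genes covering *k* samples is compared
against draws of *v* genes taken uniformly without replacement from a gene
universe; the p-value is the fraction of 10,000 draws (default) whose
coverage Z reaches at least *k*.  The default universe is the union of
catalogue and profile genes — self-contained and reproducible — and is
overridable with an explicit gene list, because the universe *is* the null:
adding never-mutated genes dilutes null coverage and makes every pathway
look more significant.  The null is evaluated with a bit-packed
implementation: profile rows over the universe are packed to bytes, a
draw's coverage is the popcount of the OR of its rows, and draws are
vectorised in batches, which makes 150 pathways × 10,000 draws a matter of
seconds.  Draws consume one seeded generator shared across pathways in
catalogue order, so a run is exactly reproducible but pathway-order
dependent; the raw proportion is reported by default and
`pseudocount=True` switches to (c+1)/(n+1), which avoids exact zeros at
the cost of a conservative floor.

**Hypergeometric model.**  A pathway with *M* annotated genes, *k* of them
mutated, is scored by the upper-tail probability of observing at least *k*
mutated genes when *n* mutated genes (those annotated anywhere in the
five-class catalogue) are allocated at random among *N* genes (the
universe).  This tests gene-level enrichment and ignores how mutations
distribute over samples, which is why the two methods disagree in a
characteristic way (see the worked example in the README: the
hypergeometric model calls many more pathways, at visibly lower mean
sample coverage).

Both p-value lists are adjusted with Benjamini–Hochberg (step-up) and
thresholded strictly at q < FDR (default 0.05); the boundary convention is
configurable.  SMP genes are the mutated genes belonging to at least one
significant pathway.

## Gene-property contrasts

Per-gene annotation is derived from the variant records: a gene is
*damaging* if any of its calls carries a positive effect-predictor
verdict (missing verdicts count as benign), its conservation score is the
mean (optionally max) of its mutated positions' scores, and known-cancer
status is a join against a reference list, with absent genes counted as
non-cancer rather than excluded.  Group contrasts use a two-sided Fisher
exact test for the binary fractions and a pooled two-sample Student t-test
for conservation (Welch available; pooled is the classical default for
this style of analysis).  Degenerate 2×2 margins (a constant flag) return
p = 1 with a warning instead of an error: there is no contrast to test,
and a screening loop should keep going.

## Network ranking

Regulatory edges (activation, inhibition, expression, repression,
phosphorylation, dephosphorylation, methylation, ubiquitination, plus an
`other` catch-all) are restricted to the SMP genes; self-loops are
dropped, parallel edges between the same ordered pair collapse into one
edge carrying the relation multiset, and genes left with no edge do not
enter the network.  Betweenness is unnormalised shortest-path betweenness
on the *directed* graph — the edges are directional, and normalisation
cannot change a ranking — while the clustering coefficient is computed on
the undirected projection, directed clustering being poorly standardised.
An `--undirected` switch recomputes betweenness on the projection.

Genes are ranked by betweenness (ties: total degree, then name, so the
ranking is deterministic) and formed into nested top-k groups
(k = 50…250 by default).  Genes with zero betweenness are the control
group and never enter a top-k group; groups truncate when fewer nonzero
genes exist than k, which in small networks makes successive groups
identical — visible, not hidden.  Each group is contrasted against the
controls with the same Fisher/t machinery as above.

## Clinical associations

The clinical table carries four binary features (poor differentiation,
metastasis, cirrhosis, HBsAg positivity), overall-survival months and an
event flag, with per-feature missingness dropped pairwise.  A mutation
status vector (a gene's profile row, or a pathway's Y row) is tested
against a binary feature by the classical small-table rule: Fisher's
exact test when the minimum *expected* cell count of the 2×2 is ≤ 5 (the
Cochran criterion — the natural reading of a "group size of 5" rule;
a minimum-observed-count mode is available), otherwise the chi-square test
with Yates' continuity correction.  Survival is compared between arms with
the log-rank test; a univariate Cox proportional-hazards ratio and
Kaplan–Meier median OS per arm are reported alongside, because the two are
routinely quoted together even though only the log-rank p is the test.
Screens report raw p-values (α = 0.05 for features, α = 0.1 for survival,
both configurable) with no multiplicity correction — this is a
hypothesis-generating screen, and BH q-values can be appended by the user
from the output table.

## Synthetic study generator

The generator emulates the study conditions of a four-cohort integration:
cohort sizes (99, 88, 10, 10), 5,000 genes, 150 pathways with sizes
uniform on 10–100 and free gene overlap, five planted driver pathways with
30% of their genes drivers.  The mutation model is per-gene Bernoulli
(background 0.01, drivers 0.08 per sample): every downstream statistic
sees only the binary profile, so base-level simulation would add realism
nothing could test.  Each mutation draws a variant class from a mixture
including 20% synonymous and 10% noncoding calls, so the functional filter
is exercised; a damaging verdict with probability 0.6 for driver genes vs
0.2 for passengers; and a conservation score from N(3, 1) vs N(1, 1).
Known-cancer flags are drawn at 0.4 for drivers vs 0.05 for passengers.
These couplings plant the direction of every gene-property contrast.

Regulatory edges are generated per pathway (expected 1.5 edges per gene)
with endpoints drawn preferentially by current degree (`hub_bias`) and by
driver status (`driver_edge_bias` = 3): degree bias alone would create
hubs whose identity is uncorrelated with the annotations, leaving the
top-k-vs-controls contrast without planted signal, so driver genes are
made more likely to become hubs.

The clinical model attaches its effect to one driver pathway's coverage
status: among the planted driver pathways, the one whose observed coverage
is nearest 1/2 is selected (recorded in the ground truth), because a
balanced carrier split maximises the information available to the tests —
an effect attached to "any driver-gene mutation" would saturate (almost
every sample carries one of ~80 driver genes) and be untestable.  Each
binary feature is Bernoulli with logit(base rate) + s·log(3); survival is
exponential with hazard h0·2.5^s, h0 fixed by a 36-month baseline median,
under independent Uniform(0, c) censoring with c calibrated so ~30% of
samples censor at the baseline hazard.  Feature values (and survival,
jointly for time and event) are set missing at rate 0.1.  Setting the odds
ratio and hazard ratio to 1 yields an exact null.

What the generator does *not* emulate: gene-length- and
expression-dependent background mutation rates, mutational signatures,
copy-number events, inter-cohort platform differences, and correlated
clinical covariates.  Passing recovery tests therefore demonstrates that
the pipeline's statistics behave as designed under their own model — not
that uniform-null pathway tests are well calibrated on real exomes, where
covariate-aware nulls are known to matter.

## Numerical and operational choices

- Hypergeometric tails use the survival function of the hypergeometric
  distribution (log-space internals); validated against exhaustive draw
  enumeration to 1e-12 for all parameter sets with N ≤ 12.
- BH adjustment delegates to the standard step-up implementation and is
  validated against a direct from-definition computation.
- Betweenness is validated exactly against a brute-force
  shortest-path-counting oracle on random digraphs of ≤ 12 nodes.
- Permutation p-values are validated against exhaustive subset enumeration
  on a 5-gene fixture within 3 Monte-Carlo standard errors at 10,000 draws.
- Replicate studies in the test suite use 1,000 permutation draws per
  pathway: planted drivers sit many null standard deviations above the
  null coverage, so p-resolution of 1e-3 is ample for FDR-5% recovery,
  and 20 recovery seeds plus 10 null seeds keep the suite fast.  The null
  calibration of the clinical screen uses 10 independent null studies of
  30 pathways × 4 features (1,200 tests) at cohort sizes (99, 88), where
  the chi-square branch — the one a calibration statement is about — is
  the branch actually taken.
- All randomness flows through seeded NumPy generators; the simulator
  spawns per-stage child generators from one seed sequence, and a fixed
  seed reproduces every output byte-for-byte.

## Known limitations

- The permutation universe default (catalogue ∪ profile genes) is smaller
  than "all genes in the genome"; supplying a full gene list makes every
  pathway more significant.  The choice is explicit precisely because it
  changes the null.
- The hypergeometric and permutation tests share the profile, so their
  q-values are dependent; no joint calibration is attempted.
- Fisher's exact test is conservative on sparse tables; null screens
  dominated by the Fisher branch will flag fewer than α of units.
- Cox fits can fail on separable arms (monotone likelihood); the hazard
  ratio is then reported as NaN while the log-rank p remains valid.
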