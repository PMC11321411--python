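# Methods

This note describes the models, procedures and numerical choices behind
`gnotofunc`, in the order a comparison of defined gnotobiotic consortia
runs through them.

## Setting and assumptions

The unit of input is a genome's KEGG Ortholog (KO) profile: a map from
KO id to copy count, produced upstream by an annotation server from a
genome's open reading frames. A consortium is an ordered list of such
genomes with taxonomy labels. Nothing downstream sees sequences or
coordinates; every analysis is set algebra, counting, or statistics on
these profiles. Two consequences follow and are stated up front:

* "function" means *predicted* function — presence of an ortholog, not
  measured activity;
* gene "clusters" are evaluated as co-occurrence within a genome, not
  physical adjacency, because KO tables carry no positions.

## Module completeness

A module (a KEGG module or a gut metabolic module, GMM) is an ordered
list of reaction steps. Each step carries one or more OR-alternatives;
an alternative is a set of KOs that must all be present (an enzyme
complex when there is more than one). Components marked optional in the
source definition never enter the denominator.

For genome *g* and module *m* with non-optional steps
*s₁ … s_T*, coverage in the default **steps** mode is

    c(g, m) = |{ i : some alternative of s_i ⊆ KOs(g) }| / T

and the module is called **present** when `c ≥ τ` with τ = 0.75
(inclusive: "at least 75%"). A **genes** mode is selectable, where
coverage is the fraction of the module's required-KO union found in the
genome. The two modes differ only for modules with OR-alternatives or
complexes; with alternatives present, "fraction of genes required" is
not well defined, which is why the step-based convention (the standard
GMM coverage) is the default. The mode in force is recorded in every
output's provenance header.

Copy number never affects module work: presence of a KO is what
satisfies a step. Copy counts are kept for prevalence tables, where
gene counts answer a different question (how much of the consortium's
coding capacity points at a function).

## Consortium set algebra and prevalence

Consortium-level KO and module sets are unions over members, with each
KO/module counted once (non-redundant counts). Unique KOs of a target
consortium are its union minus the union of all comparison consortia —
presence-based, deliberately ignoring copy number.

A prevalence row for a KO lists its copy count in every member (member
order fixed), the total gene count, and the prevalence *n/N* (members
carrying it over consortium size). Tables keep KOs carried by at least
3 members by default and sort by prevalence, then gene count, then KO
id. A bundled reference table of 24 infant-microbiome-associated KOs
across 9 isolates ships with the package; its gene counts and
prevalences are always recomputed from the per-isolate copy counts,
never read back from the published totals.

Module prevalence matrices report, per module and consortium, the
fraction of members containing the module; rows sort by the reference
(first) consortium's proportion.

KO-to-category allocation goes through a functional hierarchy table
(KO → pathway, category, subcategory). A KO annotated to several
categories counts once in each; per-category sums are therefore not
additive-exclusive, and the package documents rather than hides this.
Unknown KOs land in an explicit `unannotated` bucket, never an error.

## Comparative statistics

* **High-prevalence filter.** Before differential and dissimilarity
  analyses, modules carried by more than `floor(0.8 · N)` of the N
  pooled isolates are removed as uninformative. With the 9 + 8 + 12 = 29
  isolates of the motivating design the cutoff is 23, strict inequality
  (a module in exactly 23 isolates is retained).
* **Chi-squared.** Pairwise Pearson χ² (no continuity correction — these
  are r×c tables) on consortium × subcategory distinct-KO counts.
  All-zero rows/columns are dropped with a warning; an expected zero
  raises a degenerate-table error. Distinct-KO counting is the default;
  copy-weighted counting is selectable.
* **Dissimilarity indices.** Per consortium, Euclidean distances between
  member vectors of per-module KO counts (retained modules only), all
  unordered pairs, median reported.
* **Kruskal–Wallis / Dunn.** Rank-based KW with tie correction across
  the consortia's distance lists, then Dunn's pairwise z tests. The
  post-hoc adjustment is Benjamini–Hochberg: the source analysis does
  not state its adjustment, and BH keeps the package consistent with the
  FDR convention used elsewhere in it; the method is recorded in the
  output. If all observations are identical, p = 1 on all comparisons
  (no error).
* **PCA.** Column-centered, unscaled PCA of genome × pathway KO-count
  matrices (Euclidean geometry on counts; unit scaling selectable).
  95% group ellipses come from the 2-D score covariance at the χ²(2)
  0.95 quantile. A zero-variance matrix yields zero scores and a
  degenerate flag rather than an error.

## Reporter-score enrichment

Gene-level evidence enters as (id, p, direction) with direction −1 for
the pre-weaning/infant side. The transform is one-sided inverse normal,
`z = Φ⁻¹(1 − p) · direction`, with p clamped to `[1e−15, 1 − 1e−15]` so
z stays finite. A pathway of k annotated members scores

    Z_raw = Σ z_i / √k,

and is standardized against a Monte-Carlo background: μ_k and σ_k are
the mean and SD of the same aggregate over 10,000 random k-subsets
(without replacement within a draw) of the full annotated gene-z pool.
Background sampling from the pool *excluding* the pathway's own genes is
selectable; the full-pool convention is the default. The adjusted score
is `Z_adj = (Z_raw − μ_k)/σ_k`, and a pathway is called enriched in the
pre-weaning direction when `Z_adj < −1.6` (strict; −1.6 itself is not
enriched). The subset sampler draws the first k elements of a random
permutation, so one cumulative sum serves every k in a dataset and the
whole background costs little more than the largest k.

Fixed seed ⇒ bit-identical background moments and calls.

## Amino-acid metabolomics

Concentration tables are samples × analytes in nmol/g with two group
labels. The detection limit is 1 nmol/g; below-LOD values contribute 0
to totals by default ("half-LOD" = 0.5 nmol/g is selectable). Per
analyte, groups are compared with a two-sided Mann–Whitney–Wilcoxon
test: exact enumeration when n_A + n_B ≤ 20 and the data are tie-free,
otherwise the normal approximation with tie and continuity correction
(the two branches agree within 0.02 in p for n ≥ 8 per group). P-values
are BH-adjusted across the analyte family only — a total-free-amino-acid
comparison is one additional, separately reported test — and read at
q < 0.05. Group medians are reported alongside because the summary
statistic of interest in this design is the median level.

For heatmap-style output, rows are z-scored (mean 0, sample SD 1;
constant rows become zeros with a warning), and row/column orders come
from agglomerative **Ward-1** clustering: the Lance–Williams Ward update
applied to *unsquared* Euclidean distances, the variant that matches the
"ward1"/`ward.D` naming convention. The squared-distance variant
(`ward.D2`-style) is selectable. Ties in the merge queue break on the
smallest cluster ids, making leaf orders deterministic.

## Sialic-acid gene clusters

The default rule calls a *nan* catabolism cluster complete when nanA
(N-acetylneuraminate lyase) and nanE (epimerase) are present, with nanK
(kinase) additionally required except in *Bacteroidota*, which
catabolize sialic acid without it. A permissive variant requires nanE
only. Sialidase (nanH) is a separate single-gene rule, since its role
(releasing sialic acid from substrates such as sialyllactose) is
upstream of catabolism. The symbol → KO map (nanA K01639, nanE K01788,
nanK K00885, nanH K01186) is shipped as configuration and should be
verified against the KO catalogue in use; rule files can override any
part of it.

## Synthetic data: what it emulates, and what it does not

The generator produces every input format the pipeline reads, with
serialized ground truth:

* **Module databases** with 2–6 steps, 1–3 alternatives per step, and
  complexes with probability 0.25 by default. KO ids are drawn from a
  reserved namespace and never reused across modules, and background
  KOs come from a second, disjoint namespace. This makes planted
  coverage recovery an *exact* test: a genome built to satisfy s of t
  steps scores exactly s/t.
* **Consortia** of 9, 8 and 12 members by default — the defined
  community sizes of the motivating design — with Poisson(150)
  background KOs per genome.
* **Reporter inputs** with uniform(0,1) null p-values and planted
  pathways whose member z-scores are N(effect, 1) in the planted
  direction (default effect 1.0 at k = 20).
* **Amino-acid tables** of 7 vs 8 samples over 15 analytes with
  log-normal noise σ = 0.3 around per-analyte baselines (~30–2000
  nmol/g) and multiplicative planted effects.

What passing tests on these data show is that the *machinery* is
correct: set algebra exact, coverage equal to brute force, statistics
equal to enumeration oracles, calibrated null behavior, high power on
planted effects. What they do not show is robustness to the messiness
of real annotations — mis-assigned KOs, incomplete catalogues, copy
number inflation from fragmented assemblies, compositional effects in
real metabolomes. Synthetic module KO disjointness in particular is a
deliberate idealization; real modules share KOs.

One property deserves flagging: with 3-fold planted shifts on 2 of 15
analytes at n = 7 vs 8, the *planted-only* recovery rate (exactly the
two planted analytes flagged at BH q < 0.05) plateaus near 88% — not
because power is lacking (planted analytes are essentially always
detected) but because with 13 null analytes the discrete exact-test
p-value floor gives BH a ≈11–12% chance per replicate of dragging one
null analyte below q = 0.05. This is a property of the test/correction
combination at these sample sizes, not an implementation artifact, and
the corresponding regression check is left asserting the ≥90% target it
was designed around; it fails by that structural margin.

## Problem sizes and runtime choices

Default verification sizes — 1,000 random module/genome pairs, 500 null
pathways at 10,000 background subsets, 20 replicates of 10 planted
pathways, 100 metabolome replicates — were chosen so the whole suite
verifies every stage in well under a minute each on a single core while
keeping Monte-Carlo tolerances tight (e.g. null tail rate within 3
binomial SDs at 500 pathways).

## Known limitations

* Steps-mode vs genes-mode coverage can disagree for modules with
  alternatives; both are provided and recorded, but there is no ground
  truth for which an upstream study used.
* Abundance-weighted or community-pooled module scoring is out of
  scope: presence is per-genome.
* The reporter stage takes gene-level p-values as given; it does not
  re-derive them from raw metagenome data.
* Dunn's test uses the large-sample normal approximation for its
  pairwise z statistics regardless of group size.
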