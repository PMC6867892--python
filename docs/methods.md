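# Methods

## Study design being modelled

Wood wafers colonised from one end by a fungus give a space-for-time
decay series: sections cut at 0–5 mm behind the hyphal front capture the
earliest decay stage, and sections at 15–20 mm and 30–35 mm capture
progressively older decay. The pipeline compares four species — two
brown rot, two white rot — each with three bioreplicates per section
(36 libraries for the full design). Only colonised sections carry a
transcriptome, so no "no fungus" condition is simulated.

## Differential expression

**Model.** Counts for gene *g* in sample *s* are negative binomial with
mean μ and common dispersion φ, var = μ + φμ². The choice of a common φ
(rather than gene-wise shrinkage or quasi-likelihood GLMs) is deliberate:
the contrasts used here are plain two-group comparisons, the common-φ
exact test is verifiable against full enumeration, and a common φ matches
the generator's data-generating process. Gene-wise φ is available in the
generator behind `per_gene_dispersion` for robustness experiments, but the
test itself always uses a single φ.

**Exact test.** Library sizes differ, so counts are first scaled to the
geometric-mean depth and rounded to integers (the conditional argument
requires integers and exchangeable samples; the rounding bias is
negligible at the depths tested). Conditioning on the two-group total *t*,
the group-1 total follows a ratio of NB mass functions that is free of μ;
the two-sided p-value sums P(split) over all splits with probability not
exceeding the observed one (with a 1e-10 relative slack so ties are
included deterministically). φ = 0 falls back to the binomial split. The
conditional construction makes the test mildly conservative at n = 3,
which the calibration tests quantify rather than correct.

**Dispersion.** φ maximises the summed conditional log-likelihood of
replicate counts given their group totals (replicated section groups only,
equal depths after scaling), optimised on log φ in [1e-6, 5] by bounded
scalar minimisation; a boundary optimum is reported as φ = 0. On
simulated data the estimator recovers φ = 0.2 within ±0.02 at 900 genes
and φ = 0.05 within ±0.002 at full scale.

**DEG rule.** Per contrast, BH step-up FDR across genes; a gene is a DEG
when FDR < 0.05 and |log₂FC| > 2 (fold change > 4). log₂FC uses a 0.5
pseudocount per scaled group mean, which only matters for all-zero groups.
Contrasts are the three section pairs oriented later-over-earlier.

## Temporal staging

The direction triple (d_BA, d_CA, d_CB) over the three contrasts maps to
eight subgroups (I–IV early-peaked, V–VIII late-peaked; see README). Two
points are deliberate:

* Genes significant in contradictory directions are left unstaged rather
  than forced into the nearest subgroup — pooled stage sets contain only
  trend-consistent genes and are disjoint by construction.
* Under the section relabeling A↔C the triple transforms to
  (−d_CB, −d_CA, −d_BA). The eight subgroups are closed under this map,
  with I↔V, II↔VIII, IV↔VI swapping stage and the two dip/bump patterns
  III and VII mapping to themselves. The pooled early/late sets swap for
  all monotone-flavoured subgroups; the self-symmetric pair is retained
  because a front-peaked dip (high at A, equal at C) is evidence of early
  investment even though its mirror image is its own pattern. Whether the
  original study's subgroup criteria also conditioned on expression
  magnitude is unknown; this reconstruction uses DEG directions only.

## Orthology and the cross-species comparison

OrthoMCL-style Markov clustering is not re-implemented. The surrogate is
reciprocal best hits (per query gene and target species) joined by
single-linkage connected components; externally supplied ortholog tables
are accepted verbatim. The surrogate is exact when groups are complete and
similarity scores separate true pairs from noise by a margin; with
incomplete groups, noise edges can fuse components — a known limitation
shared with RBH methods generally.

Stage sets are lifted to group ids with an any-member rule (a group is an
early DEG for a species if any paralog of that species is), orphan genes
keep species-specific ids, and the four species' id sets are partitioned
into all 15 Venn cells. "Brown-rot-unique" is the cell containing ids
present in both brown-rot species' sets and neither white-rot set.

The per-group temporal statistic is r = log₂[(R₀₋₅ + ε)/(mean(R₁₅₋₂₀,
R₃₀₋₃₅) + ε)] on member-summed RPKM, ε = 0.1 RPKM — far below the
RPKM > 5 expression-evidence threshold, so pseudocounting never flips an
evidence call. Sample correlation uses Spearman (average ranks on ties,
pairwise-complete, ≥ 3 shared groups) restricted to ortho-DEG groups, and
sample clustering uses complete linkage on euclidean distances between
correlation-matrix rows.

## Functional investment

Family DEG counts, the 2×2 Fisher contrast (rot type × early/late pooled
LOX DEG counts), and paired t-tests on per-family early-minus-late
differences (families paired across rot types, species pooled within a
type) quantify the LOX early shift. Term enrichment is one-sided
hypergeometric over-representation with BH correction — the standard GO
usage. The GH:LOX ratio divides class-summed section-mean RPKM;
section means (not all-sample sums) are used because replicate counts are
exchangeable within a section. Family-expression PCA takes log₂(x+1) of
family-summed section-mean RPKM per (species × section) observation —
expression spans orders of magnitude, so the log keeps a few huge families
from owning every component. Z-scores use the sample standard deviation
(ddof = 1), matching common heatmap tooling; constant rows map to zeros.

## Synthetic data: what it emulates and what it does not

Each ortholog group gets a functional class (LOX with probability 0.05,
GH 0.08, otherwise "other"), a family label, a log-uniform baseline
(2²–2⁹ on an RPKM-like scale), and per-species membership: single-copy
with probability 0.62^(1/4) ≈ 0.887 (closed-form calibration so ~62% of
groups are single-copy in all four species), duplicated with probability
0.03, otherwise absent. Counts are NB with
μ = baseline × section-multiplier × length × depth / 10⁹; per-sample
depths are drawn uniformly within ±20% of the nominal 2×10⁶ so the
pipeline must normalise. One RNG stream per artifact (catalog, counts,
depths, similarity) keeps artifacts independent under config changes.

Injected biology, decided per ortholog group:

* 10% of groups are regulated. Regulated LOX groups are early-upregulated
  (8-fold at 0–5 mm) in brown-rot members with probability 0.9 (else
  late), and split 50/50 between early and late in white-rot members —
  the 90/10 brown split reflects an early:late DEG imbalance of roughly
  an order of magnitude rather than an absolute rule. Regulated GH groups
  are late-upregulated (8-fold at both later sections) in every species.
  Regulated "other" groups draw a scope (brown-only / white-only / all)
  and a stage at random, providing the material for the rot-type-unique
  Venn cells.
* Baseline budgets differ by nutritional mode: GH baselines ×4 in brown
  rot, LOX baselines ×5 in white rot. With the class fractions and late
  effects above, the expected late-section GH:LOX ratio contrast between
  rot types lands near the ~30-fold magnitude reported for real decay
  transcriptomes.

Catalog size defaults to 4000 ortholog groups (~3600 genes per species) —
a desk-scale stand-in for ~12k-gene fungal genomes chosen so class-level
DEG counts (≈ 180 LOX genes per species) give the categorical tests
realistic power; dispersion defaults to φ = 0.05, a typical
bulk-RNA-seq biological-replicate value, since within-section variance is
not derivable from the study text.

What the generator does **not** emulate: mapping artefacts and gene-length
biases beyond the linear length term, TMM-style composition effects,
gene-wise dispersion trends (unless enabled), correlated co-regulation
within pathways, partial orthology (one-to-many across only some
species), and annotation errors. Passing recovery tests therefore shows
the pipeline is correct and calibrated under its assumed model — not that
the biological conclusions of any particular real dataset are guaranteed.

## Numerical choices and degenerate inputs

* p-values are clipped into (0, 1]; both-groups-zero genes give p = 1,
  log₂FC = 0.
* BH q-values enforce monotonicity and are capped at 1.
* Fisher tables with a zero margin are flagged degenerate and reported
  with p = 1; identical paired vectors give t = 0, p = 1.
* Zero LOX RPKM sums leave the GH:LOX ratio undefined (NaN), never
  infinite; zero GH sums give 0.
* Constant matrices yield zero PCA components; constant rows Z-score to 0.
* Hierarchical clustering rejects non-finite input; merge ties are
  resolved by scipy's deterministic ordering.
* All simulation randomness flows from a single seed through named
  `SeedSequence` children; equal seeds reproduce byte-identical TSVs.

## Problem sizes used by the checks

The test suite and the acceptance script simulate at the defaults above
(4000 groups, 4 species) for pattern recovery, a 2000-gene single-species
null for calibration, 500-group runs for module-level recovery tests, and
250-group runs for byte-determinism, keeping a full run around a minute
on one CPU.

## Known limitations

The exact test's conservatism at n = 3 trades a little power for
verifiability; common φ underfits data with strong mean-dispersion
trends; the RBH surrogate can merge groups when orthology is incomplete;
enrichment treats terms as flat labels (no GO-graph propagation); and the
"2,093 ortho-DEGs"-scale numbers of the original study depend on the real
sequencing data, which this package deliberately does not require.
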