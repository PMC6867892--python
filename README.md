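# rotstage

Decay-stage transcriptomics of wood-decay fungi: a tested, reusable
pipeline for comparing how brown-rot and white-rot species regulate their
lignocellulose-degrading machinery along a wood-wafer decay gradient.

Brown-rot fungi pretreat wood with Fenton-type reactive-oxygen chemistry at
the advancing hyphal front and only later deploy glycoside hydrolases (GH);
white-rot fungi degrade lignin and carbohydrates enzymatically throughout
decay. Given per-section RNA-seq count matrices from colonised wafer
sections (0–5 mm behind the hyphal front = earliest decay, 15–20 mm and
30–35 mm = later decay; three bioreplicates each), the package

1. normalises counts to RPKM and calls differentially expressed genes
   (DEGs) between sections with a negative-binomial exact test
   (FC > 4, BH FDR < 0.05, *n* = 3);
2. classifies each gene's direction triple across the three section
   contrasts into eight temporal subgroups and pools them into
   "decay-stage-dependent" **early**- and **late**-upregulated sets;
3. lifts the stage sets to ortholog groups (reciprocal-best-hit surrogate
   or a supplied table), partitions them in a four-species Venn diagram
   (brown-rot-unique, white-rot-unique, common cells) and clusters samples
   by their early-to-late expression ratios
   r = log₂[RPKM₀₋₅ / mean(RPKM₁₅₋₂₀, RPKM₃₀₋₃₅)];
4. computes the functional-investment statistics: per-CAZY-family early/late
   DEG counts, the rot-type LOX early-shift contrast (Fisher's exact test,
   paired *t*-tests per family), hypergeometric term enrichment, the GH:LOX
   summed-RPKM transcription ratio per decay stage, and family-expression
   PCA / Z-score scaling.

A synthetic-data module (`rotstage.synthdata`) simulates the full study
design — 2 brown-rot + 2 white-rot species, negative-binomial counts with
stage-dependent mean multipliers, orthology structure with a 62%
single-copy-in-all-species rate, and injected LOX-early / GH-late
programs — with complete ground truth, so every stage of the pipeline is
exercised and calibrated without the original sequencing data.

## The statistics at the core

**DE test.** For a two-group section contrast with replicate counts scaled
to a common depth, the test conditions on the total count *t* of both
groups. Under NB sampling with common dispersion φ (var = μ + φμ²), the
group-1 total given *t* has a distribution free of μ; the two-sided p-value
sums the probabilities of all splits of *t* no more likely than the one
observed (φ = 0 reduces to a binomial split). φ is estimated by maximising
the conditional log-likelihood of within-group counts given group totals.

**Temporal staging.** With sections A = 0–5, B = 15–20, C = 30–35 mm and
DEG directions (d_BA, d_CA, d_CB) oriented later-over-earlier, subgroups
I (−,−,−), II (−,−,0), III (−,0,+), IV (0,−,−) pool to *early* and
V (+,+,+), VI (+,+,0), VII (+,0,−), VIII (0,+,+) pool to *late*;
contradictory triples are left unstaged.

**Investment ratio.** Per species and section,
GH:LOX = Σ RPKM(GH genes) / Σ RPKM(LOX genes) — the transcriptional
allocation between saccharification and oxidative chemistry.

## Worked example

The numbered drivers under `analysis/` run the whole study on simulated
data (each is a thin wrapper over the library and writes TSVs under
`results/`):

```
python analysis/01_simulate.py --seed 1
python analysis/02_differential_expression.py
python analysis/03_stage_classification.py
python analysis/04_cross_species.py
python analysis/05_functional_investment.py
```

which prints, among other things:

```
BR1: phi=0.0507; 96.7% genes with expression evidence; DEGs per contrast:
    {'15-20mm_vs_0-5mm': 260, '30-35mm_vs_0-5mm': 259, '30-35mm_vs_15-20mm': 0}
BR1: 129 early / 130 late decay-stage-dependent DEGs; subgroups: {'II': 129, 'VI': 130}
early: 56 brown-rot-unique, 45 white-rot-unique, 37 common-to-all ortho-DEGs
pooled LOX DEGs  brown 29 early/0 late, white 13 early/17 late; Fisher p = 6.2e-07
late-section GH:LOX ratios: {'BR1': 11.61, 'BR2': 12.06, 'WR1': 0.48, 'WR2': 0.44}
```

Reading: the estimated dispersion (0.0507) recovers the simulated value
(0.05); the injected early/late programs are recalled as stage subgroups;
the Venn partition isolates ortholog groups regulated only in the two
brown-rot species; brown-rot LOX DEGs concentrate in early decay while
white rot splits them across stages (the "LOX early shift"); and the
late-decay GH:LOX transcription ratio is ≫ 1 in brown rot but < 1 in
white rot — roughly a 25-fold allocation difference between the two
nutritional modes.

The package also ships the published catalog of brown-rot-unique
decay-stage-dependent DEGs (`rotstage.tables`): 34 early- plus 18
late-upregulated ortholog groups, 52 in total, with their printed RPKM and
fold-change values.

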