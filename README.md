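# utrscreen

A Python toolkit for massively parallel reporter screens of 3′ UTR variants
that act post-transcriptionally on mRNA abundance.

## The problem

Most disease-associated genetic variation is non-coding, and a large share
of it falls in 3′ untranslated regions, where it can change mRNA stability
through microRNA sites, RNA-binding-protein motifs, and other cis-elements.
Massively parallel reporter assays (MPRAs) test thousands of such variants
at once: every variant is synthesized as a ref/alt pair of reporter oligos,
transfected as a pool, and read out by sequencing both the plasmid DNA pool
and the transcribed RNA. A variant is functional when its alternative allele
shifts the RNA/DNA ratio.

`utrscreen` implements that workflow end to end as a library:

- **design** — select rare or somatic single-nucleotide variants inside
  annotated 3′ UTRs, screen candidate inserts for cloning-incompatible
  substrings, and assemble 200-nt synthesis oligos with the variant centered
  in the tested window; saturation-mutagenesis panels for known motifs.
- **reads** — parse structured reads (15-nt UMI, fixed primer segments,
  100 nt of designed sequence), assign read pairs to designed oligos with an
  exact-hash + 1-substitution matcher that refuses mismatches at the
  designed SNP, and collapse PCR duplicates by UMI.
- **quantify** — quantile-normalize replicate counts, score per-allele
  activity `A = C_RNA / C_DNA`, compute the relative activity
  `lnFC = ln(A_alt / A_ref)`, test each variant with a negative binomial
  likelihood-ratio test (shared dispersion estimated by Cox–Reid adjusted
  profile likelihood), and call variants functional at FDR ≤ 0.10 and
  |lnFC| ≥ 0.10.
- **motifs** — hexamer over-representation between up- and down-regulating
  alleles, PWM motif-strength changes against shuffled-PWM and
  nonfunctional nulls, miRNA-site overlap with direction-bias tests, and
  eCLIP peak distance tests.
- **enrich** — permutation gene-set enrichment of top-ranked variants
  against size-matched (optionally length/GC-matched) control gene sets.
- **clinical** — per-patient untranslated tumor mutational burden (uTMB) in
  six driver-role/effect-direction categories, tertile survival comparisons
  (log-rank), and carrier expression-outlier analysis.
- **simulate** — a synthetic-data generator with known ground truth for
  every layer: designed libraries over random UTRs, gamma–Poisson
  UMI-family counts, structured paired reads with PCR duplicates and
  sequencing errors, and genotype-linked patient cohorts.

## The model

For each variant the screen produces deduplicated UMI counts for both
alleles, in DNA and RNA libraries, across replicates. After rank-based
quantile normalization within each library type, the per-allele activity is
the replicate-summed RNA count over the DNA count, and the effect size is
the log ratio of alt to ref activity. Significance comes from a negative
binomial model: replicate RNA counts are `NB(rate × DNA, α)`, a rate is
fitted per allele, and the likelihood-ratio statistic against a shared-rate
null is referred to χ²(1). The dispersion α is a single per-dataset
parameter: with three replicates per allele, per-variant estimates are
unstable, and a naive pooled estimate is biased toward zero because each
small group consumes a fitted rate (a Neyman–Scott problem), so α is
maximized under a Cox–Reid adjusted profile likelihood with a
degrees-of-freedom-corrected moments fallback.

## Quick start

```bash
pip install --no-build-isolation -e .
```

```python
from utrscreen import quantify, simulate

cfg = simulate.SimConfig(seed=5, n_variants=150, frac_functional=0.3)
_, _, truth, oligos = simulate.build_library(cfg)
counts = simulate.simulate_counts(oligos, truth, cfg)
calls = quantify.quantify_screen(counts, oligos, cell_line="SIM")
```

Running `python examples/03_call_functional_variants.py` (exactly the code
above plus a truth comparison) prints:

```
tested 150 variants; shared NB dispersion 1.13e-03
called functional: 40 (truth: 41)
true positives among calls: 39/40
estimated vs true lnFC: Pearson r = 0.982

strongest calls:
variant_id    lnFC  fdr direction
  var00053  0.9602  0.0        up
  var00103  0.9045  0.0        up
  var00042 -0.8779  0.0      down
  var00110  0.8723  0.0        up
  var00007  0.8466  0.0        up
```

The `examples/` directory walks every stage:

| script | stage |
| --- | --- |
| `01_design_library.py` | variant table + UTR BED → filtered, screened, assembled oligos |
| `02_count_reads.py` | simulated FASTQ-level reads → matched, UMI-deduplicated counts |
| `03_call_functional_variants.py` | counts → activity scores → functional calls vs truth |
| `04_mechanism.py` | sequence groups, hexamer enrichment, PWM strength nulls |
| `05_enrichment.py` | top-variant ranking → permutation gene-set enrichment |
| `06_clinical.py` | simulated cohort → uTMB, survival tertiles, expression outliers |

## Reproduction

All verification is seeded and offline.

```bash
# unit, property, and end-to-end acceptance tests (~4 min)
python -m pytest -q tests/

# headline quantities as JSON (~40 s)
python scripts/acceptance.py --seed 1 --out acceptance.json
```

The acceptance script reports, among other quantities, the false-positive
rate of the functional caller on simulated null screens, the slope and RMSE
of estimated vs true lnFC, an exact count round-trip through the read
simulator and counting pipeline, and Kolmogorov–Smirnov uniformity checks
of the log-rank and permutation-enrichment p-values under their nulls. With
`--seed 1`:

```
"null_screen_false_positive_rate": 0.0,
"recovery_slope": 1.001483936800807,
"recovery_rmse": 0.054718559432155964,
"round_trip_counts_exact": true,
"logrank_null_ks_uniformity_p": 0.5308243331192445,
"enrichment_null_ks_uniformity_p": 0.6848693330429645,
```

See `docs/methods.md` for model assumptions, parameter defaults, and
limitations.
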