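# Methods

Model assumptions, parameter defaults, simulator scope, and numerical
choices. Nothing here asserts an empirical result that is not computed by
the test suite or `scripts/acceptance.py`.

## Oligo design

Three 200-nt layouts are supported, differing in the cloning segments that
flank the tested insert:

| layout | structure | insert | variant offset in insert |
| --- | --- | --- | --- |
| `design1` | 15-nt fwd subpool primer + EcoRI + insert + BamHI + 15-nt rev primer | 158 nt | 78 |
| `design2` | 15-nt fwd subpool primer + EcoRI + insert + 15-nt rev primer | 164 nt | 81 |
| `motif` | 21-nt fwd primer + EcoRI + insert + 15-nt rev primer | 158 nt | 78 |

Every layout validates that its segments sum to 200 nt at construction.
The variant sits at the centered offset `(insert_len − 1) // 2`; for
minus-strand variants the plus-strand genomic window is reverse-complemented
and alleles complemented, so the tested insert is always the transcribed
strand. Inserts containing EcoRI/BamHI sites or subpool primer sequences on
either strand are rejected before assembly.

Variant-table conventions: variant positions are 1-based (VCF style) with
alleles on the plus strand; interval inputs (UTR annotations, miRNA sites,
eCLIP peaks) are 0-based half-open (BED style). A variant at 1-based
position `p` overlaps interval `[start, end)` iff `start ≤ p − 1 < end`.

Rare-variant filtering keeps SNVs with adjusted allele frequency strictly
below 0.01 (variants with missing frequency are dropped and counted);
somatic mode instead requires recurrence in at least 2 samples.

## Read processing

Read 1 is parsed by fixed widths: 15-nt UMI, 14-nt RT primer, 6-nt
restriction segment, 15-nt subpool primer, then 100 nt of designed
sequence. Read 2 is the designed oligo in reverse-complement orientation
(auto-detected).

Because the reference set is small, fixed-length, and fully enumerable,
reads are assigned with an exact hash of the 100-nt design fragment plus
1-substitution neighborhood probing instead of a general-purpose aligner.
Acceptance requires at most one mismatch against the reference across both
reads combined (positions covered by both reads are merged, so a single
molecule error seen twice counts once), and no mismatch may fall on the
designed SNP position — an error there could silently convert one allele
into the other. Ties between equally good references leave the read
unmapped. PCR duplicates collapse to distinct (UMI, oligo) pairs.

Per-position mismatch profiles exclude 15 nt at either end of the design
(primer-derived positions, which are constrained by synthesis rather than
sequencing).

## Quantification

1. **Normalization**: rank-based quantile normalization of deduplicated
   counts across replicates, separately within DNA and RNA libraries. Tied
   counts receive the mean of the tied target values, so the procedure is
   deterministic and permutation-equivariant.
2. **Activity**: per allele, `A = C_RNA / C_DNA` on replicate-summed
   normalized counts. Alleles with fewer than 10 raw deduplicated DNA
   families (summed over replicates) are flagged low-coverage and excluded.
3. **Effect size**: `lnFC = ln(A_alt / A_ref)`. When an activity is zero
   the reported value falls back to a pseudocount (0.5) form and is flagged
   `lnFC_capped`; the flagged value is for display/ranking only.
4. **Test**: replicate RNA counts are modeled `NB(rate × DNA_obs, α)` with
   the observed DNA count as an exposure. A rate is fitted per allele by
   1-D maximization on the log scale; the likelihood-ratio statistic
   against a single shared rate is referred to χ²(1). If the NB fit
   degenerates (e.g., all-zero RNA in both alleles) a Welch t-test on
   per-replicate log ratios substitutes.
5. **Calling**: Benjamini–Hochberg over all tested variants;
   functional ⇔ FDR ≤ 0.10 and |lnFC| ≥ 0.10 (both inclusive).

### Dispersion

α is one parameter per dataset. Rationale: with three replicates per
allele, per-variant dispersion estimates are dominated by noise, while UMI
family counts are molecule counts whose overdispersion is expected to be
modest and shared in origin (pipetting, transfection, library bottlenecks).

Estimating a shared α across many 3-observation groups, each with its own
fitted rate, is a classic incidental-parameters (Neyman–Scott) setting:
the naive profile likelihood and naive moments estimator are both biased
toward zero — severely so at these group sizes (the residual sum of squares
in a group of R observations has only R − 1 degrees of freedom, but the
naive moment equation charges it for R). Two corrections are applied:

- **moments**: per group, the residual sum of squares is scaled by
  `R / (R − 1)` before subtracting `Σμ`, giving a pooled estimator of
  `Σ[(SS · R/(R−1)) − Σμ] / Σμ²` over groups.
- **adjusted profile likelihood** (default): the profiled log-likelihood at
  each α subtracts `½ log I_g` per group, where
  `I_g = Σ μ / (1 + αμ)` is the observed information of the profiled
  log-rate (the Cox–Reid adjustment, as used by edgeR). The profile is
  maximized over up to 200 randomly subsampled groups for speed.

The unit suite verifies both estimators recover a known α on synthetic
data; the acceptance suite verifies the downstream consequence (near-zero
false positives on null screens and unbiased lnFC recovery).

## Mechanism statistics

- **Motif strength** under uniform background:
  `S = Π p_i(base_i) / 0.25^n`; the per-variant change is
  `Δ = |S_var − S_ref|`. Functional-variant Δ distributions are compared
  (two-sample KS) against a position-shuffled PWM null and a size-matched
  nonfunctional-variant null; both arms require ≥ 10 pairs.
- **Hexamer enrichment** counts window *containment* (each window
  contributes at most once per hexamer) and applies a one-sided Fisher
  exact test per hexamer with BH correction. Windows are the variant ± 5 nt
  of whichever allele is higher-expressed (up group) vs lower-expressed
  (down group), so group sizes are equal by construction.
- **miRNA sites**: overlaps require a context-score percentile ≥ 50; sites
  without a percentile are dropped and counted. Direction bias uses a
  one-tailed rank-sum (site-overlapping variants shifted toward
  derepression), with a one-sample signed-rank alternative.
- **eCLIP distances**: distance to the nearest peak is 0 inside a peak,
  else the distance to the nearer peak edge; the functional-vs-
  nonfunctional comparison is a one-tailed rank-sum.

## Permutation enrichment

The query is the host-gene set of the top-N variants ranked by the maximum
|lnFC| across cell lines (each variant counted once; ties broken on variant
id for determinism). Control sets of the query's size are drawn from the
background with query genes excluded, optionally matching each query gene
on length and GC within ±10 % (relative), widening the tolerance ×1.5
stepwise when no candidate matches — widened genes are recorded. Per term,
the upper-tail p comes from a normal fit to the control occurrence counts;
when the control sd is zero, the add-one empirical p `(r + 1) / (n + 1)`
substitutes. Significance requires BH FDR < 0.05 **and** query occurrence
≥ 5.

Calibration caveat: with query-excluded controls, if the query is a large
fraction of the background, a query that is membership-rich by chance
depletes the control pool, deflating the null mean and inflating z. The
method is calibrated in its intended regime (query ≪ background, e.g.,
hundreds of genes against thousands); the acceptance suite verifies KS
uniformity of null p-values at a 4 % query fraction.

## Clinical statistics

- **uTMB**: six per-patient counts — functional overall, driver functional
  overall, driver functional detrimental, driver functional benign,
  nonfunctional, driver nonfunctional. Detrimental = functional and
  (oncogene & up) or (tumor suppressor & down); the reverse pattern is
  benign; functional variants in ambiguous/unknown-role genes are counted
  in the driver-overall bucket when the role is ambiguous.
- **Survival**: patients are split into tertiles by stable sort (ties
  resolved by patient order, deterministically); the default comparison is
  top vs bottom tertile, middle excluded, with a top-vs-rest option.
  Log-rank is two-sided via lifelines; degenerate cohorts (all-equal uTMB)
  are skipped with a flag.
- **Outliers**: carrier expression z-scores use the non-carrier patients'
  mean/sd (≥ 5 reference patients, sd > 0 required); outlier ⇔ |z| > 2;
  a consistency flag records whether sign(z) matches the screen's lnFC
  sign. Carrier-vs-reference outlier proportions are compared with a
  two-sided Fisher exact test; an empty margin reports p = 1 with OR = NaN.

## Synthetic data generator

What it emulates:

- per-variant random UTR contigs with the variant centered, inserts
  pre-screened for cloning-incompatible substrings, both strands;
- ground-truth effects: a configurable fraction of variants functional with
  |lnFC| uniform in `[effect_min, effect_max]`, signed at random; the rest
  exactly zero;
- gamma–Poisson (NB) UMI-family counts; DNA around
  `dna_depth × per-oligo lognormal abundance`, RNA drawn **conditionally on
  the observed DNA** of the same replicate (`NB(rate × DNA_obs, α)`), with
  the rate carrying a per-variant lognormal baseline and `exp(lnFC)` for
  the alt allele. Drawing RNA conditionally matters: the quantification
  model conditions on DNA, so an unconditional simulator would add DNA
  measurement noise that neither model accounts for, inflating the test;
- structured paired reads per UMI family with Poisson PCR duplication
  (`1 + Poisson(rate − 1)` copies) and per-base substitution errors;
- a patient cohort: Poisson numbers of somatic mutations drawn from the
  called variants, expression standard-normal with carriers of functional
  variants shifted by `expression_shift × sign(lnFC)`, exponential survival
  with log-hazard proportional to the functional-mutation count, uniform
  censoring.

What it does **not** emulate: indels and multi-allelic sites, UMI
collisions and sequencing-error-induced UMI splitting, PCR chimeras,
position-dependent error profiles, guanine-quadruplex or secondary-
structure effects, correlated effects between variants in the same gene,
batch effects between replicates, competing risks or informative censoring
in the cohort, and real genome annotation of any kind.

Determinism: every consumer derives its generator from
`SeedSequence([seed, k])` with a distinct `k` per stage, so tables are
reproducible bit-for-bit given `SimConfig.seed`, and the full configuration
round-trips through a YAML manifest.

### Parameter defaults and rationale

| parameter | default | rationale |
| --- | --- | --- |
| `n_replicates` | 3 | typical replication for this assay family |
| `dna_depth`, `rna_depth` | 300 | hundreds of UMI families per oligo, the regime the caller targets |
| `dispersion` | 1e-3 | UMI families are molecule counts; near-Poisson with mild extra variance (at depth 300, variance ≈ 1.3 × mean) |
| `baseline_sigma`, `library_sigma` | 0.25 | moderate lognormal spread of per-variant expression and per-oligo synthesis abundance |
| `effect_min` | 0.1 | matches the caller's effect-size floor, so "functional" truth is callable in principle |
| `pcr_duplication_rate` | 1.0 | duplicates off by default; tests enable them explicitly |
| `error_rate` | 0.0 | errors off by default; round-trip tests rely on the clean path |
| `utmb_hazard_coef` | 0.3 | mild survival link; large enough to detect in a 200-patient cohort only when amplified |

## Numerical choices

- Rate fits maximize over `log r` with `scipy.optimize.minimize_scalar`
  (bounded, ±5 log units around the Poisson estimate), avoiding positivity
  constraints and scale issues.
- NB log-likelihoods switch to Poisson below α = 1e-12 to avoid overflow of
  `1/α`.
- The dispersion search is bounded to `[1e-8, 10]` on the log scale with
  `xatol = 0.05` (α enters the test only through a variance inflation, so
  5 % log-scale accuracy is ample).
- BH correction, proportions z-test, Fisher/KS/rank-sum/hypergeometric, and
  log-rank statistics are delegated to statsmodels, scipy, and lifelines;
  the package's own numerics are limited to what is assay-specific.
- Quantile normalization computes tie-averaged ranks once per replicate
  (`scipy.stats.rankdata`), then interpolates half-ranks as the mean of the
  neighboring target values.

## Limitations

- The NB test treats observed DNA counts as a fixed exposure; DNA
  measurement noise is not propagated (the simulator makes the matching
  assumption, and the acceptance suite shows the pair is calibrated — this
  is a modeling choice, not a validated property of real libraries).
- A single shared dispersion cannot capture variant-specific technical
  variance (e.g., secondary-structure-dependent RT efficiency).
- The read matcher assumes fixed-length, perfectly registered reads; it
  does not handle indels within reads or adapter read-through.
- The permutation-enrichment p is a normal approximation to a discrete
  count; see the calibration caveat above.
- Survival analysis is limited to two-group log-rank comparisons; no
  covariate adjustment (Cox regression is out of scope).
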