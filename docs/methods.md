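# Methods

This document records the generative model behind `cffrag.simulate`, the
statistical methods in the analysis modules, and the rationale for every
non-obvious default. Parameter values were chosen a priori from power
analyses on pilot seeds (≥1000) that are disjoint from the seed panels used
by the end-to-end tests (0–19); no default was adjusted after running on
the test seeds.

## 1. Generative model

### Genome

`build_genome_model(GenomeConfig)` lays out a small synthetic genome
(default 2 × 2 Mb):

- **Subcompartment bins.** Non-overlapping 100-kb bins, each labelled
  A1/A2/B1/B2/B3 with a balanced round-robin assignment shuffled by the
  seed, mimicking Hi-C subcompartment annotations.
- **Genes.** Non-overlapping gene bodies with a TSS and TTS, random
  strand; on the minus strand the TSS is the higher coordinate, so
  "downstream" always means the transcription direction. Genes keep a
  margin from chromosome ends so 10-kb WPS tracks and ±2-kb metaprofiles
  never run off the sequence.
- **CTCF sites** placed away from genes.
- **Repeat copies.** L1HS copies (consensus 6,019 bp, some 5′-truncated:
  a nonzero consensus offset) and AluY copies with lengths on both sides
  of the dimeric 280–320 bp range, each with strand and consensus
  coordinates.

### Protection track

For each group a per-base "protection" intensity is composed
multiplicatively over a flat baseline:

1. **Compartment baseline** — each 100-kb bin is scaled by the group's
   weight for its label (`compartment_weights`).
2. **Nucleosome-depleted regions** — Gaussian dips at every TSS, TTS and
   CTCF site; depth `ndr_depth` ∈ [0, 1] (1 removes all protection at the
   site center).
3. **Phased nucleosome arrays** — a cosine with 196-bp spacing over the
   10 kb downstream of each TSS (transcription direction) and flanking
   each CTCF site. CTCF arrays use the group's `phasing_amplitude`
   directly; gene arrays use amplitude
   `phasing_amplitude × (1 − e_g)` where `e_g` is the gene's
   mixture-weighted expression, log2(x+1)-transformed and min–max scaled
   to [0, 1] across genes. Highly expressed genes in the contributing
   tissues therefore lose phasing, which is the signal the
   tissue-of-origin analysis reads out. The log transform is used because
   raw lognormal expression is dominated by outliers: without it the
   amplitude map collapses almost all genes to "fully phased".
4. **Repeat 5′ protection** — the 5′ portion of each repeat copy is scaled
   by `repeat_5p_weight`.

### Fragments

Fragment midpoints are drawn in proportion to the protection track;
lengths come from a truncated normal (mean 170, SD 10, bounds [100, 400]),
matching the chromatosomal ~166–175 bp mode of plasma cfDNA. Sampling is
fully seeded; `derive_sample_seed` gives each sample an independent
stream, and `CohortTruth` serializes every group parameter and per-sample
seed.

### Tissue expression and mixtures

`simulate_tissue_expression` draws a tissues × genes table: a tight
lognormal background (σ = 0.05) plus disjoint marker blocks — with the
default `marker_fraction` = 0.2 and 5 tissues the blocks partition all
genes — boosted 12-fold in their tissue. Tight background and strong
disjoint markers are required because the min–max scaling in the
amplitude map amplifies within-block noise by the inverse of the
expression range.

Default group mixtures implement a two-level design: the focal (last)
tissue has base weight 0.75/n (0.15 at n = 5) in the young/healthy
groups, and the remaining tissues form an exactly equal-weight "pack".
In the old/unhealthy groups the focal weight is doubled and the mixture
renormalized. Two constraints fix these numbers:

- Doubling only lifts the focal tissue above the pack if its base weight
  exceeds 1/(2n − 1); 0.15 leaves comparable margins below the pack
  before doubling (0.0625) and above it after (0.076).
- The pack weights are kept *exactly* equal on purpose: every unplanted
  tissue's rank rises in expectation when the focal tissue drops to rank
  1 (rank displacement is zero-sum), and any deterministic pack ordering
  would turn that displacement into a deterministic — hence falsely
  "significant" — shift of one specific unplanted tissue. Equal weights
  spread the displacement as exchangeable noise, which is the
  false-positive floor for this design.

### Default group parameters

| group          | A1 / A2 / B1 / B2 / B3 weight | ndr_depth | phasing amp | repeat 5′ | focal weight |
|----------------|-------------------------------|-----------|-------------|-----------|--------------|
| young          | 1.20 / 1.10 / 1.40 / 0.80 / 0.60 | 0.45 | 0.50 | 1.00 | 0.15 |
| healthy_cent   | 1.15 / 1.10 / 1.33 / 0.87 / 0.67 | 0.55 | 0.46 | 0.85 | 0.15 |
| old            | 1.08 / 1.05 / 1.28 / 0.93 / 0.73 | 0.65 | 0.42 | 0.70 | 0.26 |
| unhealthy_cent | 1.00 / 1.04 / 1.22 / 0.97 / 0.79 | 0.75 | 0.38 | 0.70 | 0.26 |

The trends encode the biology the analyses probe: with age and
deteriorating health, euchromatic (A1) and facultative-heterochromatin
(B1) signal falls while constitutive/lamina-associated heterochromatin
(B2/B3) rises, promoter NDRs deepen, nucleosome phasing attenuates, and
repeat 5′ protection drops.

## 2. Analysis methods

### Fragment filtering (`io.filter_fragments`)

Removes mitochondrial and sex-chromosome fragments, MAPQ-0 and
duplicate-flagged records; soft-clipped fragments are kept only when the
aligned span is ≥ `min_aligned` (default 75 bp). Filtering is idempotent
and commutes with interval masking; `downsample` draws a seeded uniform
subset preserving order.

### Subcompartment signal (`compartments`)

Fragments are assigned to 100-kb bins by midpoint. Size factors use
median-of-ratios normalization: per-bin geometric-mean reference over
samples, per-sample median of count/reference ratios, rescaled to
geometric mean 1. When no bin is positive in all samples the code falls
back to library-size factors with a warning. Group log2 fold changes are
computed on normalized means with a 0.5 pseudocount.

The mixed model fits `y(bin, sample) = β_group + u_bin + ε` on
log2(normalized count + 0.5) by a conjugate Gibbs sampler (vague normal
priors on β, inverse-gamma(0.001, 0.001) on both variances; 13,000
sweeps, 3,000 burn-in, thinning 10 → 1,000 retained draws; split-chain
diagnostic flagged above 1.1). A group difference is "significant" when
the central 95% credible interval of β_a − β_b excludes zero.
`min_bins = 10` guards against fitting a bin-level random intercept on
too few bins; the default 2 × 2 Mb genome has 8 bins per label, so
compartment posteriors need a ≥ 2 × 3 Mb genome (12 bins per label) —
a problem-size requirement, not a tuned threshold.

### Metaprofiles (`metaprofile`)

Strand-aware average per-base coverage around anchors (TSS/TTS strand
from the gene, CTCF unstranded), offsets −2,000…+2,000. The headline
statistic is the mean over ±1,500 bp; replicate dispersion is the CV (%)
of per-replicate window means; group comparisons use Kruskal–Wallis with
Dunn post hoc on the per-replicate window means.

### Repeat consensus coverage (`repeats`)

Fragments overlapping a repeat copy are projected into consensus
coordinates (strand-aware, honoring 5′-truncation offsets) and coverage
is divided, per consensus position, by the number of copies whose span
covers that position (copy averaging). Ambiguous placements deposit
1/k weight for k candidate copies; total deposited weight is conserved
exactly. Profiles are normalized per million fragments; the L1HS summary
is the mean over consensus positions [0, 668) (the 5′UTR containing the
internal promoter), and AluY profiles are restricted to dimeric copies
(length 280–320 bp inclusive).

### Tissue of origin (`tissue`)

- **WPS.** At position p with window w = 120: fragments spanning the whole
  window [p − w/2, p + w/2) count +1; each fragment endpoint inside the
  window counts −1. Computed per gene over the 10 kb downstream of the
  TSS in transcription direction.
- **Detrending.** Centered running-median (window 1,000 bp, edge-truncated)
  subtraction, then mean removal.
- **Period spectrum.** FFT intensities |X_k|²/N² indexed by period
  N/k, retained over [120, 280] bp; `binned()` averages intensities into
  integer-period bins; the band statistic is the mean intensity over
  periods in [193, 199] bp.
- **Normalization.** `band_intensity_per_gene` divides the band intensity
  by the track's total spectral power (Parseval: Σ|X_k|²/N² = Σx²/N).
  WPS amplitude scales linearly with local coverage, so the raw band
  intensity carries a squared per-gene coverage factor (a fixed gene
  effect set by the compartment baseline) that is unrelated to phasing;
  at high depth it correlates by chance with tissue expression profiles
  and systematically distorts the tissue ordering. Dividing by total
  power cancels the coverage factor exactly and leaves a scale-free
  periodicity fraction.
- **Ranking.** Per-gene band intensities are Pearson-correlated with each
  tissue's log2(expression + 1); because expressed genes lose phasing the
  correlation is negative for contributing tissues, and tissues are
  ranked by ascending r (rank 1 = most negative = strongest inferred
  contributor). Zero-variance tissues are excluded and reported.
- **Rank-shift test.** Per tissue, Kruskal–Wallis across groups on the
  per-sample ranks, Dunn post hoc for pairs. **BH scope:** adjustment is
  applied across the group pairs within each tissue. The alternative
  scopes were analyzed before any end-to-end run: adjusting across all
  tissues × pairs makes even a perfectly deterministic planted shift
  unattainable at FDR 0.05 with small integer-rank cohorts (best
  attainable adjusted p ≈ 0.068), while adjusting across tissues within
  one group pair inflates the per-tissue false-positive rate ≈ 4.5% per
  cohort. The within-tissue family answers the question actually asked —
  "is this tissue's rank shifted, and between which groups?" — and gives
  a deterministic planted adjusted p of 0.0285 with ≈ 1% per-cohort
  false-positive rate under the default design.

### Statistics kernels (`stats`)

Kruskal–Wallis (mid-ranks, tie correction), Dunn z tests with the tie
term T = Σ(t³ − t)/(12(N − 1)) and BH adjustment across pairs,
Benjamini–Hochberg step-up FDR, Levene's test (median-centered
Brown–Forsythe by default), Pearson r,
coefficient of variation, and the Gibbs sampler above are implemented
directly; `scipy.stats` is used only for distribution tail probabilities
(χ², F, normal). The test suite cross-checks against
`scipy.stats.kruskal` and `scipy.stats.levene` on random inputs.

## 3. End-to-end test problem sizes

All designs were frozen from pilot runs on seeds ≥ 1000 before the
pre-registered panels (seeds 0–19) were touched:

- **Periodicity:** 1 Mb genome, 10 genes, one group with full phasing at
  every gene (empty mixture), depth 100k, summed binned spectra; peak
  period must land in [193, 199] in ≥ 19/20 seeds.
- **Tissue rank shift:** default genome/groups, 3 replicates, depth 200k
  per sample; 20 cohorts; planted tissue flagged in ≥ 18/20, no unplanted
  tissue in > 1/20.
- **Compartments:** 2 × 3 Mb genome (12 bins/label), young vs old,
  3 replicates, depth 200k. Note that median-of-ratios normalization
  makes fold changes relative: A2 (1.10 → 1.05, both near the
  across-label median) has an expected log2FC near zero, so only
  A1/B1 (decrease) and B2/B3 (increase) carry testable directions.
- **NDR ordering:** ndr_depth 0.1/0.375/0.65/0.925, 24 replicates per
  group, depth 140k; groups are simulated sequentially and released to
  bound peak memory.
- **Repeat 5′:** repeat_5p_weight 1.0/0.85/0.7/0.55, 3 replicates,
  depth 100k.

## 4. Limitations

- The genome, expression and protection models are deliberately small and
  stylized; absolute effect sizes are not calibrated to human plasma
  data, only the directions and orderings the pipeline is designed to
  detect.
- Tissue ranking assumes the expression table covers the true
  contributing tissues; correlations are interpretable only relatively.
- The random-intercept model treats bins as exchangeable within a
  subcompartment and ignores spatial autocorrelation along chromosomes.
- Rank-shift inference on n = 3 per group operates at the resolution
  limit of rank statistics; the minimum attainable within-tissue adjusted
  p (0.0285 for the young/old contrast among four groups) leaves little
  headroom below FDR 0.05.
- SAM parsing accepts coordinate-sorted, proper-pair fragments; it is not
  a general-purpose alignment validator.
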