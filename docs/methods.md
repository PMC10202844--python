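# Methods

## Study design and data model

The pipeline targets transcript-level RNA-seq counts from a two-group
longitudinal design: control (CON) versus maternal nutrient reduction
(MNR), sampled at gestational days 90, 120, 140 and 165 with 8 + 8
animals per group at 90 and 165 dG and 6 + 6 at 120 and 140 dG (56
samples), sexes balanced within group.  Counts are transcript × sample
nonnegative integers with a many-to-one transcript → gene-symbol map.
Arbitrary positive gestational days and group sizes are accepted as long
as the model matrix below has full rank.

## Time encoding

Raw gestational day and its square are nearly collinear over 90–165 dG,
so time enters the model as `t = (dG − midrange)/halfrange`, mapping the
design onto [−1, 1] (t = (dG − 127.5)/37.5 for the study design).  The
significance of the interaction contrasts is invariant to this affine
re-encoding in combination with the other model terms, but coefficient
*magnitudes* are specific to it; output headers record the mapping.
Reference levels are CON and female; sex and group are coded 0/1.  A
single-timepoint design makes t and t² collapse into the intercept and
raises a design error naming the collinear columns.

## Differential expression

1. **Filtering.** Transcripts whose maximum count across all samples is
   below 15 are removed (boundary: max = 15 is kept).  Low-abundance
   transcripts otherwise destabilise the mean–variance trend.
2. **Precision weights.** log2-CPM is computed as
   `log2((c + 0.5)/(N + 1) · 1e6)` with `N` the per-sample library size
   (plain library-size normalisation; scaling-factor normalisation is a
   config option, off by default).  Per transcript, an unweighted fit on
   the model matrix yields a residual sd; a lowess curve (span 0.5,
   configurable) of sqrt(sd) against mean log2 count is interpolated at
   each observation's fitted log2 count, and the weight is the curve
   value to the power −4.  Interpolation clips to the curve's range at
   the extremes, so weights are always positive and finite.
3. **Weighted least squares.** β = (XᵀWX)⁻¹XᵀWy per transcript with the
   7-column matrix [1, sex, t, t², group, group·t, group·t²]; residual
   variance s² = weighted RSS/(n − 7) on d = n − 7 df.  Numerically
   singular transcripts are flagged and excluded downstream.
4. **Empirical-Bayes moderation.** The prior (d₀, s₀²) is estimated by
   moment-matching log s² to a scaled F distribution via digamma/
   trigamma equations (trigamma inverted by Newton iteration);
   s̃² = (d₀s₀² + d·s²)/(d₀ + d) and moderated t = β_c/(u_c·s̃) on
   d₀ + d df.  When the variances show no excess spread, d₀ is flagged
   infinite and s̃² = s₀² everywhere.  Transcripts with exactly zero
   residual variance receive the smallest positive s² observed and are
   flagged.
5. **Contrasts and multiplicity.** The MNR, MNR×t and MNR×t² columns are
   tested; Benjamini–Hochberg FDR is applied within each contrast
   separately.  After FDR, transcripts sharing a gene symbol are reduced
   to the most significant one (ties: larger |t|, then lexicographic
   transcript id) — deduplication after correction, preserving the
   adjusted values.  Candidates: FDR < 0.1 in any contrast (priority
   set), unadjusted p < 0.001 (network set); the two criteria are
   reported independently, neither implies the other.

## Splice-variant diversity

The per-gene, per-sample statistic is the number of distinct isoforms
with ≥ 1 read (threshold configurable), computed on the **unfiltered**
matrix: the low-abundance isoforms removed by the expression filter are
precisely the plausible carriers of a diversity change.  Genes with a
single annotated isoform are retained (their count is 0/1-valued); a
config flag can exclude them.

At each gestational day, a log-link Poisson GLM models the count on
group adjusting for sex (sex is dropped if constant within the
timepoint), fitted by iteratively reweighted least squares (tolerance
1e−8 on the coefficient change, 50 iterations maximum), vectorised
across genes.  Wald standard errors come from the inverse Fisher
information at the final estimates.  Unbounded fits — e.g. a group with
all-zero counts — are flagged non-converged and excluded from the
meta-analysis; genes converging at only one of the meta timepoints are
combined on that one (single-study identity).

Per-gene estimates at 120 and 140 dG are combined by fixed-effect
inverse-variance meta-analysis: weights SE⁻², combined β̂ = Σwβ/Σw,
SE = (Σw)^(−1/2), Z = β̂/SE, two-sided normal p.  Fixed-effect (not
random-effects) combination is the right estimator for two studies from
the same experiment.  Per-timepoint tables carry their own BH FDR
(default significance 0.05), as does the meta table.

The **global shift test** summarises the meta-Z distribution: mean,
moment skewness g₁ = m₃/m₂^{3/2} (the biased estimator), and a
two-sided one-sample t-test of mean 0, reported for all genes and for
the unadjusted-p < 0.05 subset.  All tests are two-sided.

## MCODE clustering

Interactions are consumed as a pre-exported edge list (self-loops
dropped, duplicates collapsed, confidence scores optionally filtered but
ignored for topology, matching the published tool's default behaviour).
Vertex weight = k × density of the highest k-core of the vertex's closed
neighborhood.  Complexes grow from the highest-weighted unassigned
vertex, admitting neighbors with weight ≥ seed weight × (1 − VWP),
VWP = 0.2; each vertex joins at most one complex; the haircut step
repeatedly prunes members with fewer than two intra-complex connections
(fluff post-processing is omitted — off by default in the published
tool).  Score = density × size; ties broken lexicographically so output
is deterministic.  Admission: score strictly > 4, at least 7 nodes
("more than six"), and ≥ 1 member gene with DE FDR < 0.1; genes missing
from the DE table are non-qualifying.  Every complex is reported with
its per-criterion flags.

## Synthetic-data generator

`SimulationSpec` defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_genes | 2000 | genes |
| mean_extra_isoforms | 3.0 | isoforms/gene = 1 + Poisson(3), mean ≈ 4 |
| major_log_mean / sd | 5.0 / 1.2 | log2 abundance of the expressed isoform |
| minor_log_mean / sd | 1.0 / 1.8 | log2 abundance of minor isoforms |
| nb_dispersion | 0.3 | NB dispersion φ (var = μ + φμ²), BCV ≈ 0.55 |
| bio_log_sd | 0.7 | shared gene×sample biological log2 effect |
| lib_size_log_sd | 0.1 | log-normal library-size factors |
| frac_de / de_effect | 0.05 / 1.0 | fraction of genes with a quadratic effect; peak log2 size |
| frac_splice / splice_effect | 0.10 / 0.5 | fraction of genes with extra isoform diversity; log rate increase |
| affected_timepoints | (120, 140) | where diversity is switched on |
| sex_effect | 0.1 | additive log2 sex effect |

Counts are negative-binomial.  Each gene has one well-expressed major
isoform and low-abundance minors — mirroring real transcriptomes, where
most annotated isoforms sit near the detection limit — so the expression
filter and the presence statistic both see realistic inputs.  The
dispersion and biological-noise defaults are set at the upper-moderate
range plausible for outbred primates; they deliberately make
per-transcript power modest (a handful of detections out of 100 injected
effects at FDR < 0.1), which is the regime the study itself operates in.

The quadratic effect is `de_effect · 4(dG−90)(165−dG)/75²` added to the
MNR log2 mean of a DE gene's major isoform: exactly zero at 90 and
165 dG, maximal (= de_effect) at 127.5 dG, symmetric.  In the centered
parameterisation this equals `de_effect·(1 − t²)·group`, so it loads on
the group and group·t² columns and leaves the linear interaction null.

Isoform diversity is injected by *switching*: latent isoforms with mean
exactly zero everywhere except MNR samples at the affected timepoints,
where they turn on at log2 mean 3.  Their number is chosen from the
gene's expected detected-isoform count so that detection rises by a
factor ≈ exp(splice_effect).  Because the off state is exactly zero,
expected detected-isoform counts are *identical* between groups
everywhere else.  DE and splice gene sets are drawn disjointly; note
that switching mechanically makes the latent transcripts themselves
differentially expressed, so expression-level evaluations exclude
splice-gene transcripts from false-positive accounting.

One master seed is split into independent child streams (structure,
assignment, counts, library sizes), so generation is reproducible and
stage-stable.

### What the generator does not emulate

Read-level sampling, mapping ambiguity and EM quantification noise,
exon/junction structure, correlated isoform usage within a gene, batch
effects, and gene–gene expression correlation.  Passing tests
demonstrate internal statistical correctness of the pipeline under its
own assumptions, not performance on any real dataset.

## Calibration properties and known limitations

- **DE p-values are calibrated.** On null simulations at the study
  design, all three contrasts' p-values are uniform (KS p ≫ 0.01 at
  ~4000 transcripts) and no gene reaches FDR < 0.1.
- **Splice Wald p-values are conservative, not uniform.**  A detected-
  isoform count is a bounded sum of Bernoulli indicators; its variance
  is strictly below its mean (var/mean ≈ 1 − p̄ plus a mixing term), so
  the Poisson working model over-states the sampling variance and the
  Wald Z-scores are shrunk (sd ≈ 0.4–0.75 across realistic settings).
  Small-p tail rates are therefore *below* nominal — the safe direction,
  asserted in the tests — but strict KS-uniformity is unattainable: even
  with exactly-Poisson counts, small-sample Wald discreteness at 6 + 6
  samples leaves KS D ≈ 0.035 at 2000 genes.
- **The global shift t-test is exact only at equal sequencing depth.**
  Library-size variation shifts every gene's detection probability in
  the same direction within a sample, correlating the per-gene meta
  Z-scores; the one-sample t-test assumes independence and becomes
  anti-conservative (measured type-I ≈ 0.2 at 10% depth variation,
  vs 0.05–0.06 at equal depth).  This is a genuine caveat of applying
  the unadjusted Poisson/meta/t-test cascade to presence counts: a
  strongly significant global shift can be mimicked by a group
  imbalance in sequencing depth.  Interpreting the statistic on real
  data requires depth-balanced groups or an offset-adjusted model
  (out of scope here, which follows the original unadjusted cascade).
- The moderated-t prior recovery is accurate to well within 15% at
  5000 transcripts; d₀ → 0 reproduces ordinary t exactly.
- MCODE reproduces the structural cases exactly (a K₇ scores 7; two
  disjoint K₅s score 5 each; admission boundaries are strict).

## Numerical choices

- Weighted LS and the batched IRLS solve per-gene normal equations with
  `numpy.linalg.solve`; singular systems fall back to per-item handling
  and are flagged rather than fixed up silently.
- IRLS linear predictors are clipped to ±30 to avoid overflow; estimates
  with |β| > 20 are treated as separated (non-converged).
- Lowess trend x-values are deduplicated before interpolation; a
  degenerate (constant-mean) trend falls back to a flat curve.
- BH FDR delegates to statsmodels' step-up implementation; NaN inputs
  are rejected rather than propagated.
- TSV writers use `%.10g` floats and fixed line endings, so identical
  seeds give byte-identical outputs (asserted end to end).

## Problem sizes used by the checks

Oracle-equivalence checks run on randomized instances of ≤ 100 items or
≤ 13-node graphs.  Calibration and recovery run at the study design with
2000 genes (≈ 8000 transcripts); replicate-level calibration uses 50
seeds at 400 genes, and power monotonicity 5 seeds per effect size at
500 genes.  These sizes give stable rates while keeping the whole suite
fast.
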