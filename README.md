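# mnrseq

Transcriptome analysis of gestational trajectories under maternal nutrient
reduction (MNR): differential expression with a quadratic group-by-time
interaction, a splice-variant-diversity statistic, and MCODE network
clustering — for transcript-level RNA-seq counts from two-group
longitudinal designs.

## The scientific problem

In a nonhuman-primate model of moderate maternal undernutrition, fetal
liver tissue is sampled at several gestational days (90, 120, 140 and
165 dG; term ≈ 185 dG) from control (CON) and nutrient-reduced (MNR)
pregnancies.  Expression differences between groups do not grow
monotonically: they peak mid-gestation and vanish again before term.
`mnrseq` implements the three analyses this design calls for:

1. **Differential expression** (`DifferentialExpression`).  For each
   transcript, log2-CPM values are modelled by weighted least squares on

   `y = β0 + β1·sex + β2·t + β3·t² + β4·group + β5·group·t + β6·group·t²`

   where `t` is gestational day centered and scaled to [−1, 1]
   (t = (dG − 127.5)/37.5 for the design above).  Observation-level
   precision weights come from a fitted mean–variance trend (the voom
   approach); residual variances are moderated by empirical Bayes
   (s̃² = (d₀s₀² + d s²)/(d₀ + d), with d₀ and s₀² estimated by
   moment-matching log s² to a scaled F distribution).  Moderated t
   statistics are reported for three contrasts — the MNR main effect
   (β4), the linear interaction (β5) and the quadratic interaction (β6),
   which captures mid-gestation-peaked divergence — each with its own
   Benjamini–Hochberg FDR.  Transcripts are then deduplicated to one per
   gene symbol (most significant kept) and candidate genes selected at
   FDR < 0.1 (priority set) or unadjusted p < 0.001 (network set).

2. **Splice-variant diversity** (`SpliceDiversity`).  For each gene and
   sample, the number of distinct isoforms with at least one read is
   counted (on the *unfiltered* matrix).  At each gestational day a
   log-link Poisson regression models that count on group, adjusting for
   sex; the 120/140 dG estimates are combined per gene by fixed-effect
   inverse-variance meta-analysis (Z = β̂/SE, weights SE⁻²).  A positive
   shift of the meta-Z distribution — summarised by its mean, moment
   skewness g₁ = m₃/m₂^{3/2}, and a one-sample t-test against zero —
   indicates globally increased isoform diversity in the MNR group.

3. **Network clustering** (`mnrseq.mcode`).  MCODE molecular-complex
   detection on a supplied gene-interaction edge list (vertex weight =
   k × density of the highest k-core of the closed neighborhood; seeded
   expansion with vertex-weight percentage 0.2; haircut on).  Clusters
   are admitted when score > 4, size ≥ 7 nodes, and at least one member
   gene has DE FDR < 0.1.

A synthetic-data generator (`mnrseq.simulate`) reproduces the statistical
structure these analyses assume — negative-binomial transcript counts
with a dominant isoform plus low-abundance minors, shared per-sample
biological variability, library-size factors, mid-gestation-peaked
expression effects, and isoform switching — with a truth table for
benchmarking.

## Worked example

```python
import mnrseq as m

spec = m.SimulationSpec(n_genes=1000, seed=42)
counts, design, truth = m.simulate_counts(spec)

de = m.DifferentialExpression(counts, design).fit()
print(de.summary())

sp = m.SpliceDiversity(counts, design).fit()
print(sp.summary())
```

prints

```
Differential expression summary
  transcripts tested: 2331 (of 4173 input)
  residual df: 49; prior df d0=12.8, s0^2=0.878
  MNR: 125 genes at FDR<0.1, 104 at p<0.001
  MNR_x_time: 1 genes at FDR<0.1, 3 at p<0.001
  MNR_x_time_sq: 121 genes at FDR<0.1, 104 at p<0.001

Splice-variant diversity summary
  genes: 1000; meta timepoints: [120, 140]
  90 dG: 0 genes at FDR<0.05
  120 dG: 0 genes at FDR<0.05
  140 dG: 0 genes at FDR<0.05
  165 dG: 0 genes at FDR<0.05
  meta: 5 genes at FDR<0.05
  global shift: mean Z = 0.279, skewness = 2.11, t-test p = 5.22e-25 (n=1000)
```

Reading this: of 4173 simulated transcripts, 2331 pass the low-count
filter (maximum count across samples ≥ 15).  The injected mid-gestation
effects surface in the quadratic interaction contrast (121 genes at
FDR < 0.1) and its aliased main effect, while the linear interaction
stays near-null — the signature pattern of divergence that peaks at
120–140 dG and closes again by 165 dG.  The splice stage finds a
right-skewed meta-Z distribution (mean 0.279, skewness 2.11): MNR samples
express more isoforms per gene at the affected timepoints.

The same pipeline runs from the shell:

```bash
mnrseq simulate --outdir fixture --n-genes 1000 --seed 42
mnrseq de     --counts fixture/counts.tsv --design fixture/design.tsv --out-prefix out/de
mnrseq splice --counts fixture/counts.tsv --design fixture/design.tsv --out-prefix out/sp
mnrseq mcode  --edges edges.tsv --de-table out/de_deduped.tsv --out out/mcode.tsv
mnrseq run-all --outdir out --seed 42          # everything, plus a manifest
```

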