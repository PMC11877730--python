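# Methods

## The measurement model

A methylation array reports, per CpG and sample, a beta value in [0, 1]:
the fraction of methylated signal. XX samples carry an active (Xa) and an
inactive (Xi) X chromosome whose methylation states differ; the array
averages them, so the package treats an XX measurement at an X-linked CpG
as `(m_Xa + m_Xi)/2` and an XY measurement as `m_Xa`. The sex difference
of region means, `Δβ = mean_XX − mean_XY`, therefore reads out half the
Xi-specific methylation: Δβ = 0.5 for a fully methylated Xi promoter over
an unmethylated Xa, Δβ = 0 when the two alleles match. All analyses run
on beta values directly (no M-value transform): every downstream
quantity — region means, Δβ, rank tests — is defined on the beta scale,
and the effect-size gates are stated in beta units.

## Annotation rules

Coordinates are 0-based half-open internally. BED tracks are read
verbatim; probe manifests follow the array convention (1-based) and are
shifted by −1 on ingest.

- **Promoter–gene pairing**: a promoter-like element (PLS) pairs with a
  gene when the element overlaps the closed window [TSS − 200, TSS + 200].
  Interval overlap (not edge distance) matches the ENCODE PLS definition.
- **Enhancer–gene pairing**: a proximal enhancer-like element (pELS)
  pairs with genes whose TSS lies in [start − 2000, end + 2000), half-open
  on the right so boundary behaviour is deterministic.
- **TSS windows** are strand-aware upstream bands: TSS200 covers 1–200 bp
  upstream of a TSS, TSS200-1500 covers 201–1500 bp upstream. A CpG in
  the TSS200 band of any gene is labelled TSS200 (the closer band wins);
  the alternative — counting a CpG in both bands for different genes in
  both window analyses — would only enlarge the TSS200-1500 set and is
  not implemented.
- **CpG-island density** follows the Weber length/GC/obs-exp criteria
  with strict inequalities: HC iff length > 500 bp AND GC > 0.55 AND
  obs/exp > 0.75; else IC iff length > 200 bp AND GC > 0.50 AND
  obs/exp > 0.48; else none. Every HC island also satisfies the IC
  clauses, so the classifier tests HC first.
- Multi-gene memberships are kept as sets; gene-level summaries expand to
  one region per (kind, gene).

## Probe QC and sex inference

A probe is dropped when the fraction of samples in which it fails QC
(detection p > 0.01, bead count < 3, or a missing beta) strictly exceeds
5% (a probe failing in exactly 5% of samples is retained), or when it is
in a mask list (polymorphic / cross-hybridising probes) or absent from a
mappability whitelist. The filter is idempotent and monotone in the
fraction threshold.

Sex is inferred from median X and Y probe intensities normalised by the
autosomal median. Samples are split by 2-means on (x_norm, y_norm) with a
fixed seed; the cluster with higher mean y_norm is XY. When the two
cluster centres' y_norm differ by less than 0.2 — far below the ~0.8 gap
between genuine XX and XY clusters, indicating a single-sex cohort — the
routine falls back to a fixed threshold (y_norm > 0.5 ⇒ XY) and warns.
Mismatches against reported sex are flagged, never auto-excluded.
Genotype-contamination screening is out of scope; a pre-computed
exclusion flag on the sample sheet is honoured at load.

Missing beta values are ignored pairwise in all means and medians; a
region's per-sex group mean weights samples equally (not by CpG
coverage). Regions with zero covered CpGs are omitted with a logged
count.

## XCI calling and the correlation battery

Allele balances are folded to `max(b, 1−b)` on ingest, so matrices on the
raw [0, 1] scale are accepted and all thresholds are stated on the skew
scale [0.5, 1]. Per gene: `proportion_subject` is the fraction of
informative (non-missing) samples with balance ≥ 0.8; the category is
*subject* iff proportion > 0.7 and median balance ≥ 0.8, *escape* iff
proportion < 0.3 and median ≤ 0.75, else *variable*. Genes with fewer
than `min_informative` (default 5) informative samples are reported
uncalled; the floor is configurable and recorded in the run manifest.

The correlation battery computes Pearson correlations between a DNAme
metric (mean XX beta, median XX beta, or Δβ) and an XCI outcome
(proportion subject or median balance) over genes present in both inputs,
under four filters: all genes; excluding genes with XY promoter beta
> 0.1 (methylation on the Xa obscures the Xi readout); only CpG-island
(HC/IC) promoters; and both. One BH-FDR family spans all combinations
requested in a single battery invocation, and the family membership is
recorded in the output; computing FDR per analysis block instead would
only rescale the adjusted values within blocks.

Category comparisons use two-sided Wilcoxon rank-sum tests (exact null
distribution when both groups have ≤ 12 tie-free observations, otherwise
the normal approximation with tie correction), BH-adjusted across the
three category pairs. Cross-tissue concordance reports the 3×3
cross-classification, the fully discordant (escape↔subject) gene list,
and a chi-square on the marginal 2×3 counts-by-tissue table — the
marginal comparison is what "similar numbers of genes per category
between tissues" tests; the full cross-table is exposed for inspection.

## PCA, PC-PR2 and per-CpG models

PCA centres and scales each CpG to unit variance (missing values imputed
by the CpG mean first; zero-variance CpGs dropped with a count), then
takes a dense SVD of the samples × CpGs matrix. The decomposition is
deterministic and the sign convention (largest-magnitude loading
positive) makes scores reproducible. Standardised scores (unit variance
per component) support cross-dataset comparison. PC ~ covariate screens
fit one simple linear model per (component, variable) pair — categorical
variables one-hot encoded with k−1 indicators, R² is the model R² — with
BH FDR across the whole family.

PC-PR2 keeps the smallest number of leading components whose cumulative
variance fraction reaches the threshold (default 0.9). For each kept
component the score is regressed on all covariates and on all-minus-one;
the covariate's per-component partial R² is
`(RSS_reduced − RSS_full)/RSS_reduced`, and its overall statistic is the
eigenvalue-weighted mean across kept components, in percent. Collinear
covariates (design condition number above 1e8) raise an error naming the
most correlated pair.

Per-CpG models are plain OLS of beta on the predictor (gestational age in
weeks) plus optional adjustment covariates, run sex-stratified by the
caller; no empirical-Bayes variance moderation is applied, because the
target analysis is a global null where the effect-size gate dominates
and per-CpG OLS keeps the slope interpretable. A CpG is significant only
when BH FDR < 0.05 **and** |slope| ≥ 0.03 beta units per week — the gate
is applied to the per-week slope, not the total span. Adjustment for
cell composition uses k−1 of the k compositional covariates (the six
cell proportions sum to one, as do the three ancestry coordinates), so
defaults use two ancestry coordinates.

## The synthetic-data generator

The generator emulates the study conditions the analyses assume, and its
defaults are fixed once:

- 200 X-linked genes with 3 promoter CpGs, 2 gene-body CpGs, one
  enhancer CpG each, plus 300 intergenic X CpGs and 200 autosomal CpGs;
  30 samples per sex.
- XCI category fractions (escape, variable, subject) = (0.10, 0.20,
  0.70): placental studies report subject-dominated distributions (on the
  order of 5%/10%/85% of assayable genes); escape and variable are
  upweighted slightly so a 200-gene study carries enough genes per
  category for the category comparisons.
- Xa promoter states ~ Beta(2, 30) (mean ≈ 0.06, unmethylated); Xi
  states by coupling mode. `somatic`: subject → Beta(30, 8)
  (mean ≈ 0.79), escape → Beta(2, 30), variable → a per-gene blend with
  propensity π_g ~ U(0.3, 0.7). `placenta`: a low Beta draw shifted down
  by `placenta_xi_depletion` (default 0.05 — the low draw is already
  near zero; a larger shift would pin everything at exactly 0) for all
  categories. `custom` blends the two with weight ρ. Degenerate Beta
  parameters (a = 0 → constant 0, b = 0 → constant 1) exist so the
  mixture arithmetic can be tested exactly.
- Intergenic CpGs are trimodal — modes near 0 (Beta(2, 30)), 0.5
  (Beta(50, 50), heterozygous-like) and 1 (Beta(30, 2)) with weights
  (0.4, 0.2, 0.4) — reproducing the X-linked beta distribution shape.
- PMDs cover 30% of intergenic/autosomal CpGs and shift both alleles
  down by 0.15.
- Bulk samples mix six cell types (Dirichlet concentrations proportional
  to placental means: syncytiotrophoblast-dominated) with per-CpG,
  per-cell-type beta offsets (sd 0.02) applied before mixing — the
  linear-mixing premise of reference-based deconvolution.
- Measurement noise is additive Gaussian (sd 0.05, array scale) clipped
  to [0, 1]. Truncation-by-clipping is simpler than a logit-normal and
  adequate for the rank-based and correlation analyses downstream; a
  logit-normal alternative would change tail behaviour only.
- Gestational ages are uniform on 8–42 weeks with `ga_effect = 0` by
  default: the no-trend placental null. Allele balances (XX samples
  only) come from folded Betas: subject → 0.5 + 0.5·Beta(8, 1)
  (median ≈ 0.95), escape → 0.5 + 0.5·Beta(1.2, 6) (median ≈ 0.57);
  variable genes mix the two per sample by π_g; 85% of gene × sample
  pairs are informative.
- Randomness flows through named streams (genes, methylation, cells,
  metadata, allele balance, noise) seeded independently from the master
  seed, so varying one component holds the others fixed.

What the generator does **not** emulate: raw probe intensities and
chemistry artefacts, probe-level technical failure structure (QC
matrices export as all-pass), within-placenta XCI skewing, imprinting,
read-level allele-specific expression, and spatial correlation along the
chromosome beyond the block structure of PMDs. Passing tests on this
generator therefore validate the statistical machinery and its
contracts — threshold logic, mixture arithmetic, variance attribution,
error control — not array-specific normalisation behaviour on real data.

## Problem sizes and experiment design

Validation experiments use: 200-gene / 60-sample studies for the
coupling analyses (20 seed replicates per mode); 5,000 CpGs × 100
samples for the gestational-age null (20 replicates) and power runs;
50 × 20 matrices for PC-PR2 oracle checks; and ~10⁴ random matrices for
classifier/oracle equivalence. These sizes give stable estimates of the
qualitative contrasts while keeping the whole suite fast.

The gestational-age power experiment spikes a slope of 0.05/week into
intermediate-methylation CpGs only (`intergenic_mode_probs = (0, 1, 0)`,
baseline beta ≈ 0.5). A slope of that size spans 1.7 beta units over
8–42 weeks, which no CpG can express linearly within [0, 1]; from
extreme baselines clipping attenuates the fitted slope below the 0.03
gate, so power is measured where the effect is expressible. With the
mid-range baseline the symmetric clipping leaves a fitted slope of
≈ 0.038/week and essentially complete power at n = 100.

## Numerical choices

- Strict vs inclusive thresholds follow the stated rules exactly:
  probe-failure fraction strictly greater than 5% drops; XCI proportion
  thresholds strict (> 0.7, < 0.3), median thresholds inclusive (≥ 0.8,
  ≤ 0.75); CGI criteria strict; differential windows require Δβ
  strictly above 0.20.
- Pearson correlations with a constant input are reported as NaN and
  excluded from the FDR family rather than erroring a whole battery.
- OLS slopes whose magnitude is below 1e-12 are snapped to zero so
  constant CpGs report slope 0, p = 1 instead of machine-epsilon noise.
- PCA rank truncation drops singular values below
  `S_max · max(n, p) · eps`.
- Window export clips at chromosome start with a flag; the background
  set (all processed CpGs) is always emitted alongside for external
  enrichment tools.

## Known limitations

- Sex inference assumes two well-separated intensity clusters; mosaic or
  aneuploid karyotypes (e.g. 45,X) will sit between clusters and are
  only surfaced via the mismatch flag.
- The XCI classifier treats samples as independent; clonal XCI skewing
  within a placenta violates this and is out of scope.
- PC-PR2 shares for small sample counts (n ≲ 20) are noisy: a pure-noise
  covariate can pick up ~10% by chance correlation with the leading
  components.
- The pipeline consumes pre-computed cell-composition, ancestry and
  epigenetic-age covariates as metadata; estimating them is out of
  scope.
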