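# Methods

This note records the statistical model the package implements, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical and design decisions that
were genuinely open.

## Phenotyping

IR status is derived from a standard OGTT (glucose load 1.75 g/kg,
capped at 75 g; samples at 0/30/60/120 min). Laboratory units are
mmol/l (glucose) and pmol/l (insulin); the indices use the conventional
mg/dl and µU/ml, with conversion constants 18.016 mg/dl per mmol/l and
6.945 pmol/l per µU/ml exposed as parameters because laboratories vary
slightly in the insulin conversion (6.0–7.175 depending on the assay
standard). WBISI uses the unweighted arithmetic mean of the four time
points (the original Matsuda definition), not trapezoidal weighting.

Classification requires *both* criteria jointly: HOMA-IR > 2.5 **and**
WBISI < 3 for IR+, neither for IR−. Both inequalities are strict, so
boundary values never classify as IR+. Subjects meeting exactly one
criterion are physiologically ambiguous; they are labelled
indeterminate and excluded from association testing rather than forced
into a group. This conjunction rule is a design choice: the reference
cohort's group means satisfy both criteria jointly in each group, but
the handling of discordant subjects is not otherwise determined, and a
disjunction would contaminate the control group with borderline cases.

## Array calibration

The red/green gain of a two-channel bead array differs systematically
between arrays and strips. The model is a single multiplicative red
factor per (strip, sample): k is the root of
mean_SNPs kR/(kR+G) = 1/2, found by bracketed bisection/Brent iteration
(the mean is strictly increasing in k, so the root is unique; it is
refined to ~1e-12). Calibration per (strip, sample) — rather than per
strip across samples — was chosen because the gain is a property of the
individual physical array.

Two consequences worth stating explicitly:

* The 0.5 target identifies the true inverse bias **exactly** only when
  the strip's true frequency spectrum is symmetric about 0.5 (e.g. when
  the B-allele assignment is random with respect to frequency, which is
  how arrays are manufactured). For an asymmetric spectrum the
  calibration still equalises the means — the scan is invariant to this
  because both groups share the same k bias structure.
* Multiplying all intensities by any constant leaves every downstream
  statistic unchanged (the ratio absorbs it); this scale invariance is
  a tested property.

Order of operations: calibrate → PAF → bead filter. The bead filter
(drop a SNP if any sample supports it with fewer than 4 beads) runs
after calibration, so the 0.5 target is taken over all SNPs with
signal; a SNP with missing PAF in *any* replicate is excluded entirely
to keep the replicate arithmetic balanced. Every excluded SNP appears
in exactly one exclusion report with a reason code (`missing` or
`low_beads`).

Replicate QC: PCA on the per-SNP-centred PAF matrix (scikit-learn);
PASS requires the largest within-group pairwise distance in the first
two components to be smaller than the smallest between-group distance.
With 3+3 replicates this is a deliberately blunt instrument — it
catches sample swaps and gross array failures, not subtle batch
effects.

## The pooled scan

For pools of n_t and n_c individuals (2n chromosomes each) the binomial
sampling variance of the frequency difference is
V = p̄_t(1−p̄_t)/(2n_t) + p̄_c(1−p̄_c)/(2n_c). The additional variance
from pool construction and array measurement is estimated from the
technical replicates as s²_t/k_t + s²_c/k_c (unbiased replicate
variance, scaled to the replicate mean). The test statistic
(p̄_t−p̄_c)²/(V + var_pool) is referred to χ²(1).

One test per SNP is computed from replicate means and pooled replicate
variances, rather than averaging nine pairwise replicate tests: the two
use the same information, but the single test is deterministic and has
a cleaner null reference. The 3×3 pairwise statistics remain available
as a diagnostic table (`PooledScanResults.pairwise_diagnostics`).

Known calibration property (measured by the test suite): with only 3
replicates per group the variance estimate carries 4 df, and plugging
it into a 1-df chi-square is slightly anti-conservative — the empirical
P < 0.01 rate under the null simulation is ≈ 0.011 rather than 0.010,
and the KS distance from uniformity is ≈ 0.005. Degenerate cases: a
SNP with zero total variance and zero difference scores χ² = 0, P = 1;
zero variance with a non-zero difference is flagged unstable, gets no
P-value, and is excluded from ranking (this cannot occur once any noise
source is active).

Ranking and windows: rank 1 is the smallest P; ties break by genome
order (natural chromosome order, position ascending) so ranks are
always a permutation. The window statistic is the mean rank over w
consecutive SNPs on the same chromosome (w = 10), centred with
⌈(w−1)/2⌉ SNPs to the left, truncated at chromosome ends, normalised
by the number of tested SNPs M and −log₁₀-transformed; scores lie in
[0, log₁₀ M]. Candidate selection takes the k highest window scores
(k = 5 default), ties again by genome order.

## Validation statistics

Genotype codes count minor-allele copies, with the orientation fixed
once on the *combined* cohorts (frequency ≤ 0.5) so model definitions
cannot flip between cohorts. Models: recessive (code 2 vs rest),
dominant (code ≥ 1 vs code 0), additive (Cochran–Armitage trend with
scores 0/1/2; invariant to affine rescoring and group swaps). A 2×2
table with an empty exposure row is degenerate: its odds ratio and CI
are reported NA while the P-value is still computed.

Fisher's two-sided P uses the minimum-likelihood rule (sum of all
hypergeometric point probabilities not exceeding the observed one) and
is computed in exact integer arithmetic, making tie handling
unambiguous — float implementations must resolve near-ties with a
tolerance. The odds ratio is the unconditional cross-product a·d/(b·c)
with the Woolf logit interval exp(ln OR ± z·√(1/a+1/b+1/c+1/d)),
matching the online calculators typically used with this design; the
conditional MLE with its exact interval is available via
`or_style="conditional"`.

Post-hoc power: for 2×2 models, the exact unconditional power of the
two-sided Fisher test at the observed group sizes and exposure
proportions, by full enumeration of both binomials (at p1 = p2 this is
the attained size and never exceeds α — a tested exactness property).
For the additive model, where no 2×2 exists, the observed trend
statistic serves as the non-centrality of a 1-df chi-square. Both are
*observed-data* power conventions and should be read as descriptive.

FDR: the two-stage BKY step-up — BH at q′ = q/(1+q), null count
m̂₀ = m − r₁, then (if r₁ > 0) BH at q′·m/m̂₀ — applied to the combined
set of model P-values *within each analysis batch* (each cohort, and
the merged analysis, separately). Which P-values form a batch is a
user-visible choice because reasonable designs differ; a fixed
significance threshold (e.g. one carried over from a previous batch)
can be supplied instead. Adjusted values are defined operationally as
the smallest nominal q at which a P enters the rejection set, found by
bisection (rejection grows monotonically with q) and made monotone in
p; they are capped at 1.

The merged analysis concatenates subjects (equivalently, sums the
tables); with a duplicated cohort this doubles every count, leaving
odds ratios unchanged and shrinking P-values — a tested identity.

## Synthetic data

The generator reproduces the statistical structure the analysis
assumes, with complete ground-truth bookkeeping. Defaults are the
study conditions: 100 subjects per group, 5,000 SNPs over 5
chromosomes, 3 technical replicates per pool, construction error
SD 0.01 on the frequency scale, 10 strips with red/green gain drawn
from [0.7, 1.4], 5% multiplicative channel noise per dye, log-normal
total intensity (the total cancels in the PAF ratio and only matters
for realism), bead counts 4 + Poisson(11), and a 0.5% low-bead dropout
rate.

Choices that merit justification:

* **Effect regions.** Each of the 5 effect loci is a contiguous region
  of 10 consecutive SNPs sharing the Δf = 0.15 frequency shift, centred
  on the named effect SNP. A truly isolated single-SNP effect is
  essentially invisible to a 10-SNP window statistic (its window mean
  is dominated by 9 null ranks), and real associated loci are tagged by
  many neighbouring SNPs through LD; the region construction emulates
  that footprint without modelling genotype correlation itself.
  Consequently the package's detection guarantees are statements about
  regionally supported signals, not about isolated variants.
* **Dropout.** The low-bead event is drawn per SNP (one random sample
  gets a sub-threshold count), so the bead-filter exclusion fraction
  equals the dropout parameter directly. The default 0.005 reflects a
  well-behaved array; dense multi-million-SNP chips show far higher
  exclusion (11.5% is the documented reference regime, available by
  setting `dropout_bead_prob=0.115`). Any dropout rate d caps the
  chance that all five named effect SNPs survive filtering at (1−d)⁵,
  which is why the default is small.
* **Pool construction error** is additive Gaussian on the frequency
  scale (clipped to [0,1]) rather than Dirichlet-weighted individual
  contributions: one parameter, directly interpretable, and sufficient
  to exercise the replicate-variance estimator.
* **Phenotypes are generated backwards** from target index values:
  group-specific HOMA-IR and WBISI targets are drawn first (log-normal,
  means tracking the reference cohort: IR+ ≈ 4.6 / 2.2, IR− ≈ 1.8 /
  5.6), then an OGTT curve is constructed that reproduces those values
  exactly, with bounded rejection sampling guaranteeing the
  classification rules recover the generator's labels with zero
  mismatches. Covariates are pair-matched between groups (the IR−
  partner inherits the IR+ subject's sex and jittered age/BMI-SDS).

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: LD correlation between
genotypes (only the shared frequency shift of an effect region),
allele-specific hybridisation bias beyond a per-strip gain, batch or
plate effects correlated across strips, population stratification,
genotyping error in the validation phase, and missing phenotype data.

## Problem sizes

The test suite and the acceptance script size their simulations as the
package's own defaults: one 20,000-SNP null study for calibration, 50
seeds of the 5,000-SNP discovery scenario for recovery, an 8,000-SNP
study for the dense-chip dropout regime, exhaustive Fisher enumeration
for all 2×2 tables with total n ≤ 60, and 1,000 random P-vectors for
the FDR oracle check. The complete suite runs in well under a minute
on one CPU, the acceptance script in under a minute.

## Known limitations

* The χ²(1) reference is slightly anti-conservative with 3+3 replicates
  (see above); with more replicates the effect vanishes. No genomic-
  control correction is applied (none is part of the design).
* The calibration identity k·γ = 1 is exact only for symmetric strip
  frequency spectra; the package's guarantees about *differences*
  between groups do not depend on this.
* The BKY batch composition materially affects which P-values clear
  the threshold; the package makes the batch explicit rather than
  prescribing one.
* Window-score prioritisation trades single-SNP sensitivity for
  regional consistency; an isolated true association with no
  neighbouring support will be missed by design.
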