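# Methods

## The problem

A GWAS locus often overlaps expression QTLs for several genes in several
tissues. The question the Simple Sum (SS) test answers is whether the GWAS
association pattern and an eQTL association pattern at the locus share an
underlying signal (colocalize), using only SNP-level summary statistics —
p-values for both traits — and a linkage-disequilibrium (LD) matrix for the
region. No individual-level data and no effect sizes are required.

## The two-stage test

Let `P^E_j` be the secondary (eQTL) p-value and `P^G_j` the GWAS p-value of
harmonized SNP `j = 1..n` inside the colocalization region, and let `R` be
the `n×n` SNP correlation matrix (signed r).

**Evidence transform.** Each eQTL p-value becomes 1-df chi-square evidence

    T_j = Qχ²₁(1 − P^E_j)      (upper-tail χ²₁ quantile)

**Stage 1 — is there any eQTL signal?** The region-wide statistic
`S1 = Σ_j T_j` is referred to its null distribution under LD. If
`z ~ N(0, R)` then `S1 = Σ λ_i χ²₁,i` with `λ_i` the eigenvalues of `R`
(eigenvalues below 1e-10 are dropped). The tail probability of this
quadratic form is computed by Imhof-type numerical inversion (below). With
`m` secondary datasets submitted in the run, stage 1 passes when
`stage1_p ≤ α/m` (Bonferroni; `α = 0.05` by default). `m` counts *submitted*
gene×tissue pairs; the number of pairs that actually had data is reported
alongside in the heatmap JSON.

**Stage 2 — does the signal track the GWAS?** GWAS evidence is
`g_j = −log10 P^G_j`, centered to `c_j = g_j − ḡ` (so `Σ c_j = 0`). The SS
statistic is

    Z_SS = Σ_j c_j T_j / sqrt(cᵀ Σ c),
    Σ_jk = 2 r_jk² + 4 δ̂ r_jk,
    δ̂   = max(mean(T) − 1, 0),

and `ss_p` is the one-sided upper-tail normal probability of `Z_SS`
(colocalization predicts a *positive* association between GWAS evidence and
eQTL chi-squares; a negative `Z_SS` simply gives `ss_p > 0.5`). The
covariance model is the null of a region that passed stage 1: eQTL z-scores
`~ N(√δ̂·1, R)`, i.e. signal of common strength with unspecified location,
which gives `Cov(T_j, T_k) = 2 r_jk² + 4 δ̂ r_jk` and makes the conditional
mean of `Σ c_j T_j` vanish through the centering of `c`.

**Sentinel codes.** Cells that cannot be tested are coded, not dropped:
`−1` no secondary data in the region; `−2` stage 1 misses `α/m`;
`−3` computation failed — most often fewer than `min_snps = 5` harmonized
SNPs, but also degenerate weights (constant GWAS p-values) or a
non-positive null variance. OK cells carry `−log10(ss_p)`, with `ss_p`
clipped to `≥ 1e-300` first.

## Quadratic-form tail probabilities

`Pr(Σ λ_i χ²₁,i > s)` is computed by Gil-Pelaez/Imhof inversion:

    p = 1/2 + (1/π) ∫₀^∞ sin θ(u) / (u ρ(u)) du,
    θ(u) = ½ Σ arctan(λ_i u) − ½ s u,
    ρ(u) = Π (1 + λ_i² u²)^{1/4}.

The envelope `1/(u ρ(u))` is strictly decreasing, so the integral is
truncated where the envelope falls below `acc/50` (`acc = 1e-6` by
default); beyond that point the phase is dominated by `−su/2` and the
discarded oscillatory tail is bounded by one half-period's area,
`≤ envelope · 2/s ≪ acc`. The adaptive subdivision limit scales with the
number of half-periods inside the truncated range. A single positive
eigenvalue short-circuits to the exact scaled-χ²₁ tail. In the far tail
(`p < 1e-8`), where the oscillatory integral loses significance, Kuonen's
saddlepoint approximation takes over; the result is always clipped to
`(1e-300, 1]`. Agreement with the χ²₂ closed form `e^{−s/2}` is ~1e-9, and
with 10⁶-draw Monte-Carlo estimates within 3 standard errors across random
eigenvalue sets (both are asserted in the test suite).

## Harmonization and LD

* Variants are joined on (chromosome, position, unordered allele pair):
  a secondary record with swapped ref/alt still matches, because p-values
  do not depend on which allele is labelled reference. Strand flips are
  *not* attempted — without allele frequencies, strand inference is unsafe.
* Within one file, duplicate variants keep the smallest p-value (logged);
  p-values outside [0, 1] are dropped and counted; `p = 0` is clamped to
  1e-300 so `−log10` stays finite. Input rows always reconcile:
  kept + dropped = read.
* Coordinates are 1-based inclusive; the analysis region is capped at
  2 Mbp (span = end − start + 1). Builds (hg19/hg38) are pass-through
  labels; mixing builds across inputs is an error, lifting over is out of
  scope.
* LD may come from a PLINK square matrix file or from VCF genotypes.
  A file whose entries are all in [0, 1] with unit diagonal is taken as r²
  and stored as `√(r²)` with a prominent warning: the signs of r are
  unrecoverable, so the `4δ̂r` cross terms of the stage-2 covariance become
  upper bounds (a conservative variance). Genotype-based LD is the signed
  pairwise-complete Pearson correlation of 0/1/2 dosages (PLINK
  `--r square`-compatible, so squaring reproduces `--r2 square`);
  monomorphic SNPs are removed before matrix construction.
* The lead SNP is the user's choice if it exists in both the dataset and
  the LD panel; otherwise the smallest-p variant present in the panel,
  iterating in ascending p-value order (ties broken by smaller position).
  The default colocalization region is lead ± 100,000 bp clipped to the
  view; a user override replaces it.

## Plot-ready summaries

* **LD bins** follow the LocusZoom-standard partition, half-open
  `[lo, hi)` with the top bin closed: lead; r² ≥ 0.8; [0.6, 0.8);
  [0.4, 0.6); [0.2, 0.4); < 0.2; missing. Every r² in [0, 1] maps to
  exactly one bin.
* **Min-p traces**: window width `w = (region size / 1,000,000) × factor`
  bp with `factor = 150` by default; region size is the coordinate extent
  `end − start`, which reproduces the canonical 22.5 bp windows for a
  150 kbp view. `w` is kept as an exact rational so a SNP at position `x`
  falls in window `⌊(x − start)/w⌋` without floating-point drift; windows
  are anchored at the view start; empty windows are omitted.
* **Gene models**: transcript isoforms are collapsed per gene by unioning
  exon intervals across transcripts (GTF via gffutils), merging
  overlapping or book-ended intervals; genes not overlapping the view are
  dropped.

## Synthetic loci

The fixture generator is the single source of truth for the statistical
validation. It draws z-scores `z ~ N(μ, R)` with `R` an AR(1)
(`r_jk = ρ^|j−k|`) or block correlation matrix, and converts them to
two-sided normal p-values. The single-causal-variant mean vector is the
field-standard `μ = effect × R[:, causal]`: expected z-scores decay with LD
to the causal SNP. Scenarios: **A** both traits null; **B** eQTL signal
only (GWAS null); **C** one shared causal SNP for both traits;
**D** distinct causal SNPs. Defaults: 50 SNPs evenly spaced over
chr13:25,200,000–25,350,000, ρ = 0.8, effect 6, MAF 0.3, 500 samples.
Genotypes realizing `R` approximately are produced by a Gaussian copula —
two latent `N(0, R)` haplotype draws per sample thresholded at the
Hardy–Weinberg quantile `Φ⁻¹(1 − MAF)` — and written as plain-text VCF.
Dichotomization attenuates correlations, so the realized dosage LD matches
the target only approximately (mean absolute deviation < 0.1 at 1,000
samples); the copula is adequate for correlation-structure tests, not a
model of recombination or demography. All draws are seeded and
bit-reproducible.

What the generator does **not** emulate: allele-frequency spectra,
strand-ambiguous variants, indels/multi-allelics, genotyping error,
population structure, or realistic LD decay from a recombination map.
Passing tests therefore validate the statistical machinery and the
plumbing, not robustness to real-data artifacts.

## Calibration: what holds and what does not

Under the stage-2 model's own null — eQTL z-scores with a *common*
noncentrality, GWAS weights independent of them — the test is exactly
calibrated: empirical rejection at nominal 0.05 is ≈ 0.05 (asserted in the
suite at 1,500 replicates). Under a *localized* secondary signal (scenario
B), however, `E[T_j] = 1 + μ_j²` varies across SNPs while the model assumes
a common mean; the term `Σ c_j μ_j²` — exactly zero under the common-mean
null — then inflates the spread of `Z_SS` (empirically ≈ 0.21 rejection at
effect 6, ρ = 0.8, 50 SNPs). This anticonservativeness of the
common-noncentrality calibration for concentrated secondary signals is a
known limitation of the stage-2 formulation implemented here; the
simulation that measures it is part of the acceptance checks and is
reported as computed, not adjusted.

## Numerical and design choices

* Problem sizes for the simulation-based checks: 2,000 replicates for
  type-I error, 200 for power, 20 eigenvalue sets × 10⁶ draws for the
  quadratic-form oracle — large enough for the stated tolerance bands at
  95% confidence.
* Stage-1 eigenvalues `< 1e-10` are dropped; LD matrices are symmetrized
  and clipped to [−1, 1] on construction; `cᵀΣc ≤ 0` is a failure (−3),
  never silently patched.
* rsID markers are resolved through an optional user-supplied lookup
  table (5-column TSV); there is no network or dbSNP dependency.
  Unresolvable rsIDs are dropped and counted.
* The heatmap grid is always rectangular: a gene×dataset pair with no
  records renders −1 rather than being omitted. Rows are genes in genomic
  order; columns are datasets in submission order; cell values are
  independent of iteration order.
* The Bonferroni denominator uses the submitted dataset count (the
  conservative reading); both counts appear in the heatmap JSON.
* Exact-float round-trips: p-values are written with `%.17g` and parsed
  with correctly-rounded `float()`, so write→parse is bit-exact.
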