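# sscoloc — two-stage Simple Sum colocalization for GWAS and eQTL summary statistics

`sscoloc` asks whether a GWAS association signal at a locus is driven by the
same underlying variation as SNP-level molecular-QTL signals (typically
eQTLs per gene×tissue), using only summary statistics and a linkage-
disequilibrium (LD) matrix. It is a library plus a small CLI for geneticists
who have a GWAS hit, a collection of secondary association datasets for the
region, and want a gene×tissue colocalization heatmap and plot-ready
regional summaries.

## The test

For harmonized SNPs `j = 1..n` in the colocalization region, eQTL p-values
become 1-df chi-square evidence `T_j = Qχ²₁(1 − P^E_j)` and GWAS p-values
become centered weights `c_j = −log10(P^G_j) − ḡ`.

* **Stage 1** screens the secondary dataset for any signal:
  `S1 = Σ T_j` is referred to the null distribution `Σ λ_i χ²₁,i`
  (λ = eigenvalues of the LD matrix `R`, tail probability by Imhof
  numerical inversion), Bonferroni-gated at `α/m` over the `m` submitted
  gene×tissue datasets.
* **Stage 2** tests whether the eQTL evidence tracks the GWAS pattern:

      Z_SS = Σ c_j T_j / sqrt(cᵀΣc),   Σ_jk = 2 r_jk² + 4 δ̂ r_jk,

  with `δ̂ = max(mean(T) − 1, 0)` the region-wide noncentrality estimate;
  `ss_p` is the one-sided upper normal tail of `Z_SS`.

Cells that cannot be tested carry sentinel codes instead of p-values:
`−1` no secondary data, `−2` stage 1 not significant after Bonferroni
correction, `−3` test failed (e.g. fewer than 5 harmonized SNPs).
See `docs/methods.md` for the full model, assumptions and limitations.

## Worked example

Simulate a colocalized locus (shared causal SNP for the GWAS and for
GENE1's pancreas eQTLs; everything else null) and run the pipeline:

```python
from sscoloc import ScenarioConfig, simulate_summary_stats, write_fixture_files
cfg = ScenarioConfig(scenario="C", seed=1, genes=("GENE1", "GENE2"),
                     tissues=("pancreas", "lung"))
write_fixture_files(simulate_summary_stats(cfg), "demo_locus")
```

```bash
sscoloc --primary demo_locus/primary.tsv --secondary demo_locus/secondary.tsv \
        --ld demo_locus/matrix.ld --region 13:25200000-25350000 \
        --gtf demo_locus/genes.gtf --marker-col markerid --out-dir demo_out
```

`demo_out/heatmap.tsv` (genes × datasets, `−log10(SS p)` or sentinel):

```
gene    pancreas        lung
GENE1   12.66252646     -2
GENE2   -2      -2
```

The colocalized pair stands out at `−log10(ss_p) ≈ 12.7`
(`Z_SS = 7.24`, `ss_p = 2.2e-13`, stage-1 p `4.9e-4` ≤ 0.05/4); the three
null pairs have eQTL data but miss the Bonferroni-corrected stage-1 gate,
hence the `−2` code ("No significant eQTLs" in `demo_out/heatmap.json`).
`demo_out/ss_results.tsv` holds one row per pair with the stage-1 p-value,
`Z_SS`, `ss_p` and the harmonized SNP count; `demo_out/plot_payload.json`
holds the GWAS scatter with LocusZoom-style LD bins relative to the lead
SNP, one lowest-p-per-window trace per secondary dataset (22.5 bp windows
for this 150 kbp region), collapsed gene models from the GTF, and the
heatmap block. The run log records dropped-row counts, the lead-SNP
choice and the Bonferroni denominator.

The same pipeline runs on real data: any whitespace/tab-separated summary
statistics with a configurable column mapping (`chrom_pos_ref_alt_b37/b38`
marker IDs, rsIDs via `--rsid-table`, or explicit CHROM/POS/REF/ALT
columns), a PLINK `--r2 square` `.ld` file or a reference-panel VCF for
LD, and a GENCODE-style GTF.

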