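"""Synthetic loci for testing: LD, genotypes and GWAS/eQTL summary stats.

Scenarios (single-causal-variant summary-statistic model, z ~ N(μ, R) with
μ = effect × R[:, causal], so the expected z-score of every SNP decays with
its LD to the causal variant):

* ``A`` — null: both GWAS and eQTL z-scores are centered at zero.
* ``B`` — eQTL-only: the eQTL dataset carries a signal, the GWAS is null
  (its p-value pattern is independent of the eQTL placement).
* ``C`` — colocalized: one shared causal SNP drives both μ vectors.
* ``D`` — independent signals: GWAS and eQTL have different causal SNPs.

Genotypes realizing the target LD approximately are drawn by a Gaussian
copula: latent haplotype vectors N(0, R) thresholded at the Hardy–Weinberg
quantile for the chosen minor-allele frequency.  Everything is seeded and
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .coloc_matrix import SecondaryCollection
from .ld_engine import GenotypeBlock, LDMatrix, write_plink_ld
from .sumstats_io import (
    P_FLOOR,
    Region,
    SummaryStatDataset,
    VariantKey,
    write_summary_stats,
)

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one simulated locus."""

    scenario: str = "A"
    n_snps: int = 50
    n_samples: int = 500
    rho: float = 0.8
    ld_model: str = "ar1"  # "ar1" or "block"
    block_size: int = 10
    effect_size: float = 6.0
    gwas_effect_size: float | None = None  # defaults to effect_size
    maf: float = 0.3
    seed: int = 0
    chrom: str = "13"
    start: int = 25_200_000
    end: int = 25_350_000
    build: str = "hg19"
    genes: tuple[str, ...] = ("GENE1",)
    tissues: tuple[str, ...] = ("tissue1",)

    def __post_init__(self) -> None:
        if self.scenario not in "ABCD":
            raise ConfigurationError(f"scenario must be one of A/B/C/D, got {self.scenario!r}")
        if not (0.0 <= self.rho < 1.0):
            raise ConfigurationError(f"AR(1) rho must lie in [0, 1), got {self.rho}")
        if self.n_snps < 2:
            raise ConfigurationError("n_snps must be >= 2")
        if not (0.0 < self.maf <= 0.5):
            raise ConfigurationError(f"MAF must lie in (0, 0.5], got {self.maf}")

    @property
    def region(self) -> Region:
        return Region(self.chrom, self.start, self.end)


def _snp_keys(config: ScenarioConfig) -> list[VariantKey]:
    positions = np.unique(
        np.linspace(config.start, config.end, config.n_snps).round().astype(np.int64)
    )
    assert positions.size == config.n_snps, "region too small for distinct positions"
    return [
        VariantKey(config.chrom, int(pos), *_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)],
                   config.build)
        for i, pos in enumerate(positions)
    ]


def simulate_ld_matrix(config: ScenarioConfig) -> LDMatrix:
    """AR(1) (r_jk = ρ^|j−k|) or block-diagonal correlation; PSD by construction."""
    n = config.n_snps
    if config.ld_model == "ar1":
        idx = np.arange(n)
        r = config.rho ** np.abs(idx[:, None] - idx[None, :])
    elif config.ld_model == "block":
        r = np.eye(n)
        for b0 in range(0, n, config.block_size):
            b1 = min(b0 + config.block_size, n)
            r[b0:b1, b0:b1] = config.rho
        np.fill_diagonal(r, 1.0)
    else:
        raise ConfigurationError(f"unknown ld_model {config.ld_model!r}")
    return LDMatrix(snps=_snp_keys(config), r=r, signed=True)


@dataclass
class FixtureBundle:
    """Everything one simulated locus produces, mutually consistent."""

    config: ScenarioConfig
    ld: LDMatrix
    primary: SummaryStatDataset
    collection: SecondaryCollection
    genotypes: GenotypeBlock


def _mean_vector(R: np.ndarray, causal: int, effect: float) -> np.ndarray:
    return effect * R[:, causal]


def _draw_pvalues(rng: np.random.Generator, chol: np.ndarray, mu: np.ndarray) -> np.ndarray:
    z = mu + chol @ rng.standard_normal(mu.size)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.clip(p, P_FLOOR, 1.0)


def _copula_genotypes(rng: np.random.Generator, chol: np.ndarray,
                      n_samples: int, maf: float) -> np.ndarray:
    n_snps = chol.shape[0]
    thresh = stats.norm.isf(maf)  # latent above this => alternate allele
    latent = chol @ rng.standard_normal((n_snps, 2 * n_samples))
    haplotypes = (latent > thresh).astype(float)
    return haplotypes[:, 0::2] + haplotypes[:, 1::2]


def simulate_summary_stats(config: ScenarioConfig) -> FixtureBundle:
    """Draw one locus under the configured scenario (seeded, reproducible).

    The scenario applies to the first (gene, tissue) pair; any additional
    genes/tissues in the config receive independent null eQTL draws.
    """
    rng = np.random.default_rng(config.seed)
    ld = simulate_ld_matrix(config)
    R = ld.r
    n = config.n_snps
    chol = np.linalg.cholesky(R + 1e-12 * np.eye(n))
    causal_shared = n // 2
    causal_gwas, causal_eqtl = causal_shared, causal_shared
    if config.scenario == "D":
        causal_gwas, causal_eqtl = n // 4, (3 * n) // 4
    g_eff = config.effect_size if config.gwas_effect_size is None else config.gwas_effect_size

    mu_gwas = np.zeros(n)
    mu_eqtl = np.zeros(n)
    if config.scenario in ("C", "D"):
        mu_gwas = _mean_vector(R, causal_gwas, g_eff)
    if config.scenario in ("B", "C", "D"):
        mu_eqtl = _mean_vector(R, causal_eqtl, config.effect_size)

    primary = SummaryStatDataset(
        label="gwas",
        variants=list(ld.snps),
        pvalues=_draw_pvalues(rng, chol, mu_gwas),
    )
    entries = {}
    first = True
    for gene in config.genes:
        for tissue in config.tissues:
            mu = mu_eqtl if first else np.zeros(n)
            entries[(gene, tissue)] = SummaryStatDataset(
                label=f"{gene}|{tissue}",
                variants=list(ld.snps),
                pvalues=_draw_pvalues(rng, chol, mu),
            )
            first = False
    genotypes = GenotypeBlock(
        samples=config.n_samples,
        snps=list(ld.snps),
        dosages=_copula_genotypes(rng, chol, config.n_samples, config.maf),
    )
    return FixtureBundle(config=config, ld=ld, primary=primary,
                         collection=SecondaryCollection(entries=entries),
                         genotypes=genotypes)


def _write_vcf(block: GenotypeBlock, path) -> None:
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({s.chrom for s in block.snps})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"S{i + 1}" for i in range(block.samples))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for snp, dosages in zip(block.snps, block.dosages):
            gts = "\t".join(gt_codes.get(d, "./.") for d in dosages)
            fh.write(f"{snp.chrom}\t{snp.pos}\t{snp.token()}\t{snp.ref}\t{snp.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def _write_secondary_tsv(collection: SecondaryCollection, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tdataset\tmarkerid\tP\n")
        for (gene, tissue), ds in collection.entries.items():
            for v, p in zip(ds.variants, ds.pvalues):
                fh.write(f"{gene}\t{tissue}\t{v.token()}\t{p:.17g}\n")


def _write_toy_gtf(config: ScenarioConfig, path) -> None:
    """Emit a small GENCODE-style GTF: each gene gets two transcripts whose
    exon sets overlap, so collapsing is exercised."""
    extent = config.end - config.start
    n_genes = len(config.genes)
    with open(path, "w") as fh:
        for i, gene in enumerate(config.genes):
            g0 = config.start + (i * extent) // max(n_genes, 1) + extent // 20
            g1 = g0 + extent // max(2 * n_genes, 2)
            strand = "+" if i % 2 == 0 else "-"
            mid = (g0 + g1) // 2

            def line(feature: str, s: int, e: int, attrs: str) -> str:
                return (f"{config.chrom}\tsynthetic\t{feature}\t{s}\t{e}\t.\t{strand}\t.\t{attrs}\n")

            gid = f'gene_id "{gene}"; gene_name "{gene}";'
            fh.write(line("gene", g0, g1, gid))
            for t, exons in enumerate((
                [(g0, g0 + (mid - g0) // 2), (mid, g1)],
                [(g0 + (mid - g0) // 4, mid + (g1 - mid) // 2)],
            )):
                tid = f'{gid} transcript_id "{gene}.t{t + 1}";'
                fh.write(line("transcript", exons[0][0], exons[-1][1], tid))
                for s, e in exons:
                    fh.write(line("exon", s, e, tid))


@dataclass(frozen=True)
class RejectionCounts:
    """Replicate bookkeeping for calibration/power simulations."""

    n_reps: int
    n_ok: int
    n_reject: int

    @property
    def rate_among_ok(self) -> float:
        """Fraction of OK results with ss_p ≤ α (type-I error estimate)."""
        return self.n_reject / self.n_ok if self.n_ok else float("nan")

    @property
    def rate_among_reps(self) -> float:
        """Fraction of replicates ending OK with ss_p ≤ α (power estimate)."""
        return self.n_reject / self.n_reps if self.n_reps else float("nan")


def simulate_rejection_counts(
    scenario: str,
    n_reps: int,
    seed: int,
    alpha: float = 0.05,
    base_config: ScenarioConfig | None = None,
) -> RejectionCounts:
    """Replicate the two-stage test under one scenario and count rejections.

    Each replicate draws a fresh locus (child seed from *seed*), runs the
    full pipeline with m = 1, and counts an OK result with ss_p ≤ *alpha*
    as a rejection.
    """
    from .simple_sum import Status, run_simple_sum

    base = base_config or ScenarioConfig()
    child_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_reps)
    n_ok = n_reject = 0
    for s in child_seeds:
        cfg = replace(base, scenario=scenario, seed=int(s))
        bundle = simulate_summary_stats(cfg)
        secondary = next(iter(bundle.collection.entries.values()))
        res = run_simple_sum(bundle.primary, secondary, bundle.ld,
                             cfg.region, alpha=alpha, m=1)
        if res.status is Status.OK:
            n_ok += 1
            if res.ss_p <= alpha:
                n_reject += 1
    return RejectionCounts(n_reps=n_reps, n_ok=n_ok, n_reject=n_reject)


def write_fixture_files(bundle: FixtureBundle, out_dir) -> dict[str, Path]:
    """Write the bundle in exactly the formats the I/O modules consume.

    Produces primary TSV, long-format secondary TSV, PLINK-style ``.ld``
    (r² square), a plain-text VCF of the copula genotypes, and a toy GTF —
    all mutually consistent.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "primary": out / "primary.tsv",
        "secondary": out / "secondary.tsv",
        "ld": out / "matrix.ld",
        "vcf": out / "panel.vcf",
        "gtf": out / "genes.gtf",
    }
    write_summary_stats(bundle.primary, paths["primary"])
    _write_secondary_tsv(bundle.collection, paths["secondary"])
    write_plink_ld(bundle.ld, paths["ld"], squared=True)
    _write_vcf(bundle.genotypes, paths["vcf"])
    _write_toy_gtf(bundle.config, paths["gtf"])
    return paths
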