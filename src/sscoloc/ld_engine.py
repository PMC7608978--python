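"""LD matrices from PLINK-style files or reference-panel genotypes.

The colocalization test needs the SNP×SNP correlation matrix R for the
analysis region.  Two sources are supported: a square matrix text file in the
dialect PLINK writes for ``--r2 square`` / ``--r square`` (``.ld``), or
genotype dosages read from a VCF reference panel, correlated internally.

When only r² values are supplied the signs of r are unrecoverable; the
matrix is stored as √(r²) with ``signed=False`` and a prominent warning,
which makes the stage-2 covariance cross terms an upper bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateError,
    FormatError,
    NoLeadSnpError,
    UndefinedEntryError,
)
from .sumstats_io import Region, SummaryStatDataset, VariantKey, normalize_chrom

logger = logging.getLogger("sscoloc")

_SYM_TOL = 1e-12


@dataclass
class LDMatrix:
    """Ordered SNP list plus symmetric pairwise correlation matrix.

    ``signed`` records whether entries are signed r (from genotypes or a
    ``--r square`` file) or nonnegative √(r²) recovered from an r² file.
    """

    snps: list[VariantKey]
    r: np.ndarray
    signed: bool = True

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.snps)
        if self.r.shape != (n, n):
            raise AlignmentError(
                f"LD matrix is {self.r.shape}, expected ({n}, {n}) for the SNP list"
            )
        if n and not np.allclose(self.r, self.r.T, atol=_SYM_TOL, rtol=0.0):
            raise FormatError("LD matrix is not symmetric")
        if n and not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise FormatError("LD matrix diagonal is not 1")
        if n and np.nanmax(np.abs(self.r)) > 1.0 + 1e-9:
            raise FormatError("LD entries exceed |r| = 1")
        # exact symmetry for downstream eigendecompositions
        self.r = (self.r + self.r.T) / 2.0
        np.clip(self.r, -1.0, 1.0, out=self.r)

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def r2(self) -> np.ndarray:
        return self.r ** 2

    def subset(self, idx) -> "LDMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return LDMatrix(
            snps=[self.snps[i] for i in idx],
            r=self.r[np.ix_(idx, idx)],
            signed=self.signed,
        )

    def r2_with(self, lead: VariantKey) -> dict[VariantKey, float]:
        """r² of every panel SNP with *lead* (for plot coloring)."""
        keys = {s.match_key: i for i, s in enumerate(self.snps)}
        i = keys.get(lead.match_key)
        if i is None:
            return {}
        return {s: float(self.r[i, j] ** 2) for j, s in enumerate(self.snps)}


def read_plink_ld(path, snps: list[VariantKey]) -> LDMatrix:
    """Read a PLINK square LD matrix (``.ld``) aligned to *snps*.

    Entries all in [0, 1] with unit diagonal are taken as r² and stored as
    √(r²) (signed=False, warning logged); any negative entry marks the file
    as signed r and it is stored as-is.
    """
    try:
        mat = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: not a numeric whitespace-delimited matrix ({exc})") from exc
    if mat.shape[0] != mat.shape[1]:
        raise FormatError(f"{path}: matrix is {mat.shape[0]}x{mat.shape[1]}, not square")
    if mat.shape[0] != len(snps):
        raise AlignmentError(
            f"{path}: matrix dimension {mat.shape[0]} does not match SNP list length {len(snps)}"
        )
    if np.any(mat < 0.0):
        return LDMatrix(snps=list(snps), r=mat, signed=True)
    if np.nanmax(mat) > 1.0 + 1e-9:
        raise FormatError(f"{path}: entries outside [-1, 1]")
    logger.warning(
        "%s: all entries nonnegative — interpreting as r^2 and storing sqrt(r^2); "
        "signs of r are unavailable, stage-2 cross terms will be upper bounds", path,
    )
    return LDMatrix(snps=list(snps), r=np.sqrt(np.clip(mat, 0.0, 1.0)), signed=False)


def write_plink_ld(matrix: LDMatrix, path, squared: bool = True) -> None:
    """Write the matrix in the PLINK square text dialect (r² by default)."""
    out = matrix.r ** 2 if squared else matrix.r
    np.savetxt(path, out, delimiter="\t", fmt="%.10g")


@dataclass
class GenotypeBlock:
    """Allele-count dosages (0/1/2, NaN = missing) for a set of samples."""

    samples: int
    snps: list[VariantKey]
    dosages: np.ndarray  # shape (n_snps, samples)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.snps), self.samples):
            raise AlignmentError(
                f"dosage array is {self.dosages.shape}, expected "
                f"({len(self.snps)}, {self.samples})"
            )


def read_vcf_genotypes(path, region: Region | None = None, build: str = "hg19") -> GenotypeBlock:
    """Load biallelic-SNP dosages from a VCF (optionally restricted to a region)."""
    from cyvcf2 import VCF  # local import: cyvcf2 pulls in htslib

    vcf = VCF(str(path), gts012=True)
    snps: list[VariantKey] = []
    rows: list[np.ndarray] = []
    # full scan with an in-Python region filter: plain-text VCFs carry no
    # tabix index, so htslib region queries are unavailable
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue  # biallelic SNPs only
        chrom = normalize_chrom(var.CHROM)
        if region is not None and not region.contains(chrom, var.POS):
            continue
        snps.append(VariantKey(chrom, var.POS, var.REF, var.ALT[0], build))
        g = np.asarray(var.gt_types, dtype=float)  # 0/1/2, 3 = unknown
        g[g == 3] = np.nan
        rows.append(g)
    n_samples = len(vcf.samples)
    vcf.close()
    dos = np.vstack(rows) if rows else np.empty((0, n_samples))
    return GenotypeBlock(samples=n_samples, snps=snps, dosages=dos)


def compute_ld_from_genotypes(block: GenotypeBlock, snps: list[VariantKey] | None = None) -> LDMatrix:
    """Signed pairwise Pearson correlation of dosage vectors.

    Missing dosages are handled pairwise-complete (PLINK-compatible), so
    squaring the result reproduces ``--r2 square``.  Monomorphic SNPs are
    excluded with a warning; a pair with fewer than two complete samples is
    an error.
    """
    if block.samples < 2:
        raise DegenerateError("at least 2 samples are required to compute LD")
    keep_snps = block.snps
    dos = block.dosages
    if snps is not None:
        wanted = {s.match_key for s in snps}
        idx = [i for i, s in enumerate(block.snps) if s.match_key in wanted]
        missing = len(wanted) - len(idx)
        if missing:
            logger.warning("%d requested SNPs absent from genotype block", missing)
        keep_snps = [block.snps[i] for i in idx]
        dos = dos[idx]

    variances = np.array([np.nanvar(row) if np.any(np.isfinite(row)) else 0.0 for row in dos])
    poly = variances > 0.0
    n_mono = int((~poly).sum())
    if n_mono:
        logger.warning("excluding %d monomorphic SNP(s) from the LD matrix", n_mono)
    keep_snps = [s for s, ok in zip(keep_snps, poly) if ok]
    dos = dos[poly]
    if not keep_snps:
        raise DegenerateError("no polymorphic SNPs left to correlate")

    frame = pd.DataFrame(dos.T)  # samples × snps; pairwise-complete Pearson
    corr = frame.corr(min_periods=2).to_numpy()
    if np.any(~np.isfinite(corr)):
        raise UndefinedEntryError(
            "some SNP pairs have fewer than 2 complete samples; LD undefined"
        )
    np.fill_diagonal(corr, 1.0)
    return LDMatrix(snps=keep_snps, r=corr, signed=True)


def select_lead_snp(
    dataset: SummaryStatDataset,
    ld_snps,
    user_choice: VariantKey | None = None,
) -> VariantKey:
    """Pick the lead SNP: user override if usable, else smallest-p fallback.

    Iterates in ascending p-value order until a variant present in the LD
    panel is found (ties broken by smaller genomic position), mirroring the
    behaviour when the lowest-p SNP is absent from the reference panel.
    """
    if not len(dataset):
        raise NoLeadSnpError("dataset is empty")
    panel = {s.match_key for s in ld_snps}
    if user_choice is not None:
        in_data = any(v.match_key == user_choice.match_key for v in dataset.variants)
        if in_data and user_choice.match_key in panel:
            return user_choice
        logger.warning(
            "requested lead SNP %s not present in both dataset and LD panel; "
            "falling back to smallest p-value", user_choice,
        )
    order = sorted(range(len(dataset)),
                   key=lambda i: (dataset.pvalues[i], dataset.variants[i].pos))
    for i in order:
        if dataset.variants[i].match_key in panel:
            if i != order[0]:
                logger.info(
                    "lowest-p SNP absent from LD panel; using %s (p=%.3g)",
                    dataset.variants[i], dataset.pvalues[i],
                )
            return dataset.variants[i]
    raise NoLeadSnpError("no dataset variant is present in the LD panel")


#: Default half-width of the colocalization window around the lead SNP (bp).
SS_HALF_WIDTH_BP = 100_000


def default_ss_region(lead: VariantKey, view: Region,
                      half_width: int = SS_HALF_WIDTH_BP) -> Region:
    """Default colocalization region: ±0.1 Mbp around the lead SNP, clipped to the view."""
    if not view.contains(lead.chrom, lead.pos):
        raise AlignmentError(f"lead SNP {lead} lies outside the view region {view}")
    return Region(
        chrom=view.chrom,
        start=max(view.start, lead.pos - half_width),
        end=min(view.end, lead.pos + half_width),
    )
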