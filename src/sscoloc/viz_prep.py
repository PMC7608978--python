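"""Plot-ready regional summaries: LD color bins, min-p traces, gene models.

These computations back the interactive regional association view: each GWAS
point is colored by its r² with the lead SNP using the LocusZoom-standard
bins; each secondary dataset is summarized as the lowest p-value per window,
with window width (region size / 1,000,000) × 150 bp; and transcript
isoforms are collapsed into single gene models (union of exon intervals).
The output is a single JSON payload; actual rendering is a client concern.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError, ParseError, RegionError
from .coloc_matrix import HeatmapMatrix
from .sumstats_io import Region, SummaryStatDataset, normalize_chrom

logger = logging.getLogger("sscoloc")


class LDBin(enum.Enum):
    """LD color category of a SNP relative to the lead SNP."""

    LEAD = "lead"
    GE_08 = "ge0.8"
    FROM_06_TO_08 = "0.6to0.8"
    FROM_04_TO_06 = "0.4to0.6"
    FROM_02_TO_04 = "0.2to0.4"
    LT_02 = "lt0.2"
    MISSING = "missing"


#: Lower edge of the top ("high LD", red) bin.
TOP_BIN_THRESHOLD = 0.8

_BIN_EDGES = (
    (0.8, LDBin.GE_08),
    (0.6, LDBin.FROM_06_TO_08),
    (0.4, LDBin.FROM_04_TO_06),
    (0.2, LDBin.FROM_02_TO_04),
    (0.0, LDBin.LT_02),
)


def bin_ld_colors(r2: float | None, is_lead: bool = False) -> LDBin:
    """Assign one LD bin.  Bins are half-open [lo, hi), top bin closed at 1.

    Missing r² (None/NaN) maps to MISSING; the lead SNP always maps to LEAD.
    """
    if is_lead:
        return LDBin.LEAD
    if r2 is None or (isinstance(r2, float) and math.isnan(r2)):
        return LDBin.MISSING
    if not (0.0 <= r2 <= 1.0):
        raise DomainError(f"r^2 must lie in [0, 1], got {r2}")
    for lo, cat in _BIN_EDGES:
        if r2 >= lo:
            return cat
    return LDBin.LT_02  # r2 == 0.0 handled above; keep type checker happy


#: Default multiplier in the window-width rule.
DEFAULT_WINDOW_FACTOR = 150


def window_size_bp(region: Region, factor: int = DEFAULT_WINDOW_FACTOR) -> float:
    """Window width in bp: (region size / 1,000,000) × factor.

    Region size is the coordinate extent end − start; e.g. a 150 kbp view
    yields 22.5 bp windows at the default factor.
    """
    if region.extent <= 0:
        raise RegionError(f"region {region} has nonpositive extent")
    return region.extent * factor / 1_000_000


@dataclass(frozen=True)
class TracePoint:
    """Left edge of one window and the smallest secondary p-value inside it."""

    window_start: float
    min_p: float


def window_min_trace(
    positions: Sequence[int],
    pvalues: Sequence[float],
    region: Region,
    factor: int = DEFAULT_WINDOW_FACTOR,
) -> list[TracePoint]:
    """Lowest p-value per window across the region.

    Windows tile [start, start + w), [start + w, start + 2w), ... anchored at
    the view start.  The fractional width w is kept exact (rational
    arithmetic) so boundary assignment never drifts: position x falls in
    window ⌊(x − start) / w⌋.  Empty windows are omitted.
    """
    if region.extent <= 0:
        raise RegionError(f"region {region} has nonpositive extent")
    positions = np.asarray(positions, dtype=np.int64)
    pvalues = np.asarray(pvalues, dtype=float)
    if positions.size != pvalues.size:
        raise DomainError("positions and pvalues must have equal length")
    w = Fraction(region.extent * factor, 1_000_000)
    best: dict[int, float] = {}
    for pos, p in zip(positions, pvalues):
        if not (region.start <= pos <= region.end):
            continue
        idx = int(Fraction(int(pos) - region.start) / w)  # exact floor division
        if p < best.get(idx, np.inf):
            best[idx] = float(p)
    return [
        TracePoint(window_start=float(region.start + idx * w), min_p=best[idx])
        for idx in sorted(best)
    ]


@dataclass
class GeneModel:
    """One gene with transcript isoforms collapsed to a single exon chain."""

    gene_id: str
    name: str
    strand: str
    chrom: str
    start: int
    end: int
    exons: list[tuple[int, int]]


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals; overlapping or adjacent merge."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def collapse_gene_models(gtf_path, region: Region) -> list[GeneModel]:
    """Collapse transcripts of every gene overlapping *region* into one model.

    Exon intervals from all transcripts are unioned and merged, yielding
    pairwise-disjoint sorted exons per gene.  Malformed GTF lines raise a
    parse error naming the line number.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(gtf_path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise ParseError(_gtf_error_message(gtf_path, exc)) from exc

    models: list[GeneModel] = []
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        gene_id = (feat.attributes.get("gene_id") or [feat.id])[0]
        chrom = normalize_chrom(feat.seqid)
        if feat.featuretype == "gene":
            name = (feat.attributes.get("gene_name") or [gene_id])[0]
            meta[gene_id] = (name, feat.strand or ".", chrom)
        elif feat.featuretype == "exon":
            exons_by_gene.setdefault(gene_id, []).append((feat.start, feat.end))
            meta.setdefault(gene_id, (gene_id, feat.strand or ".", chrom))
    for gene_id, exons in exons_by_gene.items():
        name, strand, chrom = meta[gene_id]
        merged = merge_intervals(exons)
        g_start, g_end = merged[0][0], merged[-1][1]
        if chrom != region.chrom or g_end < region.start or g_start > region.end:
            continue
        models.append(GeneModel(gene_id=gene_id, name=name, strand=strand,
                                chrom=chrom, start=g_start, end=g_end, exons=merged))
    models.sort(key=lambda g: (g.start, g.gene_id))
    return models


def _gtf_error_message(path, exc: Exception) -> str:
    """Locate the first malformed GTF line for a useful error message."""
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 9:
                    return f"{path}: malformed GTF line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                try:
                    int(fields[3]), int(fields[4])
                except ValueError:
                    return f"{path}: malformed GTF line {lineno}: non-integer coordinates"
    except OSError:
        pass
    return f"{path}: GTF parse failure ({exc})"


def build_plot_payload(
    primary: SummaryStatDataset,
    traces: Mapping[str, Sequence[TracePoint]],
    ld_bins: Sequence[LDBin],
    gene_models: Sequence[GeneModel],
    matrix: HeatmapMatrix | None,
    region: Region,
    ss_region: Region,
) -> dict:
    """Assemble the single JSON document the regional plot is drawn from.

    Contains the GWAS scatter (position, −log10 p, LD bin per point), one
    min-p trace per secondary dataset, collapsed gene models, the heatmap
    block and the gray-shading bounds of the colocalization region.
    """
    if len(ld_bins) != len(primary):
        raise DomainError("one LD bin is required per GWAS point")
    payload = {
        "region": {"chrom": region.chrom, "start": region.start, "end": region.end},
        "ss_region": {"chrom": ss_region.chrom, "start": ss_region.start, "end": ss_region.end},
        "gwas_scatter": [
            {
                "marker": v.token(),
                "pos": v.pos,
                "neglog10_p": float(-np.log10(p)),
                "ld_bin": b.value,
            }
            for v, p, b in zip(primary.variants, primary.pvalues, ld_bins)
        ],
        "traces": {
            label: [{"window_start": t.window_start, "min_p": t.min_p} for t in pts]
            for label, pts in traces.items()
        },
        "genes": [
            {
                "gene_id": g.gene_id,
                "name": g.name,
                "strand": g.strand,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "exons": [list(e) for e in g.exons],
            }
            for g in gene_models
        ],
    }
    if matrix is not None:
        payload["heatmap"] = {
            "genes": matrix.genes,
            "datasets": matrix.datasets,
            "values": matrix.values.tolist(),
        }
    return payload


def write_plot_payload(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
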