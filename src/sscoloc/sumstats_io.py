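"""Reading, validation and harmonization of summary-statistic datasets.

A *primary* dataset holds GWAS per-SNP p-values for the trait of interest; a
*secondary* dataset holds SNP-level association p-values for a molecular
phenotype (typically a gene's expression in one tissue).  Both are plain
header-bearing TSV files with a flexible column mapping: either explicit
CHROM/POS/REF/ALT columns or a single marker column in
``chrom_pos_ref_alt_b37`` / ``..._b38`` format (rsIDs are accepted and
resolved through an optional user-supplied lookup table).

Coordinates are 1-based inclusive throughout.  The analysis region is capped
at 2 Mbp.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ConfigurationError,
    EmptyInputError,
    NoOverlapError,
    ParseError,
    RegionError,
    RegionTooLargeError,
)

logger = logging.getLogger("sscoloc")

#: Largest permitted region span in base pairs (inclusive of both ends).
REGION_CAP_BP = 2_000_000

#: p = 0 is clamped here so that -log10(p) stays finite.
P_FLOOR = 1e-300

_VALID_CHROMS = frozenset([str(c) for c in range(1, 23)] + ["X"])
_ALLELE_RE = re.compile(r"^[ACGT]+$")
_MARKER_RE = re.compile(
    r"^(?:chr)?(?P<chrom>\w+)_(?P<pos>\d+)_(?P<ref>[ACGTacgt]+)"
    r"_(?P<alt>[ACGTacgt]+)_b(?P<build>37|38)$"
)
_RSID_RE = re.compile(r"^rs\d+$")

#: Default column-name mapping (role -> column header).
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "chrom": "CHROM",
    "pos": "POS",
    "ref": "REF",
    "alt": "ALT",
    "p": "P",
}

#: Optional effect columns carried through when present (unused by the test).
OPTIONAL_ROLES = ("beta", "se", "maf", "n")


def normalize_chrom(chrom: str) -> str:
    """Strip any ``chr`` prefix and upper-case X; validate the label."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.lower() == "x":
        c = "X"
    if c not in _VALID_CHROMS:
        raise ParseError(f"unrecognized chromosome label: {chrom!r}")
    return c


@dataclass(frozen=True, order=True)
class VariantKey:
    """Chromosome/position/allele identity of one SNP; the join key."""

    chrom: str
    pos: int
    ref: str
    alt: str
    build: str = "hg19"

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.pos < 1:
            raise ParseError(f"position must be >= 1, got {self.pos}")
        if not _ALLELE_RE.match(self.ref) or not _ALLELE_RE.match(self.alt):
            raise ParseError(f"alleles must be A/C/G/T strings: {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ParseError(f"ref and alt alleles are identical at {self.chrom}:{self.pos}")
        if self.build not in ("hg19", "hg38"):
            raise ParseError(f"unknown build tag: {self.build!r}")

    @property
    def match_key(self) -> tuple[str, int, str, str]:
        """Allele-order-invariant key: swapped ref/alt variants match."""
        a, b = sorted((self.ref, self.alt))
        return (self.chrom, self.pos, a, b)

    def token(self) -> str:
        build = "b37" if self.build == "hg19" else "b38"
        return f"{self.chrom}_{self.pos}_{self.ref}_{self.alt}_{build}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}({self.build})"


@dataclass(frozen=True)
class UnresolvedRsid:
    """An ``rs...`` marker awaiting resolution via a lookup table."""

    rsid: str


def parse_marker_id(token: str) -> VariantKey | UnresolvedRsid:
    """Parse one marker token.

    ``13_25200000_A_G_b37`` yields a :class:`VariantKey` on hg19 (``_b38`` on
    hg38); ``rs...`` tokens come back as :class:`UnresolvedRsid` for the
    caller to resolve against a lookup table.  Anything else is a
    :class:`~sscoloc.errors.ParseError`.
    """
    tok = str(token).strip()
    if not tok:
        raise ParseError("empty marker token")
    m = _MARKER_RE.match(tok)
    if m:
        build = "hg19" if m.group("build") == "37" else "hg38"
        return VariantKey(
            chrom=m.group("chrom"),
            pos=int(m.group("pos")),
            ref=m.group("ref"),
            alt=m.group("alt"),
            build=build,
        )
    if _RSID_RE.match(tok):
        return UnresolvedRsid(tok)
    raise ParseError(f"marker token matches neither chrom_pos_ref_alt_b37/38 nor rsID: {tok!r}")


@dataclass(frozen=True)
class Region:
    """1-based inclusive genomic interval, capped at 2 Mbp."""

    chrom: str
    start: int
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def extent(self) -> int:
        """Length as coordinate difference (used by the trace-window rule)."""
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def validate_region(chrom: str | int, start: int, end: int) -> Region:
    """Build a :class:`Region`, enforcing ordering and the 2 Mbp cap."""
    c = normalize_chrom(str(chrom))
    start, end = int(start), int(end)
    if start < 1:
        raise RegionError(f"region start must be >= 1, got {start}")
    if start > end:
        raise RegionError(f"region start {start} exceeds end {end}")
    span = end - start + 1
    if span > REGION_CAP_BP:
        raise RegionTooLargeError(
            f"region span {span:,} bp exceeds the {REGION_CAP_BP // 1_000_000} Mbp cap"
        )
    return Region(c, start, end)


def parse_region_string(text: str) -> Region:
    """Parse ``chr13:25,200,000-25,350,000``-style strings."""
    m = re.match(r"^(?:chr)?(\w+):([\d,]+)-([\d,]+)$", text.strip())
    if not m:
        raise RegionError(f"cannot parse region string: {text!r}")
    return validate_region(m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", "")))


@dataclass
class ParseReport:
    """Row accounting for one parsed file: input = kept + dropped."""

    n_input: int = 0
    n_kept: int = 0
    n_dropped_pvalue: int = 0
    n_dropped_marker: int = 0
    n_duplicates: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_pvalue + self.n_dropped_marker + self.n_duplicates


@dataclass
class SummaryStatDataset:
    """Ordered variants with aligned p-values (plus optional effect columns)."""

    label: str
    variants: list[VariantKey]
    pvalues: np.ndarray
    extra: pd.DataFrame | None = None
    report: ParseReport | None = None

    def __post_init__(self) -> None:
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        if len(self.variants) != len(self.pvalues):
            raise AlignmentError("variants and pvalues have different lengths")
        if np.any(~np.isfinite(self.pvalues)) or np.any(self.pvalues <= 0) or np.any(self.pvalues > 1):
            raise ParseError("p-values must lie in (0, 1] after clamping")
        keys = [v.match_key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ParseError(f"duplicate variants in dataset {self.label!r}")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def build(self) -> str:
        return self.variants[0].build if self.variants else "hg19"

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def restrict(self, region: Region) -> "SummaryStatDataset":
        """Subset to variants inside *region* (chromosome-aware)."""
        idx = [i for i, v in enumerate(self.variants)
               if region.contains(v.chrom, v.pos)]
        return SummaryStatDataset(
            label=self.label,
            variants=[self.variants[i] for i in idx],
            pvalues=self.pvalues[idx],
            extra=self.extra.iloc[idx].reset_index(drop=True) if self.extra is not None else None,
        )


def load_rsid_table(path) -> dict[str, VariantKey]:
    """Load a 5-column rsID lookup TSV: rsid, chrom, pos, ref, alt.

    An optional 6th column carries the build tag (default hg19).
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    required = {"rsid", "chrom", "pos", "ref", "alt"}
    if not required.issubset(cols):
        raise ConfigurationError(
            f"rsID table must have columns {sorted(required)}, found {cols}"
        )
    table: dict[str, VariantKey] = {}
    for row in df.itertuples(index=False):
        build = getattr(row, "build", "hg19") or "hg19"
        table[row.rsid] = VariantKey(row.chrom, int(row.pos), row.ref, row.alt, build)
    return table


def _resolve_column_map(columns: Sequence[str], column_map: Mapping[str, str] | None) -> dict[str, str]:
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    if "p" not in cmap:
        raise ConfigurationError("column map must assign the 'p' role")
    if "marker" not in cmap and not {"chrom", "pos", "ref", "alt"}.issubset(cmap):
        raise ConfigurationError(
            "column map must supply either a 'marker' column or all of chrom/pos/ref/alt"
        )
    for role, name in cmap.items():
        if role in ("marker", "chrom", "pos", "ref", "alt", "p") and name not in columns:
            raise ConfigurationError(f"mapped column {name!r} (role {role!r}) not found in header")
    return cmap


def _clean_pvalues(raw: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Return (clamped p array, keep mask); p=0 -> P_FLOOR, p outside [0,1] dropped."""
    def _to_float(x) -> float:
        try:
            return float(x)
        except (TypeError, ValueError):
            return np.nan

    # float() is correctly rounded (pd.to_numeric's fast path is not),
    # which keeps write→parse round-trips bit-exact
    p = raw.map(_to_float).to_numpy(dtype=float)
    keep = np.isfinite(p) & (p >= 0.0) & (p <= 1.0)
    p = np.where(p == 0.0, P_FLOOR, p)
    return p, keep


def dataset_from_frame(
    df: pd.DataFrame,
    column_map: Mapping[str, str] | None = None,
    build: str = "hg19",
    label: str = "dataset",
    rsid_lookup: Mapping[str, VariantKey] | None = None,
) -> SummaryStatDataset:
    """Validate an already-loaded frame into a :class:`SummaryStatDataset`.

    Shared by the file reader and the long-format secondary-collection
    reader.  Rows with unparseable markers or out-of-range p-values are
    dropped and counted; duplicate variants keep the smallest p-value.
    """
    cmap = _resolve_column_map(df.columns, column_map)
    report = ParseReport(n_input=len(df))

    p, keep = _clean_pvalues(df[cmap["p"]])
    report.n_dropped_pvalue = int((~keep).sum())

    variants: list[VariantKey | None] = [None] * len(df)
    if "marker" in cmap:
        for i, tok in enumerate(df[cmap["marker"]].astype(str)):
            if not keep[i]:
                continue
            try:
                parsed = parse_marker_id(tok)
            except ParseError:
                keep[i] = False
                report.n_dropped_marker += 1
                continue
            if isinstance(parsed, UnresolvedRsid):
                resolved = (rsid_lookup or {}).get(parsed.rsid)
                if resolved is None:
                    keep[i] = False
                    report.n_dropped_marker += 1
                    continue
                parsed = resolved
            variants[i] = parsed
    else:
        for i, row in enumerate(zip(df[cmap["chrom"]], df[cmap["pos"]],
                                    df[cmap["ref"]], df[cmap["alt"]])):
            if not keep[i]:
                continue
            try:
                variants[i] = VariantKey(str(row[0]), int(row[1]), str(row[2]), str(row[3]), build)
            except (ParseError, ValueError):
                keep[i] = False
                report.n_dropped_marker += 1

    # Duplicate VariantKey (exact or allele-swapped): keep smallest p, log.
    best: dict[tuple, int] = {}
    for i in np.flatnonzero(keep):
        key = variants[i].match_key
        j = best.get(key)
        if j is None or p[i] < p[j]:
            if j is not None:
                report.n_duplicates += 1
            best[key] = i
        else:
            report.n_duplicates += 1
    order = sorted(best.values())
    report.n_kept = len(order)
    if report.n_dropped:
        logger.warning(
            "%s: dropped %d of %d rows (%d bad p, %d bad marker, %d duplicates)",
            label, report.n_dropped, report.n_input, report.n_dropped_pvalue,
            report.n_dropped_marker, report.n_duplicates,
        )
    if not order:
        raise EmptyInputError(f"{label}: no valid rows after parsing")

    extra_cols = {role: cmap[role] for role in OPTIONAL_ROLES if role in cmap and cmap[role] in df.columns}
    extra = None
    if extra_cols:
        extra = df.iloc[order][list(extra_cols.values())].reset_index(drop=True)
        extra.columns = list(extra_cols)

    ds_variants = [variants[i] for i in order]
    builds = {v.build for v in ds_variants}
    if len(builds) > 1:
        raise AlignmentError(f"{label}: mixed genome builds in one file: {sorted(builds)}")
    return SummaryStatDataset(label=label, variants=ds_variants, pvalues=p[order],
                              extra=extra, report=report)


def parse_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    build: str = "hg19",
    label: str | None = None,
    rsid_lookup: Mapping[str, VariantKey] | None = None,
) -> SummaryStatDataset:
    """Read one whitespace/tab-separated summary-statistics file."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if df.empty:
        raise EmptyInputError(f"{path}: file has no data rows")
    return dataset_from_frame(df, column_map, build, label or str(path), rsid_lookup)


def write_summary_stats(dataset: SummaryStatDataset, path) -> None:
    """Write a dataset back out as marker + p TSV (round-trip safe)."""
    df = pd.DataFrame({
        "markerid": [v.token() for v in dataset.variants],
        "P": dataset.pvalues,
    })
    if dataset.extra is not None:
        for col in dataset.extra.columns:
            df[col] = dataset.extra[col].to_numpy()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class HarmonizedIndex:
    """Aligned row indices into primary, secondary and LD for the common SNPs."""

    keys: list[VariantKey]
    primary_idx: np.ndarray
    secondary_idx: np.ndarray
    ld_idx: np.ndarray
    n_excluded_primary: int = 0
    n_excluded_secondary: int = 0
    n_excluded_ld: int = 0

    def __len__(self) -> int:
        return len(self.keys)


def harmonize_datasets(primary: SummaryStatDataset, secondary: SummaryStatDataset, ld) -> HarmonizedIndex:
    """Ordered (by genomic position) intersection of variants in all three sources.

    Matching is allele-order invariant: a secondary variant recorded with
    swapped ref/alt still matches (p-values do not depend on which allele is
    labelled reference).  Strand flips are not attempted.
    """
    builds = {primary.build, secondary.build}
    ld_snps: Sequence[VariantKey] = ld.snps
    if ld_snps:
        builds.add(ld_snps[0].build)
    if len(builds) > 1:
        raise AlignmentError(f"inputs are on different genome builds: {sorted(builds)}")

    def index_of(variants: Iterable[VariantKey]) -> dict[tuple, int]:
        out: dict[tuple, int] = {}
        for i, v in enumerate(variants):
            out.setdefault(v.match_key, i)
        return out

    p_map = index_of(primary.variants)
    s_map = index_of(secondary.variants)
    l_map = index_of(ld_snps)
    common = set(p_map) & set(s_map) & set(l_map)
    if not common:
        raise NoOverlapError(
            f"no shared variants between primary ({len(p_map)}), "
            f"secondary ({len(s_map)}) and LD ({len(l_map)})"
        )
    ordered = sorted(common)  # (chrom, pos, allele, allele) — genomic order
    return HarmonizedIndex(
        keys=[primary.variants[p_map[k]] for k in ordered],
        primary_idx=np.array([p_map[k] for k in ordered], dtype=np.intp),
        secondary_idx=np.array([s_map[k] for k in ordered], dtype=np.intp),
        ld_idx=np.array([l_map[k] for k in ordered], dtype=np.intp),
        n_excluded_primary=len(p_map) - len(common),
        n_excluded_secondary=len(s_map) - len(common),
        n_excluded_ld=len(l_map) - len(common),
    )
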