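"""Orchestration of the SS test across genes × secondary datasets.

Secondary collections arrive as a long-format TSV (``gene`` and ``dataset``
columns plus the usual variant/p columns).  Every (gene, dataset) pair in
the rectangular grid gets exactly one cell: −log10(SS p) when the test ran,
or a sentinel code (−1/−2/−3) otherwise — pairs with no data at all render
−1 so the grid stays rectangular (the gray squares of the heatmap).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError
from .ld_engine import LDMatrix
from .simple_sum import (
    DEFAULT_ALPHA,
    SENTINEL_REASONS,
    SSResult,
    Status,
    run_simple_sum,
)
from .sumstats_io import (
    Region,
    SummaryStatDataset,
    VariantKey,
    dataset_from_frame,
)

logger = logging.getLogger("sscoloc")

DEFAULT_GENE_COL = "gene"
DEFAULT_DATASET_COL = "dataset"


@dataclass
class SecondaryCollection:
    """Map (gene, dataset_label) → SummaryStatDataset, insertion-ordered."""

    entries: dict[tuple[str, str], SummaryStatDataset]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g, _ in self.entries:
            seen.setdefault(g)
        return list(seen)

    @property
    def datasets(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, d in self.entries:
            seen.setdefault(d)
        return list(seen)

    @property
    def build(self) -> str:
        for ds in self.entries.values():
            if len(ds):
                return ds.build
        return "hg19"


def parse_secondary_collection(
    path,
    column_map: Mapping[str, str] | None = None,
    build: str = "hg19",
    gene_col: str = DEFAULT_GENE_COL,
    dataset_col: str = DEFAULT_DATASET_COL,
    rsid_lookup=None,
) -> SecondaryCollection:
    """Read a long-format secondary TSV and group it by (gene, dataset).

    Each group goes through the same validation as a primary file (p-value
    range filter, zero clamping, duplicate collapse to the smallest p).
    Empty groups are dropped.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    for col in (gene_col, dataset_col):
        if col not in df.columns:
            raise ConfigurationError(
                f"secondary file {path} is missing the required {col!r} column"
            )
    if df.empty:
        raise EmptyInputError(f"{path}: file has no data rows")
    entries: dict[tuple[str, str], SummaryStatDataset] = {}
    for (gene, dataset), group in df.groupby([gene_col, dataset_col], sort=False):
        label = f"{gene}|{dataset}"
        try:
            ds = dataset_from_frame(
                group.reset_index(drop=True), column_map, build, label, rsid_lookup
            )
        except EmptyInputError:
            logger.warning("secondary group %s has no valid rows; dropped", label)
            continue
        entries[(str(gene), str(dataset))] = ds
    if not entries:
        raise EmptyInputError(f"{path}: no usable (gene, dataset) groups")
    return SecondaryCollection(entries=entries)


@dataclass
class HeatmapMatrix:
    """genes × datasets grid of −log10(SS p) or sentinel values."""

    genes: list[str]
    datasets: list[str]
    values: np.ndarray  # shape (len(genes), len(datasets))
    results: dict[tuple[str, str], SSResult]
    m: int
    m_with_data: int = 0
    alpha: float = DEFAULT_ALPHA

    def reason(self, gene: str, dataset: str) -> str | None:
        res = self.results[(gene, dataset)]
        if res.status is Status.OK:
            return None
        return res.reason or SENTINEL_REASONS[res.sentinel]


def _gene_order(collection: SecondaryCollection) -> list[str]:
    """Genes in genomic order (smallest variant position), ties alphabetical."""
    min_pos: dict[str, int] = {}
    for (gene, _), ds in collection.entries.items():
        if len(ds):
            p = int(ds.positions.min())
            min_pos[gene] = min(min_pos.get(gene, p), p)
    return sorted(collection.genes, key=lambda g: (min_pos.get(g, 2**62), g))


def compute_coloc_matrix(
    primary: SummaryStatDataset,
    collection: SecondaryCollection,
    ld: LDMatrix,
    ss_region: Region,
    alpha: float = DEFAULT_ALPHA,
) -> HeatmapMatrix:
    """Run the SS test for every (gene, dataset) pair in the collection.

    The Bonferroni denominator m is the number of submitted secondary
    datasets (gene×tissue pairs); the count of pairs that actually had data
    in the region is reported alongside.  Rows are genes in genomic order,
    columns datasets in submission order; cell values do not depend on the
    iteration order over entries.
    """
    m = len(collection)
    genes = _gene_order(collection)
    datasets = collection.datasets
    values = np.full((len(genes), len(datasets)), -1.0)  # NO_DATA until filled
    results: dict[tuple[str, str], SSResult] = {}
    m_with_data = 0
    for gi, gene in enumerate(genes):
        for di, dataset in enumerate(datasets):
            sec = collection.entries.get((gene, dataset))
            res = run_simple_sum(primary, sec, ld, ss_region, alpha=alpha, m=m)
            if res.status is not Status.NO_DATA:
                m_with_data += 1
            results[(gene, dataset)] = res
            values[gi, di] = res.cell_value
    return HeatmapMatrix(genes=genes, datasets=datasets, values=values,
                         results=results, m=m, m_with_data=m_with_data, alpha=alpha)


def export_heatmap_table(matrix: HeatmapMatrix, path) -> None:
    """Write the heatmap as TSV (genes × datasets) plus a companion JSON.

    Sentinel values appear verbatim in the TSV; the JSON carries the reason
    string for every non-OK cell together with per-cell stage-1 p-values.
    """
    df = pd.DataFrame(matrix.values, index=matrix.genes, columns=matrix.datasets)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")

    cells = []
    for gene in matrix.genes:
        for dataset in matrix.datasets:
            res = matrix.results[(gene, dataset)]
            cells.append({
                "gene": gene,
                "dataset": dataset,
                "status": res.status.value,
                "value": res.cell_value,
                "sentinel": res.sentinel,
                "reason": matrix.reason(gene, dataset),
                "stage1_p": res.stage1_p,
                "ss_p": res.ss_p,
                "n_snps": res.n_snps,
            })
    meta = {
        "alpha": matrix.alpha,
        "bonferroni_m_submitted": matrix.m,
        "m_with_data": matrix.m_with_data,
        "stage1_threshold": matrix.alpha / matrix.m if matrix.m else None,
        "cells": cells,
    }
    p = str(path)
    json_path = p[: -len(".tsv")] + ".json" if p.endswith(".tsv") else p + ".json"
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_heatmap_table(path) -> pd.DataFrame:
    """Re-read an exported heatmap TSV (round-trip helper)."""
    return pd.read_csv(path, sep="\t", index_col="gene")


def export_results_table(matrix: HeatmapMatrix, path) -> None:
    """One row per gene×dataset: status, value, stage1_p, n_snps (TSV)."""
    rows = []
    for (gene, dataset), res in matrix.results.items():
        rows.append({
            "gene": gene,
            "dataset": dataset,
            "status": res.status.value,
            "value": res.cell_value,
            "neglog10_ss_p": res.neglog10_ss_p,
            "stage1_p": res.stage1_p,
            "ss_z": res.ss_z,
            "ss_p": res.ss_p,
            "n_snps": res.n_snps,
            "reason": res.reason,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
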