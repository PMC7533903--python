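"""Droplet and gene QC filters applied around the UMI window.

Order of application: lower UMI bound -> upper UMI bound -> mitochondrial
ceiling -> gene-count ceiling -> gene-count floor -> gene prevalence floor ->
TCR/BCR gene masking. Boundary conventions are literal: a cell is removed if
mito fraction >= mito_max or n_genes >= max_genes_per_cell, kept only if
n_genes >= min_genes_per_cell, and kept in the UMI window if
lower < total <= upper (the cell sitting exactly at the percentile is an
observed cell and is retained).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .census import ChainCensus
from .io import CountMatrix
from .thresholds import ThresholdSet

__all__ = [
    "DropletProfile",
    "FilterParams",
    "FilterReport",
    "profile_droplets",
    "apply_qc",
    "mask_vdj_genes",
    "VDJ_GENE_PATTERN",
]

# V(D)J segment genes (TRAV1-2, TRBJ2-7, IGKV4-1, ...) plus immunoglobulin
# heavy-constant genes whose symbols omit the segment letter (IGHM, IGHG1,
# IGHA2, IGHE, IGHD). The segment letter must sit right after the locus code,
# so TRAF1 or IGHMBP2-like symbols never match.
VDJ_GENE_PATTERN = r"^(TR[ABGD][VDJC]|IG[HKL][VDJC]|IGH(A[12]?|D|E|G[1-4P]?|M)$)"


@dataclass(frozen=True)
class DropletProfile:
    """Per-barcode QC metrics: UMI total, gene count, mito fraction, census."""

    barcode: str
    total_umi: int
    n_genes: int
    mito_fraction: float
    census: ChainCensus | None = None


@dataclass(frozen=True)
class FilterParams:
    """QC filter settings.

    Defaults: genes must be expressed in >=10 retained cells; cells must
    express >=200 genes; cells with >=10% mitochondrial UMIs or >=3000 genes
    are removed as likely dead cells or multiplets.
    """

    min_cells_per_gene: int = 10
    min_genes_per_cell: int = 200
    mito_max: float = 0.10
    max_genes_per_cell: int = 3000
    mito_prefix: str = "MT-"
    mito_case_insensitive: bool = False
    vdj_gene_pattern: str = VDJ_GENE_PATTERN


@dataclass
class FilterReport:
    """Counts removed per rule, in application order."""

    n_input_barcodes: int
    n_input_genes: int
    removed: dict[str, int] = field(default_factory=dict)
    n_retained_barcodes: int = 0
    n_retained_genes: int = 0
    retained_barcodes: list[str] = field(default_factory=list)

    def check_totals(self) -> bool:
        return sum(self.removed[k] for k in _CELL_RULES) + self.n_retained_barcodes == self.n_input_barcodes


_CELL_RULES = ("lower_umi", "upper_umi", "mito_fraction", "max_genes", "min_genes")


def _mito_mask(symbols: Sequence[str], params: FilterParams) -> np.ndarray:
    if params.mito_case_insensitive:
        prefix = params.mito_prefix.upper()
        return np.array([s.upper().startswith(prefix) for s in symbols], bool)
    return np.array([s.startswith(params.mito_prefix) for s in symbols], bool)


def profile_droplets(
    matrix: CountMatrix,
    censuses: Mapping[str, ChainCensus] | None = None,
    params: FilterParams = FilterParams(),
) -> list[DropletProfile]:
    """Compute per-barcode UMI total, expressed-gene count and mito fraction.

    Mitochondrial genes are identified by symbol prefix (default ``MT-``).
    A barcode with zero UMIs has mito fraction 0 by convention.
    """
    counts = matrix.counts
    totals = np.asarray(counts.sum(axis=0)).ravel()
    n_genes = counts.getnnz(axis=0)
    mito = _mito_mask(matrix.feature_symbols, params)
    if mito.any():
        mito_totals = np.asarray(counts[mito.nonzero()[0], :].sum(axis=0)).ravel()
    else:
        mito_totals = np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito_totals / np.maximum(totals, 1), 0.0)
    return [
        DropletProfile(
            barcode=b,
            total_umi=int(totals[j]),
            n_genes=int(n_genes[j]),
            mito_fraction=float(frac[j]),
            census=None if censuses is None else censuses.get(b),
        )
        for j, b in enumerate(matrix.barcodes)
    ]


def mask_vdj_genes(
    feature_symbols: Sequence[str],
    pattern: str = VDJ_GENE_PATTERN,
) -> np.ndarray:
    """Boolean mask, True where a symbol is a TCR or BCR gene to remove.

    TCR/BCR segment genes are masked so that downstream transcriptional
    clustering is not driven by clonotype identity.
    """
    rx = re.compile(pattern)
    return np.array([bool(rx.match(s)) for s in feature_symbols], bool)


def apply_qc(
    matrix: CountMatrix,
    profiles: Sequence[DropletProfile],
    thresholds: ThresholdSet,
    params: FilterParams = FilterParams(),
) -> tuple[CountMatrix, FilterReport]:
    """Apply the full QC filter cascade and return the retained matrix.

    Cells are removed, in order, by: UMI total <= lower threshold; UMI total
    > upper threshold; mito fraction >= mito_max; n_genes >= max ceiling;
    n_genes < min floor. Genes are then removed if expressed in fewer than
    ``min_cells_per_gene`` retained cells, or if they match the TCR/BCR gene
    pattern. Each rule's removals are counted against the cells surviving the
    previous rules.

    Raises
    ------
    ValueError
        If no cell survives; the message carries the stage-wise counts.
    """
    if [p.barcode for p in profiles] != list(matrix.barcodes):
        by_bc = {p.barcode: p for p in profiles}
        try:
            profiles = [by_bc[b] for b in matrix.barcodes]
        except KeyError as exc:
            raise ValueError(f"profile missing for barcode {exc}") from exc

    report = FilterReport(
        n_input_barcodes=len(matrix.barcodes), n_input_genes=len(matrix.feature_ids)
    )
    alive = np.ones(len(profiles), bool)

    def cut(rule: str, fails: np.ndarray) -> None:
        removed = alive & fails
        report.removed[rule] = int(removed.sum())
        alive[removed] = False

    totals = np.array([p.total_umi for p in profiles])
    n_genes = np.array([p.n_genes for p in profiles])
    mito = np.array([p.mito_fraction for p in profiles])

    cut("lower_umi", totals <= thresholds.lower)
    cut("upper_umi", totals > thresholds.upper)
    cut("mito_fraction", mito >= params.mito_max)
    cut("max_genes", n_genes >= params.max_genes_per_cell)
    cut("min_genes", n_genes < params.min_genes_per_cell)

    report.n_retained_barcodes = int(alive.sum())
    report.retained_barcodes = [b for b, k in zip(matrix.barcodes, alive) if k]
    if report.n_retained_barcodes == 0:
        raise ValueError(
            "all cells removed by QC; removals per stage: " f"{report.removed}"
        )

    cell_filtered = matrix.subset(barcode_mask=alive)
    cells_per_gene = cell_filtered.counts.getnnz(axis=1)
    gene_keep = cells_per_gene >= params.min_cells_per_gene
    report.removed["gene_floor"] = int((~gene_keep).sum())
    vdj = mask_vdj_genes(cell_filtered.feature_symbols, params.vdj_gene_pattern)
    report.removed["vdj_mask"] = int((gene_keep & vdj).sum())
    gene_keep &= ~vdj

    out = cell_filtered.subset(feature_mask=gene_keep)
    report.n_retained_genes = out.shape[0]
    return out, report
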