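"""Readers and writers for the 10x-style droplet file formats.

Two formats are handled: the MatrixMarket count-matrix trio
(``matrix.mtx[.gz]`` + ``barcodes.tsv[.gz]`` + ``features.tsv[.gz]``) and the
V(D)J contig annotation table (``filtered_contig_annotations.csv`` dialect).
Gzip-compressed inputs are accepted transparently. Parsing of the container
formats themselves is delegated to :mod:`scipy.io` and :mod:`pandas`; this
module adds the validation the pipeline relies on (sidecar/header dimension
agreement, integral non-negative counts, mandatory contig columns).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Chain",
    "ContigRecord",
    "CountMatrix",
    "FormatError",
    "read_count_matrix",
    "read_contigs",
    "write_count_matrix",
    "write_contigs",
]


class FormatError(ValueError):
    """An input file violates the expected format."""


class Chain(str, Enum):
    """TCR chain locus of a contig; loci other than TRA/TRB are ``OTHER``."""

    TRA = "TRA"
    TRB = "TRB"
    OTHER = "other"

    @classmethod
    def parse(cls, value: object) -> "Chain":
        token = str(value).strip().upper()
        if token == "TRA":
            return cls.TRA
        if token == "TRB":
            return cls.TRB
        return cls.OTHER


@dataclass(frozen=True)
class ContigRecord:
    """One assembled V(D)J contig call for one droplet barcode."""

    barcode: str
    chain: Chain
    productive: bool
    full_length: bool = True
    high_confidence: bool = True
    umis: int = 0

    def __post_init__(self) -> None:
        if not self.barcode:
            raise ValueError("contig barcode must be non-empty")
        if self.umis < 0:
            raise ValueError("contig UMI count must be non-negative")


@dataclass
class CountMatrix:
    """A droplet gene-expression count matrix (features x barcodes).

    ``feature_ids`` and ``feature_symbols`` have equal length; symbols are the
    names used for mitochondrial / V(D)J-gene pattern matching. ``counts`` is
    a sparse CSC matrix of non-negative integers.
    """

    feature_ids: list[str]
    feature_symbols: list[str]
    barcodes: list[str]
    counts: sp.csc_matrix = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        n_feat, n_bc = self.counts.shape
        if len(self.feature_ids) != n_feat or len(self.feature_symbols) != n_feat:
            raise FormatError(
                f"feature list length ({len(self.feature_ids)}) does not match "
                f"matrix row count ({n_feat})"
            )
        if len(self.barcodes) != n_bc:
            raise FormatError(
                f"barcode list length ({len(self.barcodes)}) does not match "
                f"matrix column count ({n_bc})"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("barcodes are not unique")
        _validate_counts(self.counts)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def umi_totals(self) -> np.ndarray:
        """Per-barcode total UMI counts (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset(
        self,
        feature_mask: np.ndarray | None = None,
        barcode_mask: np.ndarray | None = None,
    ) -> "CountMatrix":
        """Return a new matrix restricted to the masked features/barcodes."""
        fm = np.ones(self.shape[0], bool) if feature_mask is None else np.asarray(feature_mask, bool)
        bm = np.ones(self.shape[1], bool) if barcode_mask is None else np.asarray(barcode_mask, bool)
        return CountMatrix(
            feature_ids=[f for f, k in zip(self.feature_ids, fm) if k],
            feature_symbols=[s for s, k in zip(self.feature_symbols, fm) if k],
            barcodes=[b for b, k in zip(self.barcodes, bm) if k],
            counts=self.counts[np.ix_(fm.nonzero()[0], bm.nonzero()[0])],
        )


def _validate_counts(m: sp.spmatrix) -> None:
    data = m.data
    if data.size == 0:
        return
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(np.equal(np.mod(data, 1), 0)):
            raise FormatError("count matrix contains non-integer entries")
    if data.min() < 0:
        raise FormatError("count matrix contains negative entries")


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_lines(path: str | Path) -> list[str]:
    with _open_maybe_gzip(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_count_matrix(
    mtx_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
) -> CountMatrix:
    """Read a 10x-layout MatrixMarket count matrix with its sidecars.

    Duplicate (row, col) coordinate entries are summed. The features sidecar
    may carry one column (symbol only) or two or more (id, symbol, ...).

    Raises
    ------
    FormatError
        If header dimensions disagree with the sidecar lengths, or the matrix
        holds negative or non-integer values.
    """
    try:
        with _open_maybe_gzip(mtx_path, "rb") as fh:
            raw = scipy.io.mmread(fh)
    except ValueError as exc:
        raise FormatError(f"cannot parse MatrixMarket file {mtx_path}: {exc}") from exc
    counts = sp.csc_matrix(raw)  # tocsc sums duplicate coordinate entries
    counts.sum_duplicates()
    counts.eliminate_zeros()

    barcodes = _read_lines(barcodes_path)
    feat_rows = [line.split("\t") for line in _read_lines(features_path)]
    if feat_rows and len(feat_rows[0]) >= 2:
        feature_ids = [r[0] for r in feat_rows]
        feature_symbols = [r[1] for r in feat_rows]
    else:
        feature_ids = [r[0] for r in feat_rows]
        feature_symbols = list(feature_ids)

    return CountMatrix(feature_ids, feature_symbols, barcodes, counts)


def write_count_matrix(matrix: CountMatrix, out_dir: str | Path, gzip_output: bool = False) -> dict[str, Path]:
    """Write a matrix in the 10x trio layout; returns the written paths.

    ``read_count_matrix(*write_count_matrix(m))`` round-trips exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzip_output else ""
    paths = {
        "matrix": out_dir / f"matrix.mtx{suffix}",
        "barcodes": out_dir / f"barcodes.tsv{suffix}",
        "features": out_dir / f"features.tsv{suffix}",
    }
    coo = sp.coo_matrix(matrix.counts)
    with _open_maybe_gzip(paths["matrix"], "wb") as fh:
        scipy.io.mmwrite(fh, coo, field="integer")
    with _open_maybe_gzip(paths["barcodes"], "wt") as fh:
        fh.writelines(b + "\n" for b in matrix.barcodes)
    with _open_maybe_gzip(paths["features"], "wt") as fh:
        fh.writelines(
            f"{fid}\t{sym}\tGene Expression\n"
            for fid, sym in zip(matrix.feature_ids, matrix.feature_symbols)
        )
    return paths


_TRUE_TOKENS = {"true", "t", "1", "yes"}
_FALSE_TOKENS = {"false", "f", "0", "no", "none", "nan", ""}


def _parse_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise FormatError(f"cannot interpret {value!r} as a boolean")


def read_contigs(csv_path: str | Path) -> list[ContigRecord]:
    """Read a 10x-dialect contig annotation CSV into ContigRecords.

    Mandatory columns: ``barcode``, ``chain``, ``productive``. Optional
    ``full_length`` / ``high_confidence`` default to true with a warning and
    ``umis`` defaults to 0. Column order is irrelevant; boolean columns accept
    both "True"/"False" and "true"/"false" spellings.
    """
    with _open_maybe_gzip(csv_path) as fh:
        table = pd.read_csv(fh, dtype=str, keep_default_na=False)
    table.columns = [c.strip().lower() for c in table.columns]
    missing = {"barcode", "chain", "productive"} - set(table.columns)
    if missing:
        raise FormatError(f"contig table is missing mandatory columns: {sorted(missing)}")
    for optional in ("full_length", "high_confidence"):
        if optional not in table.columns:
            warnings.warn(
                f"contig table lacks column {optional!r}; assuming true for all contigs",
                stacklevel=2,
            )
            table[optional] = "true"
    if "umis" not in table.columns:
        table["umis"] = "0"

    records = []
    for row in table.itertuples(index=False):
        records.append(
            ContigRecord(
                barcode=str(row.barcode),
                chain=Chain.parse(row.chain),
                productive=_parse_bool(row.productive),
                full_length=_parse_bool(row.full_length),
                high_confidence=_parse_bool(row.high_confidence),
                umis=int(float(row.umis)) if str(row.umis).strip() else 0,
            )
        )
    return records


def write_contigs(contigs: Sequence[ContigRecord], csv_path: str | Path) -> Path:
    """Write contigs back out in the annotation-CSV dialect."""
    csv_path = Path(csv_path)
    frame = pd.DataFrame(
        {
            "barcode": [c.barcode for c in contigs],
            "chain": [c.chain.value if c.chain is not Chain.OTHER else "Multi" for c in contigs],
            "productive": ["True" if c.productive else "False" for c in contigs],
            "full_length": ["True" if c.full_length else "False" for c in contigs],
            "high_confidence": ["True" if c.high_confidence else "False" for c in contigs],
            "umis": [c.umis for c in contigs],
        }
    )
    frame.to_csv(csv_path, index=False)
    return csv_path


def strip_barcode_suffix(barcode: str) -> str:
    """Drop a trailing ``-<digits>`` GEM-well suffix, e.g. ``AAAC-1`` -> ``AAAC``."""
    stem, sep, tail = barcode.rpartition("-")
    if sep and tail.isdigit():
        return stem
    return barcode
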