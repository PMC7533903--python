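"""Per-barcode productive TCR chain census and droplet classification.

Most T cells carry one productive TCRα and one productive TCRβ chain. Because
TCRα rearranges on both chromosomes, a sizeable minority (10–19%) of cells
express two productive TCRα chains, and 6–7% express two TCRβ chains. Three or
more productive chains at a single locus is impossible for one diploid cell,
so a barcode with >2 productive TRA and/or >2 productive TRB chains must
contain more than one cell: a *structural multiplet*. Barcodes with exactly
one productive chain at either locus (and no locus above two) anchor the UMI
distribution of presumed live single cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import Chain, ContigRecord

__all__ = ["ChainCensus", "CountingRule", "census", "group_sizes", "census_table"]

GROUPS = ("0", "1", "2", "3plus")


def _group_of(n: int) -> str:
    return str(n) if n <= 2 else "3plus"


@dataclass(frozen=True)
class CountingRule:
    """Which contigs count toward the per-barcode chain census.

    Productivity is the hard requirement; the full-length and high-confidence
    flags are configurable tighteners that guard against ambient contigs
    inflating the counts.
    """

    require_productive: bool = True
    require_full_length: bool = True
    require_high_confidence: bool = True

    def counts(self, contig: ContigRecord) -> bool:
        if contig.chain not in (Chain.TRA, Chain.TRB):
            return False
        if self.require_productive and not contig.productive:
            return False
        if self.require_full_length and not contig.full_length:
            return False
        if self.require_high_confidence and not contig.high_confidence:
            return False
        return True


@dataclass(frozen=True)
class ChainCensus:
    """Productive TRA/TRB chain counts and derived class for one barcode."""

    barcode: str
    n_tra: int
    n_trb: int

    @property
    def group_tra(self) -> str:
        return _group_of(self.n_tra)

    @property
    def group_trb(self) -> str:
        return _group_of(self.n_trb)

    @property
    def is_structural_multiplet(self) -> bool:
        """>2 chains at either locus — impossible for a single diploid cell."""
        return self.n_tra > 2 or self.n_trb > 2

    @property
    def is_single_chain(self) -> bool:
        """Exactly one chain at either locus and no locus above two."""
        return (self.n_tra == 1 or self.n_trb == 1) and not self.is_structural_multiplet


def census(
    contigs: Iterable[ContigRecord],
    barcodes: Sequence[str] | None = None,
    rule: CountingRule = CountingRule(),
) -> dict[str, ChainCensus]:
    """Count qualifying TRA/TRB contigs per barcode.

    Parameters
    ----------
    contigs
        Parsed contig records; row order is irrelevant.
    barcodes
        Optional droplet barcode list (e.g. the GEX matrix columns). Every
        listed barcode receives a census even if it has no contigs (counts 0).
    rule
        Which contigs qualify; default requires productive AND full_length AND
        high_confidence.
    """
    tra: dict[str, int] = {}
    trb: dict[str, int] = {}
    seen: dict[str, None] = {}
    if barcodes is not None:
        for b in barcodes:
            seen[b] = None
    for contig in contigs:
        seen.setdefault(contig.barcode, None)
        if not rule.counts(contig):
            continue
        if contig.chain is Chain.TRA:
            tra[contig.barcode] = tra.get(contig.barcode, 0) + 1
        else:
            trb[contig.barcode] = trb.get(contig.barcode, 0) + 1
    return {
        b: ChainCensus(barcode=b, n_tra=tra.get(b, 0), n_trb=trb.get(b, 0))
        for b in seen
    }


def group_sizes(censuses: Mapping[str, ChainCensus]) -> pd.DataFrame:
    """Barcode counts per chain-count group {0, 1, 2, 3plus} for each locus."""
    out = pd.DataFrame(0, index=list(GROUPS), columns=["tra", "trb"], dtype=int)
    out.index.name = "group"
    for c in censuses.values():
        out.loc[c.group_tra, "tra"] += 1
        out.loc[c.group_trb, "trb"] += 1
    return out


def census_table(censuses: Mapping[str, ChainCensus]) -> pd.DataFrame:
    """Flat per-barcode table (exportable as TSV)."""
    return pd.DataFrame(
        {
            "barcode": [c.barcode for c in censuses.values()],
            "n_tra": [c.n_tra for c in censuses.values()],
            "n_trb": [c.n_trb for c in censuses.values()],
            "group_tra": [c.group_tra for c in censuses.values()],
            "group_trb": [c.group_trb for c in censuses.values()],
            "is_structural_multiplet": [c.is_structural_multiplet for c in censuses.values()],
            "is_single_chain": [c.is_single_chain for c in censuses.values()],
        }
    )


def write_census(censuses: Mapping[str, ChainCensus], path: str | Path) -> Path:
    path = Path(path)
    census_table(censuses).to_csv(path, sep="\t", index=False)
    return path
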