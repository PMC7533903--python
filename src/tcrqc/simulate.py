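"""Synthetic paired GEX + V(D)J droplet datasets with ground-truth labels.

The generator emulates the droplet populations a raw 10x matrix contains:

* **live singlets** — UMI totals lognormal, low mitochondrial fraction, one
  productive TCRα chain (two with probability ``dual_tra_prob``, reflecting
  the 10–19% of T cells with two rearranged TCRα alleles) and one TCRβ chain
  (two with probability ``dual_trb_prob``, 6–7%);
* **doublets** — element-wise sum of two independent live cells' count
  vectors; their chain set is the union of the component cells' chains, so a
  doublet can expose >2 productive chains at one locus, which is impossible
  for a single diploid cell;
* **dead cells** — UMI totals scaled down, mitochondrial fraction drawn from
  a high-mean Beta, no productive contigs (configurable leak);
* **ambient/empty droplets** — low-UMI multinomial draws from the pooled live
  expression profile, no contigs.

Each expressed chain is independently lost with probability
``chain_dropout`` before being emitted as a productive contig, modelling
V(D)J capture failure. Gene-expression realism is deliberately minimal (a
fixed multinomial profile with a mitochondrial block): the QC method consumes
only UMI totals, gene counts, mitochondrial fractions and chain counts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import Chain, ContigRecord, CountMatrix, write_contigs, write_count_matrix

__all__ = ["SimConfig", "SimTruth", "simulate_droplets", "truth_confusion", "write_simulation"]

_MITO_SYMBOLS = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]
# a few real TCR/BCR segment symbols so the V(D)J gene mask has work to do
_VDJ_SYMBOLS = ["TRAC", "TRBC1", "TRBC2", "TRAV1-2", "TRBV20-1", "IGHM", "IGKC"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; droplet composition rates must sum below 1,
    the remainder being live singlets."""

    n_droplets: int = 2000
    doublet_rate: float = 0.10
    dead_rate: float = 0.15
    ambient_rate: float = 0.20
    umi_logmean: float = 8.5
    umi_logsd: float = 0.5
    dead_umi_scale: float = 0.1
    ambient_umi_logmean: float = 3.9
    ambient_umi_logsd: float = 0.5
    mito_live_beta: tuple[float, float] = (2.0, 48.0)
    mito_dead_beta: tuple[float, float] = (9.0, 21.0)
    dual_tra_prob: float = 0.15
    dual_trb_prob: float = 0.065
    chain_dropout: float = 0.05
    dead_chain_leak: float = 0.0
    low_conf_contig_rate: float = 0.0
    contig_umi_mean: float = 4.0
    n_genes_total: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("doublet_rate", "dead_rate", "ambient_rate", "chain_dropout",
                     "dual_tra_prob", "dual_trb_prob", "dead_chain_leak",
                     "low_conf_contig_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1); got {v}")
        if self.singlet_rate <= 0:
            raise ValueError(
                "doublet_rate + dead_rate + ambient_rate must leave a positive "
                "singlet fraction"
            )
        if self.n_droplets < 1 or self.n_genes_total <= len(_MITO_SYMBOLS) + len(_VDJ_SYMBOLS):
            raise ValueError("n_droplets must be >=1 and n_genes_total large enough")

    @property
    def singlet_rate(self) -> float:
        return 1.0 - self.doublet_rate - self.dead_rate - self.ambient_rate


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated droplet."""

    barcode: str
    label: str  # singlet | doublet | dead | ambient
    component_cells: tuple[str, ...]
    true_n_tra: int  # pre-dropout productive chain counts
    true_n_trb: int


_BASES = np.array(list("ACGT"))


def _barcodes(rng: np.random.Generator, n: int, length: int = 14) -> list[str]:
    seen: dict[str, None] = {}
    while len(seen) < n:
        for bc in ["".join(row) + "-1" for row in _BASES[rng.integers(0, 4, size=(n - len(seen), length))]]:
            seen.setdefault(bc, None)
    return list(seen)[:n]


class _CellFactory:
    """Draws live single cells: a count vector plus its productive chains."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        n_mito = len(_MITO_SYMBOLS)
        n_other = config.n_genes_total - n_mito
        # fixed expression profile over non-mito genes, drawn once per simulation
        self.body_profile = rng.dirichlet(np.ones(n_other))
        self.mito_idx = np.arange(n_mito)
        self.body_idx = np.arange(n_mito, config.n_genes_total)
        self._serial = 0
        self.cell_totals: dict[str, int] = {}

    def draw(self) -> tuple[str, np.ndarray, list[str], list[str]]:
        cfg, rng = self.config, self.rng
        self._serial += 1
        cell_id = f"cell{self._serial:06d}"
        total = max(1, int(rng.lognormal(cfg.umi_logmean, cfg.umi_logsd)))
        mito_frac = rng.beta(*cfg.mito_live_beta)
        counts = self._allocate(total, mito_frac)
        self.cell_totals[cell_id] = int(counts.sum())
        n_tra = 1 + (rng.random() < cfg.dual_tra_prob)
        n_trb = 1 + (rng.random() < cfg.dual_trb_prob)
        tra = [f"{cell_id}:TRA{k}" for k in range(n_tra)]
        trb = [f"{cell_id}:TRB{k}" for k in range(n_trb)]
        return cell_id, counts, tra, trb

    def _allocate(self, total: int, mito_frac: float) -> np.ndarray:
        rng = self.rng
        counts = np.zeros(self.config.n_genes_total, dtype=np.int64)
        n_mito = rng.binomial(total, mito_frac)
        if n_mito:
            counts[self.mito_idx] += rng.multinomial(
                n_mito, np.full(len(self.mito_idx), 1.0 / len(self.mito_idx))
            )
        if total - n_mito:
            counts[self.body_idx] += rng.multinomial(total - n_mito, self.body_profile)
        return counts

    def draw_dead(self) -> np.ndarray:
        cfg, rng = self.config, self.rng
        total = max(1, int(rng.lognormal(cfg.umi_logmean + np.log(cfg.dead_umi_scale), cfg.umi_logsd)))
        return self._allocate(total, rng.beta(*cfg.mito_dead_beta))

    def draw_ambient(self) -> np.ndarray:
        cfg, rng = self.config, self.rng
        total = max(1, int(rng.lognormal(cfg.ambient_umi_logmean, cfg.ambient_umi_logsd)))
        # pooled profile: mean live mito weight plus the fixed body profile
        mean_mito = cfg.mito_live_beta[0] / sum(cfg.mito_live_beta)
        return self._allocate(total, mean_mito)


def _feature_lists(n_genes_total: int) -> tuple[list[str], list[str]]:
    symbols = list(_MITO_SYMBOLS) + list(_VDJ_SYMBOLS)
    symbols += [f"GENE{k:04d}" for k in range(n_genes_total - len(symbols))]
    ids = [f"SIM{k:07d}" for k in range(n_genes_total)]
    return ids, symbols


def simulate_droplets(
    config: SimConfig = SimConfig(),
    return_cell_totals: bool = False,
):
    """Generate a deterministic synthetic droplet dataset.

    Returns the count matrix, the productive-contig table and one SimTruth
    per droplet. Identical configs (including seed) give identical output.
    With ``return_cell_totals`` a fourth element maps each component cell id
    to its UMI total, for conservation checks (a doublet column must equal
    the sum of its two component cells).
    """
    rng = np.random.default_rng(config.seed)
    factory = _CellFactory(config, rng)
    barcodes = _barcodes(rng, config.n_droplets)
    labels = rng.choice(
        ["singlet", "doublet", "dead", "ambient"],
        size=config.n_droplets,
        p=[config.singlet_rate, config.doublet_rate, config.dead_rate, config.ambient_rate],
    )

    dense = np.zeros((config.n_genes_total, config.n_droplets), dtype=np.int64)
    contigs: list[ContigRecord] = []
    truth: list[SimTruth] = []

    def emit(barcode: str, chain: Chain, chain_ids: list[str]) -> int:
        """Apply per-chain dropout and emit surviving productive contigs."""
        kept = 0
        for _ in chain_ids:
            if rng.random() < config.chain_dropout:
                continue
            kept += 1
            contigs.append(
                ContigRecord(
                    barcode=barcode,
                    chain=chain,
                    productive=True,
                    full_length=True,
                    high_confidence=True,
                    umis=1 + int(rng.poisson(config.contig_umi_mean)),
                )
            )
        return kept

    for j, (bc, label) in enumerate(zip(barcodes, labels)):
        if label == "singlet":
            cell_id, counts, tra, trb = factory.draw()
            dense[:, j] = counts
            cells = (cell_id,)
        elif label == "doublet":
            id1, c1, tra1, trb1 = factory.draw()
            id2, c2, tra2, trb2 = factory.draw()
            dense[:, j] = c1 + c2
            tra, trb = tra1 + tra2, trb1 + trb2
            cells = (id1, id2)
        elif label == "dead":
            dense[:, j] = factory.draw_dead()
            if rng.random() < config.dead_chain_leak:
                tra, trb = ["leak:TRA"], ["leak:TRB"]
                cells = ()
            else:
                tra, trb, cells = [], [], ()
        else:  # ambient
            dense[:, j] = factory.draw_ambient()
            tra, trb, cells = [], [], ()

        emit(bc, Chain.TRA, tra)
        emit(bc, Chain.TRB, trb)
        if config.low_conf_contig_rate and rng.random() < config.low_conf_contig_rate:
            contigs.append(
                ContigRecord(
                    barcode=bc, chain=Chain.TRA, productive=True,
                    full_length=False, high_confidence=False, umis=1,
                )
            )
        truth.append(
            SimTruth(
                barcode=bc,
                label=str(label),
                component_cells=cells,
                true_n_tra=len(tra),
                true_n_trb=len(trb),
            )
        )

    ids, symbols = _feature_lists(config.n_genes_total)
    matrix = CountMatrix(
        feature_ids=ids,
        feature_symbols=symbols,
        barcodes=barcodes,
        counts=sp.csc_matrix(dense),
    )
    if return_cell_totals:
        return matrix, contigs, truth, dict(factory.cell_totals)
    return matrix, contigs, truth


def truth_confusion(
    truth: Sequence[SimTruth],
    retained_barcodes: Sequence[str],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Retained/removed counts per true label, plus removal metrics.

    Metrics: ``doublet_removal_sensitivity`` (fraction of true doublets
    removed) and ``singlet_retention`` (fraction of true singlets retained).

    Raises
    ------
    ValueError
        If a retained barcode is absent from the truth table.
    """
    known = {t.barcode for t in truth}
    unknown = set(retained_barcodes) - known
    if unknown:
        raise ValueError(f"retained barcodes not present in truth: {sorted(unknown)[:5]}")
    retained = set(retained_barcodes)
    labels = ["singlet", "doublet", "dead", "ambient"]
    table = pd.DataFrame(0, index=labels, columns=["retained", "removed"], dtype=int)
    table.index.name = "label"
    for t in truth:
        table.loc[t.label, "retained" if t.barcode in retained else "removed"] += 1
    totals = table.sum(axis=1)
    metrics = {
        "doublet_removal_sensitivity": (
            float(table.loc["doublet", "removed"] / totals["doublet"]) if totals["doublet"] else float("nan")
        ),
        "singlet_retention": (
            float(table.loc["singlet", "retained"] / totals["singlet"]) if totals["singlet"] else float("nan")
        ),
    }
    return table, metrics


def write_simulation(
    out_dir: str | Path,
    matrix: CountMatrix,
    contigs: Sequence[ContigRecord],
    truth: Sequence[SimTruth],
) -> dict[str, Path]:
    """Write the dataset in the exact formats the readers consume."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = write_count_matrix(matrix, out_dir)
    paths["contigs"] = write_contigs(contigs, out_dir / "filtered_contig_annotations.csv")
    truth_path = out_dir / "truth.tsv"
    pd.DataFrame([asdict(t) for t in truth]).assign(
        component_cells=lambda d: d["component_cells"].map(lambda c: ";".join(c))
    ).to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
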