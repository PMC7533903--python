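"""End-to-end QC orchestration: read, threshold, filter, report, write.

The pipeline per sample is: read the raw matrix and contig table; compute the
lower UMI threshold on all barcodes; census productive TRA/TRB chains; anchor
the upper UMI threshold to the single-chain barcodes surviving the lower
threshold; apply the filter cascade; write the filtered matrix, retained
barcode list and a JSON QC report. Multi-sample mode computes per-sample
thresholds and, when aggregation is requested, applies the mean of the
per-sample upper thresholds to every sample.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io as vdj_io
from .census import CountingRule, census, write_census
from .filters import FilterParams, FilterReport, apply_qc, profile_droplets
from .stats import group_qc_stats
from .thresholds import (
    ThresholdParams,
    ThresholdSet,
    aggregate_thresholds,
    lower_umi_threshold,
    percentile_sweep,
    upper_umi_threshold,
)

logger = logging.getLogger(__name__)

__all__ = ["QCReport", "run_pipeline", "run_multi_sample"]


@dataclasses.dataclass
class QCReport:
    """Everything one QC run decided, with full parameter provenance."""

    sample_id: str
    thresholds: ThresholdSet
    filter_report: FilterReport
    group_stats: pd.DataFrame
    threshold_params: ThresholdParams
    filter_params: FilterParams
    counting_rule: CountingRule
    aggregate_upper: float | None = None

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "thresholds": dataclasses.asdict(self.thresholds),
            "aggregate_upper": self.aggregate_upper,
            "n_input_barcodes": self.filter_report.n_input_barcodes,
            "n_retained_barcodes": self.filter_report.n_retained_barcodes,
            "n_input_genes": self.filter_report.n_input_genes,
            "n_retained_genes": self.filter_report.n_retained_genes,
            "removed_per_rule": self.filter_report.removed,
            "group_stats": self.group_stats.to_dict(orient="records"),
            "params": {
                "thresholds": dataclasses.asdict(self.threshold_params),
                "filters": dataclasses.asdict(self.filter_params),
                "counting_rule": dataclasses.asdict(self.counting_rule),
            },
        }

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path


def run_pipeline(
    gex_dir: str | Path,
    vdj_csv: str | Path,
    out_dir: str | Path,
    sample_id: str = "sample",
    threshold_params: ThresholdParams = ThresholdParams(),
    filter_params: FilterParams = FilterParams(),
    counting_rule: CountingRule = CountingRule(),
    upper_override: float | None = None,
    strip_suffix: bool = False,
    write_sweep: bool = False,
    write_plot: bool = False,
) -> QCReport:
    """Run the full QC pipeline for one sample and write its outputs.

    ``gex_dir`` must hold the MTX trio (``matrix.mtx[.gz]``,
    ``barcodes.tsv[.gz]``, ``features.tsv[.gz]``); ``vdj_csv`` is the contig
    annotation table. ``upper_override`` replaces the sample's own upper
    threshold (used for cross-sample aggregation). With ``strip_suffix`` the
    GEM-well suffix is stripped from both GEX and V(D)J barcodes before
    joining.
    """
    gex_dir = Path(gex_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    matrix = _read_gex(gex_dir)
    contigs = vdj_io.read_contigs(vdj_csv)
    if strip_suffix:
        matrix.barcodes = [vdj_io.strip_barcode_suffix(b) for b in matrix.barcodes]
        contigs = [
            dataclasses.replace(c, barcode=vdj_io.strip_barcode_suffix(c.barcode))
            for c in contigs
        ]
    logger.info(
        "%s: %d barcodes x %d genes; %d contigs",
        sample_id, len(matrix.barcodes), len(matrix.feature_ids), len(contigs),
    )

    umi_totals = dict(zip(matrix.barcodes, matrix.umi_totals()))
    lower = lower_umi_threshold(list(umi_totals.values()), threshold_params)
    logger.info("%s: lower UMI threshold %.1f", sample_id, lower)

    censuses = census(contigs, barcodes=matrix.barcodes, rule=counting_rule)
    thresholds = upper_umi_threshold(
        censuses, umi_totals, threshold_params, sample_id=sample_id, lower=lower
    )
    logger.info(
        "%s: upper UMI threshold %.1f (percentile %.1f of %d single-chain cells; "
        "%d structural multiplets in window)",
        sample_id, thresholds.upper, threshold_params.percentile,
        thresholds.n_single_chain, thresholds.n_multiplet_class,
    )
    if upper_override is not None:
        thresholds = dataclasses.replace(thresholds, upper=float(upper_override))
        logger.info("%s: upper threshold overridden to %.1f", sample_id, thresholds.upper)

    profiles = profile_droplets(matrix, censuses, filter_params)
    filtered, filter_report = apply_qc(matrix, profiles, thresholds, filter_params)
    for rule, n in filter_report.removed.items():
        logger.info("%s: rule %-14s removed %d", sample_id, rule, n)
    logger.info(
        "%s: retained %d/%d barcodes, %d/%d genes",
        sample_id,
        filter_report.n_retained_barcodes, filter_report.n_input_barcodes,
        filter_report.n_retained_genes, filter_report.n_input_genes,
    )

    stats_table = group_qc_stats(profiles, censuses)
    report = QCReport(
        sample_id=sample_id,
        thresholds=thresholds,
        filter_report=filter_report,
        group_stats=stats_table,
        threshold_params=threshold_params,
        filter_params=filter_params,
        counting_rule=counting_rule,
    )

    vdj_io.write_count_matrix(filtered, out_dir / "filtered")
    (out_dir / "retained_barcodes.txt").write_text(
        "".join(b + "\n" for b in filter_report.retained_barcodes)
    )
    write_census(censuses, out_dir / "chain_census.tsv")
    stats_table.to_csv(out_dir / "group_stats.tsv", sep="\t", index=False)
    report.write(out_dir / "qc_report.json")
    if write_sweep:
        sweep, recommended = percentile_sweep(censuses, umi_totals, lower=lower)
        sweep.to_csv(out_dir / "percentile_sweep.csv", index=False)
        logger.info("%s: recommended percentile %.0f", sample_id, recommended)
    if write_plot:
        from .plotting import plot_umi_histogram

        plot_umi_histogram(
            list(umi_totals.values()), thresholds, out_dir / "umi_histogram.png"
        )
    return report


def _read_gex(gex_dir: Path) -> vdj_io.CountMatrix:
    def find(stem: str) -> Path:
        for name in (f"{stem}", f"{stem}.gz"):
            p = gex_dir / name
            if p.exists():
                return p
        raise FileNotFoundError(f"{stem}[.gz] not found in {gex_dir}")

    return vdj_io.read_count_matrix(
        find("matrix.mtx"), find("barcodes.tsv"), find("features.tsv")
    )


def run_multi_sample(
    samples: Sequence[Mapping[str, str]],
    out_dir: str | Path,
    aggregate: bool = True,
    **kwargs,
) -> list[QCReport]:
    """Per-sample QC with optional cross-sample upper-threshold aggregation.

    ``samples`` is a sequence of mappings with keys ``sample_id``, ``gex_dir``
    and ``vdj_csv`` (e.g. rows of a manifest CSV). With ``aggregate`` the mean
    of the per-sample upper thresholds replaces each sample's own threshold
    in a second pass.
    """
    out_dir = Path(out_dir)
    reports = [
        run_pipeline(
            s["gex_dir"], s["vdj_csv"], out_dir / s["sample_id"],
            sample_id=s["sample_id"], **kwargs,
        )
        for s in samples
    ]
    if aggregate and len(reports) > 1:
        mean_upper = aggregate_thresholds([r.thresholds for r in reports])
        logger.info("aggregate upper threshold (mean of samples): %.1f", mean_upper)
        reports = [
            run_pipeline(
                s["gex_dir"], s["vdj_csv"], out_dir / s["sample_id"],
                sample_id=s["sample_id"], upper_override=mean_upper, **kwargs,
            )
            for s in samples
        ]
        for r in reports:
            r.aggregate_upper = mean_upper
            r.write(out_dir / r.sample_id / "qc_report.json")
    return reports
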