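"""Lower and TCR-anchored upper UMI thresholds for droplet cell calling.

The lower threshold removes dead cells and cell-free ambient RNA: it is the
local minimum of the (log-scale, smoothed) UMI histogram to the left of the
mode. The upper threshold removes multiplets and is anchored to the TCR data:
it is the 85th nearest-rank percentile of the UMI totals of *single-chain*
barcodes — cells with exactly one productive TCRα and/or one productive TCRβ
chain, which are presumed live single cells. A percentile sweep quantifies,
for any candidate percentile, the fraction of structural multiplets removed
against the fraction of single-chain cells retained; with other datasets the
appropriate percentile may differ, so it is a parameter. For a pooled
multi-sample analysis the mean of the per-sample upper thresholds is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .census import ChainCensus

__all__ = [
    "ThresholdParams",
    "ThresholdSet",
    "nearest_rank_percentile",
    "lower_umi_threshold",
    "upper_umi_threshold",
    "aggregate_thresholds",
    "percentile_sweep",
]


@dataclass(frozen=True)
class ThresholdParams:
    """Tunables for UMI thresholding.

    percentile
        Percentile of the single-chain UMI distribution used as the upper
        threshold (nearest-rank definition). Default 85.
    histogram_bins
        Number of log10(UMI+1) histogram bins for the lower threshold.
    smoothing_window
        Width (odd) of the centered moving average applied to the histogram.
    floor
        Lower threshold returned when the histogram has no local minimum left
        of its mode (monotone left flank).
    min_dip_ratio
        A local minimum only counts as the inter-population valley if its
        smoothed density is at most this fraction of the mode density;
        shallow Poisson-noise dips on the flank of the main peak are walked
        past. Set to 1 to accept the first local minimum unconditionally.
    """

    percentile: float = 85.0
    histogram_bins: int = 100
    smoothing_window: int = 5
    floor: float = 0.0
    min_dip_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")
        if self.histogram_bins < 1:
            raise ValueError("histogram_bins must be positive")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")
        if not 0 < self.min_dip_ratio <= 1:
            raise ValueError("min_dip_ratio must be in (0, 1]")


@dataclass(frozen=True)
class ThresholdSet:
    """Per-sample UMI window plus the census sizes that informed it."""

    sample_id: str
    lower: float
    upper: float
    n_single_chain: int
    n_multiplet_class: int

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValueError(
                f"lower threshold ({self.lower}) must be below upper ({self.upper})"
            )


def nearest_rank_percentile(values: Sequence[float] | np.ndarray, p: float) -> float:
    """The ceil(p/100 * n)-th order statistic of ``values``.

    Deterministic and interpolation-free; p must lie in (0, 100].
    """
    if not 0 < p <= 100:
        raise ValueError("percentile must be in (0, 100]")
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n == 0:
        raise ValueError("cannot take a percentile of an empty sample")
    # tiny epsilon guards against p*n/100 landing a hair above an integer
    rank = int(math.ceil(p * n / 100 - 1e-9))
    return float(arr[max(rank, 1) - 1])


def _smooth(hist: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edge windows are truncated, not padded."""
    kernel = np.ones(window)
    num = np.convolve(hist.astype(float), kernel, mode="same")
    den = np.convolve(np.ones_like(hist, dtype=float), kernel, mode="same")
    return num / den


def lower_umi_threshold(
    umi_totals: Sequence[float] | np.ndarray | Mapping[str, float],
    params: ThresholdParams = ThresholdParams(),
) -> float:
    """Local minimum of the smoothed log10-UMI histogram left of its mode.

    The histogram is built on log10(UMI+1) with ``params.histogram_bins``,
    smoothed by a centered moving average of width ``params.smoothing_window``;
    the mode is the global density maximum (ties broken toward smaller UMI)
    and the scan walks leftward from it to the first local minimum deep
    enough to count as the inter-population valley (density at most
    ``params.min_dip_ratio`` of the mode density); its upper bin edge is
    back-transformed to UMI units. A monotone left flank (no qualifying
    local minimum) returns ``params.floor``.
    """
    if isinstance(umi_totals, Mapping):
        umi_totals = list(umi_totals.values())
    values = np.asarray(umi_totals, dtype=float)
    if values.size == 0:
        raise ValueError("no barcodes supplied")
    log_umi = np.log10(values + 1.0)
    hist, edges = np.histogram(log_umi, bins=params.histogram_bins)
    smoothed = _smooth(hist, params.smoothing_window)
    mode = int(np.argmax(smoothed))  # argmax takes the first maximum: smaller UMI
    i = _first_local_min_left_of(smoothed, mode, params.min_dip_ratio)
    if i is None:
        return float(params.floor)
    return float(10 ** edges[i + 1] - 1.0)


def _first_local_min_left_of(
    density: np.ndarray, mode: int, min_dip_ratio: float = 0.5
) -> int | None:
    """Index of the qualifying local minimum nearest to ``mode`` on its left.

    A bin is a local minimum when it is <= both neighbours; it qualifies when
    its density is at most ``min_dip_ratio`` of the mode density. Plateaus of
    equal density resolve to their leftmost bin (smaller UMI). Returns None
    when no qualifying minimum exists.
    """
    ceiling = min_dip_ratio * density[mode]
    for i in range(mode - 1, 0, -1):
        if (
            density[i] <= density[i + 1]
            and density[i] <= density[i - 1]
            and density[i] <= ceiling
        ):
            while i > 1 and density[i - 1] == density[i]:
                i -= 1
            return i
    return None


def upper_umi_threshold(
    censuses: Mapping[str, ChainCensus],
    umi_totals: Mapping[str, float],
    params: ThresholdParams = ThresholdParams(),
    sample_id: str = "sample",
    lower: float = 0.0,
) -> ThresholdSet:
    """Upper UMI threshold: percentile of single-chain barcodes' UMI totals.

    Only barcodes present in ``umi_totals`` with UMI above ``lower`` are
    considered, so the threshold is anchored to droplets that already passed
    the dead-cell/ambient filter.

    Raises
    ------
    ValueError
        If no single-chain barcode remains; in that case a chain-independent
        fallback (e.g. a fixed percentile of all passing barcodes) must be
        chosen by the caller.
    """
    single = [
        umi_totals[b]
        for b, c in censuses.items()
        if c.is_single_chain and b in umi_totals and umi_totals[b] > lower
    ]
    n_multiplet = sum(
        1
        for b, c in censuses.items()
        if c.is_structural_multiplet and b in umi_totals and umi_totals[b] > lower
    )
    if not single:
        raise ValueError(
            "no single-chain barcodes available to anchor the upper UMI "
            "threshold; use a chain-independent fallback such as a fixed "
            "percentile of all passing barcodes"
        )
    upper = nearest_rank_percentile(single, params.percentile)
    return ThresholdSet(
        sample_id=sample_id,
        lower=float(lower),
        upper=upper,
        n_single_chain=len(single),
        n_multiplet_class=n_multiplet,
    )


def aggregate_thresholds(thresholds: Iterable[ThresholdSet]) -> float:
    """Mean of per-sample upper thresholds, for pooled multi-sample analysis."""
    uppers = [t.upper for t in thresholds]
    if not uppers:
        raise ValueError("no per-sample thresholds to aggregate")
    return float(np.mean(uppers))


def percentile_sweep(
    censuses: Mapping[str, ChainCensus],
    umi_totals: Mapping[str, float],
    grid: Sequence[float] | None = None,
    lower: float = 0.0,
) -> tuple[pd.DataFrame, float]:
    """Trade-off table over candidate upper-threshold percentiles.

    For each candidate percentile the implied threshold is computed on the
    single-chain barcodes, and two fractions are reported: structural
    multiplets strictly above the threshold (removed) and single-chain
    barcodes at or below it (retained). Returns the table and the candidate
    maximizing Youden's J = removed + retained - 1.
    """
    if grid is None:
        grid = np.arange(50.0, 100.1, 5.0)
    single = np.asarray(
        [
            umi_totals[b]
            for b, c in censuses.items()
            if c.is_single_chain and b in umi_totals and umi_totals[b] > lower
        ]
    )
    multi = np.asarray(
        [
            umi_totals[b]
            for b, c in censuses.items()
            if c.is_structural_multiplet and b in umi_totals and umi_totals[b] > lower
        ]
    )
    if single.size == 0:
        raise ValueError("no single-chain barcodes for percentile sweep")
    rows = []
    for p in grid:
        thr = nearest_rank_percentile(single, float(p))
        removed = float(np.mean(multi > thr)) if multi.size else float("nan")
        retained = float(np.mean(single <= thr))
        rows.append(
            {
                "percentile": float(p),
                "threshold": thr,
                "multiplet_removed_fraction": removed,
                "single_retained_fraction": retained,
            }
        )
    table = pd.DataFrame(rows)
    score = table["multiplet_removed_fraction"].fillna(0.0) + table["single_retained_fraction"] - 1.0
    recommended = float(table.loc[score.idxmax(), "percentile"])
    return table, recommended
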