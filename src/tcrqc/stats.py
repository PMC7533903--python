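"""Group-wise validation statistics for the chain-count classes.

Cells are grouped by their productive chain count at each locus (0, 1, 2,
3-plus) and compared against the single-chain reference group: cells with
zero chains are expected to show lower UMI totals and higher mitochondrial
fractions (dead-cell enrichment), while the 3-plus class — necessarily
multiplets — shows higher UMI totals. A two-sided Wilcoxon rank-sum test is
used for each comparison; no multiple-testing correction is applied by
default (a Bonferroni option is provided).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .census import GROUPS, ChainCensus
from .filters import DropletProfile

__all__ = ["group_qc_stats", "rank_sum_test"]

REFERENCE_GROUP = "1"


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value for x vs y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        return float("nan")
    return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def group_qc_stats(
    profiles: Sequence[DropletProfile],
    censuses: Mapping[str, ChainCensus],
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-locus, per-group medians and rank-sum tests against group "1".

    Returns one row per (locus, group) with the group size, median UMI total,
    median mitochondrial fraction, and two-sided rank-sum p-values of the UMI
    and mito distributions against the single-chain reference group. Groups
    with fewer than two members are reported with NaN p-values and flagged in
    the ``tested`` column.
    """
    rows = []
    joined = [(p, censuses[p.barcode]) for p in profiles if p.barcode in censuses]
    for locus, group_of in (("TRA", lambda c: c.group_tra), ("TRB", lambda c: c.group_trb)):
        by_group: dict[str, tuple[list[int], list[float]]] = {g: ([], []) for g in GROUPS}
        for p, c in joined:
            umis, mitos = by_group[group_of(c)]
            umis.append(p.total_umi)
            mitos.append(p.mito_fraction)
        ref_umi, ref_mito = by_group[REFERENCE_GROUP]
        for g in GROUPS:
            umis, mitos = by_group[g]
            if g == REFERENCE_GROUP:
                p_umi = p_mito = float("nan")
                tested = False
            else:
                p_umi = rank_sum_test(umis, ref_umi)
                p_mito = rank_sum_test(mitos, ref_mito)
                tested = not (np.isnan(p_umi) and np.isnan(p_mito))
            rows.append(
                {
                    "locus": locus,
                    "group": g,
                    "n": len(umis),
                    "median_umi": float(np.median(umis)) if umis else float("nan"),
                    "median_mito_fraction": float(np.median(mitos)) if mitos else float("nan"),
                    "p_umi_vs_single": p_umi,
                    "p_mito_vs_single": p_mito,
                    "tested": tested,
                }
            )
    table = pd.DataFrame(rows)
    if bonferroni:
        n_tests = int(table["tested"].sum()) * 2
        for col in ("p_umi_vs_single", "p_mito_vs_single"):
            table[col] = np.minimum(table[col] * n_tests, 1.0)
    return table
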