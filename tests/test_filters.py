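"""Droplet profiling, the QC filter cascade and the TCR/BCR gene mask."""

import numpy as np
import pytest

from tcrqc import (
    FilterParams,
    ThresholdSet,
    apply_qc,
    mask_vdj_genes,
    profile_droplets,
)

from conftest import build_matrix

WIDE_OPEN = ThresholdSet(
    sample_id="toy", lower=0.0, upper=1e12, n_single_chain=1, n_multiplet_class=0
)


class TestProfileDroplets:
    def test_toy_profile(self, toy_matrix):
        profiles = profile_droplets(toy_matrix)
        a, b = profiles
        assert (a.total_umi, a.n_genes, a.mito_fraction) == (5, 1, 0.0)
        assert (b.total_umi, b.n_genes) == (2, 1)
        assert b.mito_fraction == 1.0  # only MT-CO1 expressed

    def test_mixed_mito_column(self):
        m = build_matrix(["GENEA", "MT-CO1"], ["A-1"], [[5], [5]])
        (p,) = profile_droplets(m)
        assert p.total_umi == 10 and p.n_genes == 2 and p.mito_fraction == 0.5

    def test_all_zero_column_has_zero_mito_fraction(self):
        m = build_matrix(["GENEA", "MT-CO1"], ["A-1", "B-1"], [[5, 0], [0, 0]])
        assert profile_droplets(m)[1].mito_fraction == 0.0
        assert profile_droplets(m)[1].total_umi == 0

    def test_totals_match_brute_force_column_sums(self):
        rng = np.random.default_rng(5)
        dense = rng.integers(0, 8, size=(15, 9))
        m = build_matrix(
            [f"G{i}" for i in range(15)], [f"B{i}-1" for i in range(9)], dense
        )
        profiles = profile_droplets(m)
        for j, p in enumerate(profiles):
            assert p.total_umi == sum(int(dense[i, j]) for i in range(15))
            assert p.n_genes == sum(1 for i in range(15) if dense[i, j] > 0)

    def test_case_insensitive_mito_prefix(self):
        m = build_matrix(["mt-co1", "GENEA"], ["A-1"], [[4], [4]])
        params = FilterParams(mito_case_insensitive=True)
        assert profile_droplets(m, params=params)[0].mito_fraction == 0.5


class TestMaskVdjGenes:
    @pytest.mark.parametrize(
        "symbol",
        ["TRAV1-2", "TRBC1", "TRBV20-1", "TRAJ33", "TRGV9", "TRDC",
         "IGHV3-23", "IGKC", "IGLV2-14", "IGHM", "IGHG1", "IGHA2", "IGHE", "IGHD"],
    )
    def test_tcr_bcr_genes_masked(self, symbol):
        assert mask_vdj_genes([symbol])[0]

    @pytest.mark.parametrize(
        "symbol",
        ["TRAF1", "CD3E", "MT-CO1", "ACTB", "GAPDH", "B2M", "IGHMBP2",
         "TRIM22", "IGF1R", "CD8A", "FOXP3", "IL2RA"],
    )
    def test_other_genes_retained(self, symbol):
        assert not mask_vdj_genes([symbol])[0]


def toy_qc_matrix():
    """14 barcodes engineered so every cell rule removes a known set.

    Genes 0..299 form the shared body; gene 300 ("RARE") is expressed in only
    9 of the retained cells; MT-CO1 is the mitochondrial gene.
    """
    n_genes = 3400
    symbols = ["MT-CO1", "RARE"] + [f"G{i:04d}" for i in range(n_genes - 2)]
    barcodes = [f"B{i:02d}-1" for i in range(14)]
    dense = np.zeros((n_genes, 14), dtype=np.int64)
    body = slice(2, 252)  # 250 body genes
    for j in range(14):
        dense[body, j] = 1
    # B00 fails min-genes: only 150 genes
    dense[:, 0] = 0
    dense[2:152, 0] = 1
    # B01 fails mito: 250 body + 34 mito of 284 = 12%
    dense[0, 1] = 34
    # B02 fails the gene ceiling: 3200 expressed genes
    dense[:, 2] = 0
    dense[2 : 2 + 3200, 2] = 1
    # B03 sits exactly at 10% mito: removed (rule is >=)
    dense[body, 3] = 1
    dense[0, 3] = 250 * 1 // 9  # 27 -> 27/277 = 9.7%: adjust to exact 10%
    dense[0, 3] = 0
    dense[body, 3] = 9  # body total 2250
    dense[0, 3] = 250  # 250 / 2500 = 10% exactly
    # B04 expresses exactly 200 genes: kept (rule is >=)
    dense[:, 4] = 0
    dense[2:202, 4] = 1
    # B05..B13 are ordinary cells; gene RARE in 9 of them
    for j in range(5, 14):
        dense[1, j] = 1
    return build_matrix(symbols, barcodes, dense)


class TestApplyQC:
    def test_each_rule_removes_expected_barcodes(self):
        m = toy_qc_matrix()
        filtered, report = apply_qc(m, profile_droplets(m), WIDE_OPEN)
        assert report.removed["min_genes"] == 1  # B00
        assert report.removed["mito_fraction"] == 2  # B01 (12%), B03 (exactly 10%)
        assert report.removed["max_genes"] == 1  # B02
        assert report.removed["lower_umi"] == 0 and report.removed["upper_umi"] == 0
        removed = set(m.barcodes) - set(report.retained_barcodes)
        assert removed == {"B00-1", "B01-1", "B02-1", "B03-1"}
        assert "B04-1" in report.retained_barcodes  # exactly 200 genes kept

    def test_gene_floor_uses_retained_cells(self):
        m = toy_qc_matrix()
        filtered, report = apply_qc(m, profile_droplets(m), WIDE_OPEN)
        # 10 retained cells; RARE is expressed in 9 of them -> dropped
        assert report.n_retained_barcodes == 10
        assert "RARE" not in filtered.feature_symbols
        # the first 200 body genes are in all 10 retained cells -> kept;
        # the other 50 body genes miss B04 (9 cells) and fall to the floor
        assert "G0000" in filtered.feature_symbols
        assert filtered.shape[0] == 200

    def test_removal_counts_are_order_consistent(self):
        m = toy_qc_matrix()
        _, report = apply_qc(m, profile_droplets(m), WIDE_OPEN)
        cell_rules = ("lower_umi", "upper_umi", "mito_fraction", "max_genes", "min_genes")
        assert sum(report.removed[r] for r in cell_rules) + report.n_retained_barcodes == 14
        assert report.check_totals()

    def test_umi_window_boundaries(self):
        m = build_matrix(
            [f"G{i}" for i in range(5)],
            ["LOW-1", "EDGE-1", "MID-1", "TOP-1", "HIGH-1"],
            np.array(
                [[1, 2, 3, 4, 5],
                 [1, 2, 3, 4, 5],
                 [0, 2, 3, 4, 5],
                 [0, 0, 3, 4, 5],
                 [0, 0, 0, 4, 5]]
            ),
        )
        # totals: 2, 6, 12, 20, 25; keep if lower < total <= upper
        thresholds = ThresholdSet(
            sample_id="t", lower=2.0, upper=20.0, n_single_chain=1, n_multiplet_class=0
        )
        params = FilterParams(min_genes_per_cell=0, min_cells_per_gene=0)
        _, report = apply_qc(m, profile_droplets(m), thresholds, params)
        assert report.retained_barcodes == ["EDGE-1", "MID-1", "TOP-1"]
        assert report.removed["lower_umi"] == 1 and report.removed["upper_umi"] == 1

    def test_second_pass_removes_no_cells(self):
        m = toy_qc_matrix()
        filtered, _ = apply_qc(m, profile_droplets(m), WIDE_OPEN)
        again, report2 = apply_qc(filtered, profile_droplets(filtered), WIDE_OPEN)
        cell_rules = ("lower_umi", "upper_umi", "mito_fraction", "max_genes", "min_genes")
        assert all(report2.removed[r] == 0 for r in cell_rules)
        assert again.barcodes == filtered.barcodes

    def test_all_cells_removed_raises_with_diagnostics(self):
        m = build_matrix(["GENEA"], ["A-1"], [[5]])
        with pytest.raises(ValueError, match="min_genes"):
            apply_qc(m, profile_droplets(m), WIDE_OPEN)

    def test_vdj_genes_masked_from_output(self):
        symbols = ["TRAC", "CD3E"] + [f"G{i}" for i in range(3)]
        dense = np.ones((5, 12), dtype=np.int64)
        m = build_matrix(symbols, [f"B{i}-1" for i in range(12)], dense)
        params = FilterParams(min_genes_per_cell=0)
        filtered, report = apply_qc(m, profile_droplets(m), WIDE_OPEN, params)
        assert "TRAC" not in filtered.feature_symbols
        assert "CD3E" in filtered.feature_symbols
        assert report.removed["vdj_mask"] == 1
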