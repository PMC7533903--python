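"""UMI thresholding: nearest-rank percentile, lower-threshold histogram scan,
upper-threshold anchoring and the percentile sweep."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from tcrqc import (
    ChainCensus,
    SimConfig,
    ThresholdParams,
    ThresholdSet,
    aggregate_thresholds,
    census,
    lower_umi_threshold,
    nearest_rank_percentile,
    percentile_sweep,
    simulate_droplets,
    upper_umi_threshold,
)
from tcrqc.thresholds import _first_local_min_left_of, _smooth


class TestNearestRank:
    def test_85th_of_twenty_values(self):
        values = np.arange(100, 2001, 100)  # 100, 200, ..., 2000
        # ceil(0.85 * 20) = 17 -> 17th order statistic
        assert nearest_rank_percentile(values, 85) == 1700

    def test_percentile_100_is_maximum(self):
        assert nearest_rank_percentile([3, 1, 2], 100) == 3

    def test_singleton(self):
        assert nearest_rank_percentile([42], 85) == 42

    @given(
        values=st.lists(st.integers(0, 10**6), min_size=1, max_size=200),
        p=st.sampled_from([1.0, 2.5, 5.0, 10.0, 25.0, 33.0, 50.0, 66.0, 75.0, 85.0, 90.0, 95.0, 99.0, 100.0]),
    )
    def test_matches_inverted_cdf_oracle(self, values, p):
        ours = nearest_rank_percentile(values, p)
        oracle = float(np.percentile(values, p, method="inverted_cdf"))
        assert ours == oracle

    def test_invalid_percentile_rejected(self):
        with pytest.raises(ValueError):
            nearest_rank_percentile([1.0], 0)
        with pytest.raises(ValueError):
            nearest_rank_percentile([1.0], 101)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            nearest_rank_percentile([], 50)


class TestLowerThreshold:
    def test_toy_density_scan(self):
        # mode at bin 3 (density 9); local min at bin 2 (density 2)
        assert _first_local_min_left_of(np.array([5.0, 2.0, 9.0, 4.0]), 2) == 1

    def test_plateau_resolves_to_smaller_umi(self):
        assert _first_local_min_left_of(np.array([5.0, 2.0, 2.0, 9.0]), 3) == 1

    def test_monotone_flank_has_no_minimum(self):
        assert _first_local_min_left_of(np.array([1.0, 2.0, 5.0, 9.0]), 3) is None

    def test_bimodal_sample_threshold_between_modes(self):
        rng = np.random.default_rng(0)
        low = rng.lognormal(np.log(100), 0.3, 500)
        high = rng.lognormal(np.log(5000), 0.3, 500)
        thr = lower_umi_threshold(np.concatenate([low, high]))
        assert 100 < thr < 5000

    def test_monotone_left_flank_returns_floor(self):
        # histogram counts increase strictly toward the mode: 1,2,3,... copies
        values = np.concatenate(
            [np.full(k + 1, 10.0 ** (1 + k / 2)) for k in range(8)]
        )
        params = ThresholdParams(histogram_bins=8, smoothing_window=1, floor=0.0)
        assert lower_umi_threshold(values, params) == 0.0

    def test_invariant_under_duplication(self):
        rng = np.random.default_rng(1)
        values = np.concatenate(
            [rng.lognormal(np.log(50), 0.4, 300), rng.lognormal(np.log(4000), 0.4, 300)]
        )
        assert lower_umi_threshold(values) == lower_umi_threshold(
            np.concatenate([values, values])
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            lower_umi_threshold([])

    def test_smoothing_preserves_mass(self):
        hist = np.array([1.0, 4.0, 0.0, 2.0, 7.0, 3.0])
        smoothed = _smooth(hist, 3)
        assert smoothed.shape == hist.shape
        assert smoothed.min() >= 0


def make_censuses(singles, multiplets):
    censuses = {}
    for b in singles:
        censuses[b] = ChainCensus(barcode=b, n_tra=1, n_trb=1)
    for b in multiplets:
        censuses[b] = ChainCensus(barcode=b, n_tra=3, n_trb=2)
    return censuses


class TestUpperThreshold:
    def test_default_percentile_is_85(self):
        assert ThresholdParams().percentile == 85

    def test_anchored_to_single_chain_cells_only(self):
        singles = [f"s{i}" for i in range(20)]
        multis = ["m1", "m2"]
        umi = {b: 100 * (i + 1) for i, b in enumerate(singles)}
        umi.update({"m1": 50_000, "m2": 60_000})
        ts = upper_umi_threshold(make_censuses(singles, multis), umi)
        assert ts.upper == 1700  # 85th nearest rank of 100..2000
        assert ts.n_single_chain == 20 and ts.n_multiplet_class == 2

    def test_lower_threshold_excludes_anchor_cells(self):
        singles = [f"s{i}" for i in range(20)]
        umi = {b: 100 * (i + 1) for i, b in enumerate(singles)}
        ts = upper_umi_threshold(make_censuses(singles, []), umi, lower=1000)
        # only the 10 cells above 1000 anchor the percentile
        assert ts.n_single_chain == 10
        assert ts.upper == nearest_rank_percentile(
            [v for v in umi.values() if v > 1000], 85
        )

    def test_no_single_chain_cells_instructs_fallback(self):
        with pytest.raises(ValueError, match="fallback"):
            upper_umi_threshold(make_censuses([], ["m1"]), {"m1": 100.0})

    def test_threshold_set_requires_lower_below_upper(self):
        with pytest.raises(ValueError):
            ThresholdSet(
                sample_id="s", lower=10.0, upper=5.0, n_single_chain=1, n_multiplet_class=0
            )


class TestAggregate:
    @pytest.mark.parametrize(
        "uppers,expected",
        [([1000.0, 2000.0], 1500.0), ([1400.0], 1400.0), ([1200.0, 1800.0, 1500.0], 1500.0)],
    )
    def test_mean_of_sample_uppers(self, uppers, expected):
        sets = [
            ThresholdSet(sample_id=f"s{i}", lower=0.0, upper=u, n_single_chain=1, n_multiplet_class=0)
            for i, u in enumerate(uppers)
        ]
        assert aggregate_thresholds(sets) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_thresholds([])


class TestPercentileSweep:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.singles = [f"s{i}" for i in range(400)]
        self.multis = [f"m{i}" for i in range(60)]
        umi = {b: float(v) for b, v in zip(self.singles, rng.lognormal(8.5, 0.5, 400))}
        umi.update(
            {b: float(v) for b, v in zip(self.multis, rng.lognormal(9.2, 0.5, 60))}
        )
        self.umi = umi
        self.censuses = make_censuses(self.singles, self.multis)

    def test_retained_fraction_within_nearest_rank_bounds(self):
        table, _ = percentile_sweep(self.censuses, self.umi)
        n = len(self.singles)
        for row in table.itertuples():
            p = row.percentile / 100
            assert p - 1 / n <= row.single_retained_fraction <= p + 1e-12

    def test_threshold_monotone_in_percentile(self):
        table, _ = percentile_sweep(self.censuses, self.umi)
        assert (np.diff(table["threshold"]) >= 0).all()
        assert (np.diff(table["multiplet_removed_fraction"]) <= 0).all()

    def test_single_candidate_grid_is_recommended(self):
        _, recommended = percentile_sweep(self.censuses, self.umi, grid=[85.0])
        assert recommended == 85.0


def test_multiplets_have_stochastically_larger_umi(default_sim):
    """Structural-multiplet barcodes sit above single-chain barcodes in the
    UMI distribution (doublets sum two transcriptomes)."""
    _, matrix, contigs, _ = default_sim
    censuses = census(contigs, barcodes=matrix.barcodes)
    umi = dict(zip(matrix.barcodes, matrix.umi_totals()))
    single = [umi[b] for b, c in censuses.items() if c.is_single_chain]
    multi = [umi[b] for b, c in censuses.items() if c.is_structural_multiplet]
    assert len(multi) >= 30
    p = sps.mannwhitneyu(multi, single, alternative="greater").pvalue
    assert p < 0.01
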