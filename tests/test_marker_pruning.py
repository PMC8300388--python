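import numpy as np
import pytest

from panelgp.marker_pruning import (PanelSelection, TargetUnreachableError,
                                    prune_gend, prune_phyd, prune_rand,
                                    prune_to_count, scenario_gap_sample,
                                    verify_phyd)

from conftest import make_dataset, make_map


class TestPhyD:
    def test_zero_threshold_keeps_all(self, small_cohort):
        dataset, _ = small_cohort
        sel = prune_phyd(dataset.map, 0)
        assert len(sel) == dataset.n_markers

    def test_even_spacing_keeps_every_tenth(self):
        m = make_map([1000 * (i + 1) for i in range(1000)])
        sel = prune_phyd(m, 10_000)
        assert len(sel) == 100
        np.testing.assert_array_equal(sel.indices, np.arange(0, 1000, 10))

    def test_greedy_hand_trace(self):
        m = make_map([100, 150, 300])
        sel = prune_phyd(m, 100)
        np.testing.assert_array_equal(sel.indices, [0, 2])

    def test_first_marker_of_each_chromosome_kept(self):
        m = make_map([100, 200, 100, 200], chromosomes=[1, 1, 2, 2])
        sel = prune_phyd(m, 1_000_000)
        np.testing.assert_array_equal(sel.indices, [0, 2])

    def test_output_verifies_min_gap(self, small_cohort):
        dataset, _ = small_cohort
        for gap in (5_000, 50_000, 250_000):
            sel = prune_phyd(dataset.map, gap)
            assert verify_phyd(sel, dataset.map, gap)


class TestGenD:
    def test_duplicated_pair_loses_one(self):
        col = np.array([0, 1, 2, 0, 1, 2, 1, 0])
        dataset = make_dataset(np.column_stack([col, col]),
                               positions=[1000, 2000])
        sel = prune_gend(dataset, r2_max=0.5)
        assert len(sel) == 1

    def test_independent_markers_all_kept(self):
        rng = np.random.default_rng(0)
        dosages = rng.integers(0, 3, size=(200, 10))
        dataset = make_dataset(dosages, positions=[1000 * (i + 1) for i in range(10)])
        sel = prune_gend(dataset, r2_max=0.5)
        assert len(sel) == 10

    def test_three_way_perfect_ld_single_survivor(self):
        col = np.array([0, 1, 2, 2, 1, 0, 1, 1])
        dataset = make_dataset(np.column_stack([col, col, col]),
                               positions=[1000, 2000, 3000])
        sel = prune_gend(dataset, r2_max=0.9)
        assert len(sel) == 1

    def test_window_smaller_than_step_rejected(self, small_cohort):
        dataset, _ = small_cohort
        with pytest.raises(ValueError, match="window"):
            prune_gend(dataset, 0.5, window_kb=5, step_kb=50)

    def test_no_violating_pair_survives(self, small_cohort):
        from panelgp.marker_pruning import _pairwise_r2

        dataset, _ = small_cohort
        sel = prune_gend(dataset, r2_max=0.3)
        # brute-force rescan of surviving pairs guaranteed to share a window
        # position (closer than window minus step: 50 - 5 kb)
        pos = dataset.map.positions
        chrom = dataset.map.chromosomes
        for a_i, i in enumerate(sel.indices):
            for j in sel.indices[a_i + 1:]:
                if chrom[i] != chrom[j] or pos[j] - pos[i] > 45_000:
                    continue
                r2 = _pairwise_r2(dataset.dosages[:, i], dataset.dosages[:, j])
                assert np.isnan(r2) or r2 <= 0.3


class TestRanD:
    def test_full_sample_returns_all(self, small_cohort):
        dataset, _ = small_cohort
        sel = prune_rand(dataset.map, dataset.n_markers, seed=1)
        assert len(sel) == dataset.n_markers

    def test_deterministic_under_seed(self, small_cohort):
        dataset, _ = small_cohort
        a = prune_rand(dataset.map, 50, seed=3)
        b = prune_rand(dataset.map, 50, seed=3)
        np.testing.assert_array_equal(a.indices, b.indices)

    def test_uniformity_over_repetitions(self):
        # sampling 1 of 4 markers 2000 times: each within binomial 99% band
        m = make_map([100, 200, 300, 400])
        counts = np.zeros(4, dtype=int)
        for seed in range(2000):
            counts[prune_rand(m, 1, seed=seed).indices[0]] += 1
        assert np.all(counts >= 425) and np.all(counts <= 575)

    def test_out_of_range_target(self, small_cohort):
        dataset, _ = small_cohort
        with pytest.raises(ValueError):
            prune_rand(dataset.map, dataset.n_markers + 1, seed=0)


class TestPruneToCount:
    def test_phyd_even_spacing_exact_count(self):
        from panelgp.genotype_io import GenotypeDataset

        m = make_map([1000 * (i + 1) for i in range(1000)])
        rng = np.random.default_rng(0)
        dosages = rng.integers(0, 3, size=(20, 1000))
        dataset = GenotypeDataset([f"s{i}" for i in range(20)], m,
                                  dosages.astype(np.int8))
        sel = prune_to_count(dataset, "PhyD", 100, seed=0)
        assert len(sel) == 100
        # even spacing: the bisected threshold sits near 10x the spacing
        assert 9_000 <= sel.threshold <= 10_000

    def test_target_equal_to_total(self, small_cohort):
        dataset, _ = small_cohort
        sel = prune_to_count(dataset, "PhyD", dataset.n_markers, seed=0)
        np.testing.assert_array_equal(sel.indices, np.arange(dataset.n_markers))

    def test_gend_ceiling_unreachable(self):
        col = np.array([0, 1, 2, 2, 1, 0, 0, 1])
        dataset = make_dataset(np.column_stack([col] * 4),
                               positions=[1000, 2000, 3000, 4000])
        with pytest.raises(TargetUnreachableError) as err:
            prune_to_count(dataset, "GenD", 3, seed=0)
        assert err.value.achievable_max == 1

    def test_gend_exact_count(self, small_cohort):
        dataset, _ = small_cohort
        sel = prune_to_count(dataset, "GenD", 150, seed=0)
        assert len(sel) == 150


class TestScenarioSampler:
    def test_constant_walk_exact_count(self):
        sel = scenario_gap_sample(335_753, mean_gap=67, gap_variance=0.0)
        assert len(sel) == (335_753 - 1) // 67 + 1 == 5012
        assert np.all(np.diff(sel.indices) == 67)

    def test_gap_one_selects_everything(self):
        sel = scenario_gap_sample(500, mean_gap=1, gap_variance=0.0)
        assert len(sel) == 500

    def test_mean_gap_too_large_rejected(self):
        with pytest.raises(ValueError):
            scenario_gap_sample(50, mean_gap=50)

    def test_realized_gap_moments(self):
        # 50 seeds at variance 80: realized mean within [65, 69]; realized
        # variance increases across requested variances 20/40/80
        mean_gaps, var_by_request = [], {}
        for v in (20.0, 40.0, 80.0):
            all_gaps = []
            for seed in range(50):
                sel = scenario_gap_sample(100_000, 67, v, seed=seed)
                all_gaps.append(np.diff(sel.indices))
            gaps = np.concatenate(all_gaps)
            var_by_request[v] = gaps.var()
            if v == 80.0:
                assert 65 <= gaps.mean() <= 69
        assert var_by_request[20.0] < var_by_request[40.0] < var_by_request[80.0]


class TestSelectionInvariants:
    @pytest.mark.parametrize("builder", [
        lambda ds: prune_phyd(ds.map, 20_000),
        lambda ds: prune_gend(ds, 0.5),
        lambda ds: prune_rand(ds.map, 37, seed=5),
    ])
    def test_sorted_unique_subset(self, small_cohort, builder):
        dataset, _ = small_cohort
        sel = builder(dataset)
        assert np.all(np.diff(sel.indices) > 0)
        assert sel.indices.min() >= 0
        assert sel.indices.max() < dataset.n_markers

    def test_selection_rejects_unsorted(self):
        with pytest.raises(ValueError):
            PanelSelection("RanD", np.array([3, 1, 2]))
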