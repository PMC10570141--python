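"""Synthetic-data generators: determinism, ground-truth consistency, errors."""

import numpy as np
import pandas as pd
import pytest

from ademtrack import (
    BulkSimSpec,
    ValidationError,
    cumulative_divisions,
    sholl_auc,
    simulate_bulk_series,
    simulate_cell_counts,
    simulate_qpcr_plate,
    simulate_sholl_profiles,
    simulate_timepoint_summaries,
    simulate_turnover_densities,
    telomere_length,
)


class TestBulkSeries:
    def test_same_seed_is_byte_identical(self):
        spec = BulkSimSpec(n_genes=100, seed=7, n_up_gradual=10, n_down_gradual=10)
        s1, t1 = simulate_bulk_series(spec)
        s2, t2 = simulate_bulk_series(spec)
        pd.testing.assert_frame_equal(s1.counts, s2.counts)
        pd.testing.assert_series_equal(t1.labels, t2.labels)

    def test_no_signal_spec_labels_all_null(self):
        spec = BulkSimSpec(n_genes=50, n_up_gradual=0, n_down_gradual=0,
                           per_step_log2_effect=0.0, seed=1)
        _, truth = simulate_bulk_series(spec)
        assert (truth.labels == "null").all()
        assert np.allclose(truth.true_means.to_numpy().std(axis=1), 0.0)

    def test_trend_gene_true_means_are_monotone(self):
        spec = BulkSimSpec(n_genes=60, n_up_gradual=15, n_down_gradual=15, seed=2)
        _, truth = simulate_bulk_series(spec)
        tm = truth.true_means
        for g in truth.genes_with_label("up_gradual"):
            assert (np.diff(tm.loc[g].to_numpy()) > 0).all()
        for g in truth.genes_with_label("down_gradual"):
            assert (np.diff(tm.loc[g].to_numpy()) < 0).all()

    def test_up_genes_rise_empirically(self):
        # net change over the series dwarfs sampling noise at 0.3 log2/step
        spec = BulkSimSpec(n_genes=500, n_up_gradual=50, n_down_gradual=0, seed=3)
        series, truth = simulate_bulk_series(spec)
        ages = series.timepoints()
        first = series.counts[series.samples_at(ages[0])].mean(axis=1)
        last = series.counts[series.samples_at(ages[-1])].mean(axis=1)
        up = truth.genes_with_label("up_gradual")
        assert (last[up] > first[up]).mean() >= 0.95

    def test_empirical_means_converge_to_truth(self):
        # 200 replicates per timepoint: count means match mu * mean(lib)
        spec = BulkSimSpec(n_genes=100, timepoints=(3.0, 12.0, 24.0),
                           reps_per_timepoint=200, n_up_gradual=20,
                           n_down_gradual=20, switch_timepoint=1, seed=4)
        series, truth = simulate_bulk_series(spec)
        rel_errs = []
        for age in series.timepoints():
            samples = series.samples_at(age)
            expected = truth.true_means[age] * truth.lib_sizes[samples].mean()
            observed = series.counts[samples].mean(axis=1)
            rel_errs.append(np.abs(observed - expected) / expected)
        rel = np.concatenate(rel_errs)
        assert (rel < 0.05).mean() >= 0.95

    def test_spec_validation_names_the_problem(self):
        with pytest.raises(ValidationError, match="trend-gene"):
            BulkSimSpec(n_genes=10, n_up_gradual=8, n_down_gradual=8)
        with pytest.raises(ValidationError, match="replicates"):
            BulkSimSpec(reps_per_timepoint=(1,) * 7)
        with pytest.raises(ValidationError, match="dispersion"):
            BulkSimSpec(dispersion=0.0)
        with pytest.raises(ValidationError, match="timepoints"):
            BulkSimSpec(timepoints=(3.0, 3.0, 9.0), reps_per_timepoint=3,
                        switch_timepoint=1)


class TestCellCounts:
    def test_unknown_signature_gene_listed(self):
        with pytest.raises(ValidationError, match="bogus"):
            simulate_cell_counts((10, 10), 20, ["bogus"], 1.0, seed=0)

    def test_seed_determinism(self):
        sig = [f"c{i:05d}" for i in range(5)]
        a, la = simulate_cell_counts((20, 20), 50, sig, 1.0, seed=11)
        b, lb = simulate_cell_counts((20, 20), 50, sig, 1.0, seed=11)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_series_equal(la, lb)

    def test_shift_scales_signature_means(self):
        sig = [f"c{i:05d}" for i in range(20)]
        counts, labels = simulate_cell_counts((800, 800), 200, sig, 1.0, seed=12)
        m_shift = counts.loc[labels == "shifted", sig].mean().mean()
        m_ctrl = counts.loc[labels == "control", sig].mean().mean()
        assert m_shift / m_ctrl == pytest.approx(2.0, rel=0.15)

    def test_zero_shift_groups_exchangeable(self):
        sig = [f"c{i:05d}" for i in range(20)]
        counts, labels = simulate_cell_counts((500, 500), 100, sig, 0.0, seed=13)
        m_shift = counts.loc[labels == "shifted", sig].mean().mean()
        m_ctrl = counts.loc[labels == "control", sig].mean().mean()
        assert m_shift / m_ctrl == pytest.approx(1.0, rel=0.1)


class TestShollSimulator:
    def test_flat_zero_profile(self):
        profiles = simulate_sholl_profiles(5, peak_height=0.0, noise_sd=0.0, seed=0)
        assert all(sholl_auc(p) == 0.0 for p in profiles)

    def test_seed_determinism(self):
        a = simulate_sholl_profiles(4, peak_height=8.0, noise_sd=1.0, seed=3)
        b = simulate_sholl_profiles(4, peak_height=8.0, noise_sd=1.0, seed=3)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.intersections, pb.intersections)

    def test_auc_linear_in_peak_height(self):
        full = simulate_sholl_profiles(400, peak_height=12.0, noise_sd=0.0, seed=5)
        half = simulate_sholl_profiles(400, peak_height=6.0, noise_sd=0.0, seed=6)
        mean_full = np.mean([sholl_auc(p) for p in full])
        mean_half = np.mean([sholl_auc(p) for p in half])
        assert mean_half / mean_full == pytest.approx(0.5, rel=0.05)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValidationError):
            simulate_sholl_profiles(2, radii=np.array([5.0, 10.0, 20.0]), seed=0)


class TestQpcrSimulator:
    def test_noiseless_unit_ratio_recovers_reference(self):
        assay = simulate_qpcr_plate(1.0, ref_length_kb=100.0, cq_noise_sd=0.0)
        assert telomere_length(assay) == pytest.approx(100.0)

    def test_noiseless_ratio_two_doubles(self):
        assay = simulate_qpcr_plate(2.0, ref_length_kb=100.0, cq_noise_sd=0.0)
        assert telomere_length(assay) == pytest.approx(200.0)

    def test_noisy_plate_unbiased(self):
        ests = [telomere_length(simulate_qpcr_plate(1.5, 100.0, 0.05, seed=s))
                for s in range(100)]
        assert np.mean(ests) == pytest.approx(150.0, rel=0.05)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValidationError):
            simulate_qpcr_plate(0.0, 100.0)


class TestTurnoverSimulator:
    def test_half_residual_single_round_is_one_division(self):
        record, truth = simulate_turnover_densities(1, 0.5, 200.0, seed=0)
        assert truth == pytest.approx(1.0)
        assert cumulative_divisions(record) == pytest.approx(1.0)

    def test_truth_matches_hand_computed_sum(self):
        record, truth = simulate_turnover_densities(3, 0.02, 220.0, seed=8,
                                                    noise_sd=0.1)
        by_hand = sum(np.log2(rec / res) for res, rec in record.rounds)
        assert truth == pytest.approx(by_hand)
        assert cumulative_divisions(record) == pytest.approx(by_hand)

    def test_fraction_bounds(self):
        with pytest.raises(ValidationError):
            simulate_turnover_densities(1, 1.0, 200.0)
        with pytest.raises(ValidationError):
            simulate_turnover_densities(1, 0.0, 200.0)


class TestTimepointSummaries:
    def test_deterministic_and_shaped(self):
        a = simulate_timepoint_summaries([0, 1, 1, 1, 1, 2, 2], seed=5)
        b = simulate_timepoint_summaries([0, 1, 1, 1, 1, 2, 2], seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert list(a.index) == [3.0, 6.0, 9.0, 12.0, 14.0, 16.0, 24.0]

    def test_zero_noise_returns_truth(self):
        out = simulate_timepoint_summaries([1.0, 2.0, 3.0], ages=[3, 6, 9],
                                           noise_sd=0.0, seed=0)
        np.testing.assert_allclose(out["summary"].to_numpy(), [1.0, 2.0, 3.0])
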