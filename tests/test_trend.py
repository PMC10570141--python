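"""ADEM calling: neighbor comparisons, monotone-run classification, age correlation."""

import numpy as np
import pandas as pd
import pytest

from ademtrack import (
    BulkSimSpec,
    ExpressionSeries,
    NeighborScan,
    ValidationError,
    classify_adem,
    neighbor_comparisons,
    simulate_bulk_series,
)
from ademtrack.containers import DEResult
from ademtrack.trend import age_correlation_values

TIMEPOINTS = [3.0, 6.0, 9.0, 12.0, 14.0, 16.0, 24.0]


def make_scan(means_rows: dict[str, list[float]],
              significant_steps: dict[str, list[int]] | None = None,
              multigroup_pass: set[str] | None = None) -> NeighborScan:
    """Hand-built scan: zero SEMs (strict monotonicity), chosen DEG steps."""
    genes = list(means_rows)
    t = len(next(iter(means_rows.values())))
    ages = TIMEPOINTS[:t]
    means = pd.DataFrame(means_rows, index=ages).T
    sems = means * 0.0
    significant_steps = significant_steps or {}
    comparisons = []
    for step in range(t - 1):
        rows = {}
        for g in genes:
            sig = step in significant_steps.get(g, [])
            lfc = np.log2((means_rows[g][step + 1] + 0.5) / (means_rows[g][step] + 0.5))
            rows[g] = {"log2fc": 2.0 * np.sign(lfc) if sig else lfc,
                       "p": 0.001 if sig else 0.9,
                       "p_adj": 0.01 if sig else 0.95,
                       "mean_a": means_rows[g][step], "mean_b": means_rows[g][step + 1]}
        comparisons.append(DEResult(pd.DataFrame(rows).T, f"step{step}"))
    mg_rows = {}
    for g in genes:
        ok = multigroup_pass is not None and g in multigroup_pass
        mg_rows[g] = {"log2fc": 2.0 if ok else 0.0, "p": 0.001 if ok else 0.9,
                      "p_adj": 0.01 if ok else 0.95, "mean_a": 1.0, "mean_b": 1.0}
    multigroup = DEResult(pd.DataFrame(mg_rows).T, "all")
    return NeighborScan(ages, means, sems, comparisons, multigroup)


def brute_force_best_run(values: list[float], direction: int) -> int:
    """Oracle: longest strictly monotone window length, by enumeration."""
    log_means = np.log2(np.asarray(values) + 0.5)
    best = 0
    n = len(values)
    for i in range(n):
        for j in range(i + 1, n):
            window = log_means[i:j + 1]
            diffs = np.diff(window) * direction
            if (diffs > 0).all():
                best = max(best, j - i + 1)
    return best


class TestNeighborComparisons:
    def test_seven_timepoints_give_six_comparisons(self):
        spec = BulkSimSpec(n_genes=60, reps_per_timepoint=2, seed=0,
                           n_up_gradual=5, n_down_gradual=5)
        series, _ = simulate_bulk_series(spec)
        scan = neighbor_comparisons(series)
        assert len(scan.comparisons) == 6
        assert scan.timepoints == TIMEPOINTS

    def test_strong_up_gene_positive_in_all_steps(self):
        # modest trend-gene fraction keeps library composition stable
        spec = BulkSimSpec(n_genes=500, n_up_gradual=10, n_down_gradual=0,
                           per_step_log2_effect=0.5, reps_per_timepoint=6,
                           dispersion=0.05, seed=1)
        series, truth = simulate_bulk_series(spec)
        scan = neighbor_comparisons(series)
        up = truth.genes_with_label("up_gradual")
        signs = np.stack([c.table.loc[up, "log2fc"].to_numpy() > 0
                          for c in scan.comparisons])
        assert signs.all(axis=0).mean() >= 0.9

    def test_single_timepoint_rejected(self):
        counts = pd.DataFrame(np.ones((5, 4), dtype=int),
                              index=[f"g{i}" for i in range(5)],
                              columns=[f"s{i}" for i in range(4)])
        meta = pd.DataFrame({"age_months": [3.0] * 4, "sex": ["F"] * 4,
                             "replicate": [1, 2, 3, 4]},
                            index=pd.Index([f"s{i}" for i in range(4)],
                                           name="sample_id"))
        with pytest.raises(ValidationError, match="timepoints"):
            neighbor_comparisons(ExpressionSeries(counts, meta))


class TestClassifyAdem:
    def test_perfect_monotone_rise_is_padem_full_run(self):
        scan = make_scan({"g": [1, 2, 3, 4, 5, 6, 7]},
                         significant_steps={"g": [0, 1, 2, 3, 4, 5]},
                         multigroup_pass={"g"})
        (call,) = classify_adem(scan, epsilon=0.0)
        assert call.direction == "P-ADEM"
        assert call.run_length == 7
        assert (call.run_start, call.run_end) == (0, 6)

    def test_constant_means_are_none(self):
        scan = make_scan({"g": [5, 5, 5, 5, 5, 5, 5]}, multigroup_pass={"g"})
        (call,) = classify_adem(scan, epsilon=0.0)
        assert call.direction == "none"
        assert call.run_length == 0

    def test_v_shaped_gene_reports_earliest_descending_window(self):
        # falls over t1..t5, rises after; steps 1-4 significant
        scan = make_scan({"g": [5, 4, 3, 2, 1, 2, 3]},
                         significant_steps={"g": [0, 1, 2, 3]},
                         multigroup_pass={"g"})
        (call,) = classify_adem(scan, epsilon=0.0, min_run=5)
        assert call.direction == "N-ADEM"
        assert (call.run_start, call.run_end) == (0, 4)
        assert call.run_length == 5 == brute_force_best_run([5, 4, 3, 2, 1, 2, 3], -1)
        assert call.n_significant_steps == 4

    def test_run_below_min_run_is_none(self):
        scan = make_scan({"g": [1, 2, 3, 4, 1, 1, 1]},
                         significant_steps={"g": [0, 1, 2]},
                         multigroup_pass={"g"})
        (call,) = classify_adem(scan, epsilon=0.0, min_run=5)
        assert call.direction == "none"

    def test_multigroup_gate_blocks_non_deg(self):
        scan = make_scan({"g": [1, 2, 3, 4, 5, 6, 7]},
                         significant_steps={"g": [0]},
                         multigroup_pass=set())
        (call,) = classify_adem(scan, epsilon=0.0, require_deg="multigroup")
        assert call.direction == "none"
        (call,) = classify_adem(scan, epsilon=0.0, require_deg="none")
        assert call.direction == "P-ADEM"

    def test_any_step_gate_requires_significant_step_inside_run(self):
        scan = make_scan({"g": [1, 2, 3, 4, 5, 6, 7]}, significant_steps={},
                         multigroup_pass={"g"})
        (call,) = classify_adem(scan, epsilon=0.0, require_deg="any_step_in_run")
        assert call.direction == "none"

    def test_min_run_longer_than_series_rejected(self):
        scan = make_scan({"g": [1, 2, 3, 4, 5, 6, 7]})
        with pytest.raises(ValidationError):
            classify_adem(scan, min_run=8)

    def test_direction_is_exclusive(self):
        scan = make_scan({"g": [1, 2, 3, 1, 5, 4, 3]},
                         significant_steps={"g": [0, 1, 3, 4, 5]},
                         multigroup_pass={"g"})
        calls = classify_adem(scan, epsilon=0.0, min_run=2)
        assert len(calls) == 1 and calls[0].direction in {"P-ADEM", "N-ADEM", "none"}

    def test_extending_a_trend_never_shortens_the_run(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            vals = list(rng.uniform(1, 100, 6))
            scan_a = make_scan({"g": vals}, multigroup_pass={"g"})
            (call_a,) = classify_adem(scan_a, epsilon=0.0, min_run=2,
                                      require_deg="none")
            extended = vals + [vals[-1] * 2.0]  # continues any up-trend
            scan_b = make_scan({"g": extended}, multigroup_pass={"g"})
            (call_b,) = classify_adem(scan_b, epsilon=0.0, min_run=2,
                                      require_deg="none")
            if call_a.direction == "P-ADEM":
                assert call_b.direction == "P-ADEM"
                assert call_b.run_length >= call_a.run_length

    def test_shuffled_timepoints_destroy_most_calls(self):
        spec = BulkSimSpec(n_genes=1000, seed=15)
        series, _ = simulate_bulk_series(spec)
        base_calls = classify_adem(neighbor_comparisons(series))
        base_rate = np.mean([c.direction != "none" for c in base_calls])
        # permute the age labels attached to the timepoint groups
        rng = np.random.default_rng(16)
        ages = series.timepoints()
        perm = dict(zip(ages, rng.permutation(ages)))
        meta = series.meta.copy()
        meta["age_months"] = meta["age_months"].map(perm)
        shuffled = ExpressionSeries(series.counts.copy(), meta, series.gene_lengths_kb)
        calls = classify_adem(neighbor_comparisons(shuffled))
        rate = np.mean([c.direction != "none" for c in calls])
        # chance monotone runs survive the noise tolerance occasionally, but
        # destroying the ordering must collapse the call rate
        assert rate <= 0.05
        assert rate <= base_rate / 3.0


class TestAgeCorrelation:
    def test_expression_equal_to_age_is_perfect(self):
        ages = np.array([3.0, 6.0, 9.0, 12.0, 24.0])
        res = age_correlation_values(ages.copy(), ages)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_negated_expression_flips_sign(self):
        ages = np.array([3.0, 6.0, 9.0, 12.0, 24.0])
        res = age_correlation_values(-ages, ages)
        assert res.pearson_r == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(17)
        ages = rng.uniform(3, 24, 20)
        expr = rng.normal(size=20)
        res = age_correlation_values(expr, ages)
        r_oracle = (np.mean(ages * expr) - ages.mean() * expr.mean()) / (
            ages.std() * expr.std())
        assert res.pearson_r == pytest.approx(r_oracle, abs=1e-12)
        slope_oracle = r_oracle * expr.std() / ages.std()
        assert res.slope == pytest.approx(slope_oracle, abs=1e-12)

    def test_zero_variance_is_degenerate_not_nan(self):
        res = age_correlation_values(np.full(6, 2.5), np.array([3, 6, 9, 12, 16, 24.0]))
        assert res.degenerate
        assert res.pearson_r == 0.0 and np.isfinite(res.pearson_p)
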