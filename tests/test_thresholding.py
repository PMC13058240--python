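import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyetrack import (
    ValidationError,
    build_roc,
    compare_threshold_strategies,
    evaluate_threshold,
    pooled_threshold,
    retention_curve,
    select_threshold,
)
from dyetrack import paperlike_config, simulate_intensities

STAINED = [5.0, 4.0, 3.0]
UNSTAINED = [1.0, 2.0, 4.0]


def roc_by_enumeration(stained, unstained):
    """Independent O(n^2) oracle: try every candidate, count >= matches."""
    s = np.asarray(stained, float)
    u = np.asarray(unstained, float)
    cands = sorted(set(s) | set(u), reverse=True)
    cands = [max(cands) + 1.0] + cands
    return {
        t: (np.mean(s >= t), np.mean(u >= t))
        for t in cands
    }


class TestBuildRoc:
    def test_matches_hand_enumeration(self):
        roc = build_roc(STAINED, UNSTAINED)
        points = dict(zip(roc.thresholds, zip(roc.tpr, roc.fpr)))
        assert points[3.0] == (1.0, pytest.approx(1 / 3))
        assert points[5.0] == (pytest.approx(1 / 3), 0.0)

    def test_perfect_separation_reaches_corner(self):
        roc = build_roc([10.0, 11.0], [1.0, 2.0])
        assert any(t == 1.0 and f == 0.0 for t, f in zip(roc.tpr, roc.fpr))

    def test_identical_samples_give_diagonal(self):
        roc = build_roc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(roc.tpr, roc.fpr)

    def test_rates_monotone_in_descending_thresholds(self):
        rng = np.random.default_rng(0)
        roc = build_roc(rng.normal(1, 1, 50), rng.normal(0, 1, 50))
        assert np.all(np.diff(roc.tpr) >= 0) and np.all(np.diff(roc.fpr) >= 0)
        assert roc.tpr[-1] == 1.0 and roc.fpr[-1] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            build_roc([], [1.0])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        s=st.lists(st.integers(-5, 10), min_size=1, max_size=40),
        u=st.lists(st.integers(-5, 10), min_size=1, max_size=40),
    )
    def test_sweep_equals_exhaustive_enumeration(self, s, u):
        roc = build_roc(s, u)
        oracle = roc_by_enumeration(s, u)
        assert len(roc.thresholds) == len(oracle)
        for t, tpr, fpr in zip(roc.thresholds, roc.tpr, roc.fpr):
            assert (tpr, fpr) == pytest.approx(oracle[t])

    def test_agrees_with_sklearn_roc_curve(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        s = rng.normal(2, 1, 200)
        u = rng.normal(0, 1, 300)
        roc = build_roc(s, u)
        y = np.r_[np.ones_like(s), np.zeros_like(u)]
        fpr, tpr, _ = sklearn_metrics.roc_curve(y, np.r_[s, u], drop_intermediate=False)
        assert set(zip(np.round(fpr, 12), np.round(tpr, 12))) == set(
            zip(np.round(roc.fpr, 12), np.round(roc.tpr, 12))
        )


class TestSelectThreshold:
    def test_closest_topleft_example(self):
        rep = select_threshold(build_roc(STAINED, UNSTAINED), "closest_topleft")
        assert rep.threshold == 3.0
        assert rep.accuracy == pytest.approx(5 / 6)
        assert rep.average == pytest.approx(5 / 6)

    def test_tie_breaks_toward_lower_fpr(self):
        # t=3 and t=5 both at distance 0.5; t=5 has FPR 0
        rep = select_threshold(build_roc([5.0, 3.0], [4.0, 1.0]))
        assert rep.threshold == 5.0 and rep.fpr == 0.0

    @pytest.mark.parametrize("criterion", ["closest_topleft", "balanced_accuracy"])
    def test_perfect_separation_gives_perfect_metrics(self, criterion):
        rep = select_threshold(build_roc([10.0, 12.0], [1.0, 2.0]), criterion)
        assert (rep.tpr, rep.fpr, rep.accuracy) == (1.0, 0.0, 1.0)

    def test_report_invariants(self):
        rng = np.random.default_rng(2)
        rep = select_threshold(build_roc(rng.normal(1, 1, 100), rng.normal(0, 1, 100)))
        assert rep.tnr == pytest.approx(1.0 - rep.fpr)
        assert rep.average == pytest.approx((rep.tpr + rep.tnr) / 2)
        assert 0.5 <= rep.average <= 1.0

    def test_converges_to_equal_density_crossing(self):
        """With equal-sd Gaussian classes the optimum approaches the midpoint."""
        rng = np.random.default_rng(8)
        mu_u, mu_s, sd = 0.0, 5.0, 1.0
        rep = select_threshold(build_roc(rng.normal(mu_s, sd, 100_000), rng.normal(mu_u, sd, 100_000)))
        assert abs(rep.threshold - (mu_s + mu_u) / 2) < 2 * sd

    def test_validation_metrics_on_holdout(self):
        rep = select_threshold(build_roc(STAINED, UNSTAINED)).with_validation([4.0, 2.0], [1.0])
        assert rep.validation.tpr == 0.5 and rep.validation.tnr == 1.0


class TestEvaluateThreshold:
    @pytest.mark.parametrize(
        "threshold,tpr,tnr,accuracy",
        [
            (3.0, 1.0, 2 / 3, 5 / 6),
            (0.0, 1.0, 0.0, 0.5),  # below everything
            (6.0, 0.0, 1.0, 0.5),  # above everything
        ],
    )
    def test_inclusive_rule_metrics(self, threshold, tpr, tnr, accuracy):
        m = evaluate_threshold(threshold, STAINED, UNSTAINED)
        assert (m.tpr, m.tnr) == (pytest.approx(tpr), pytest.approx(tnr))
        assert m.accuracy == pytest.approx(accuracy)

    def test_adding_stained_above_threshold_never_lowers_tpr(self):
        base = evaluate_threshold(3.0, STAINED, UNSTAINED)
        grown = evaluate_threshold(3.0, STAINED + [7.0], UNSTAINED)
        assert grown.tpr >= base.tpr


class TestPooledThreshold:
    def test_single_timepoint_general_equals_per_timepoint(self):
        samples = {0.0: (STAINED, UNSTAINED)}
        general = pooled_threshold(samples, mode="general")
        per_tp = pooled_threshold(samples, mode="per_timepoint")
        assert general == per_tp[0.0]

    def test_identical_timepoints_pool_to_same_threshold(self):
        samples = {0.0: (STAINED, UNSTAINED), 2.0: (STAINED, UNSTAINED)}
        assert pooled_threshold(samples).threshold == pooled_threshold(
            {0.0: (STAINED, UNSTAINED)}
        ).threshold

    def test_general_beats_t0_threshold_on_ageing_dilution_series(self):
        """Pooling over time points outperforms carrying the t=0 threshold forward."""
        config = paperlike_config()
        rng = np.random.default_rng(12)
        samples = {
            float(t): (
                simulate_intensities("stained", 0.8 * i, 2000, config, rng, competitor="A"),
                simulate_intensities("unstained", 0.0, 2000, config, rng, competitor="B"),
            )
            for i, t in enumerate(range(0, 11, 2))
        }
        general = pooled_threshold(samples, mode="general")
        t0 = pooled_threshold({0.0: samples[0.0]}, mode="general")
        acc_general = np.mean(
            [evaluate_threshold(general.threshold, s, u).accuracy for s, u in samples.values()]
        )
        acc_t0 = np.mean(
            [evaluate_threshold(t0.threshold, s, u).accuracy for s, u in samples.values()]
        )
        assert acc_general >= acc_t0


class TestCompareStrategies:
    def test_identical_pairs_collapse_to_one_threshold(self):
        cmp = compare_threshold_strategies(STAINED, UNSTAINED, STAINED, UNSTAINED)
        assert cmp.separate[0].threshold == cmp.unified.threshold
        assert cmp.separate[1].threshold == cmp.unified.threshold

    def test_perfectly_separated_pairs_reach_accuracy_one(self):
        cmp = compare_threshold_strategies([10.0, 11.0], [1.0], [12.0, 13.0], [2.0])
        assert cmp.separate_mean_accuracy == 1.0
        assert cmp.unified_mean_accuracy == 1.0

    def test_separate_thresholds_win_under_background_offsets(self):
        """Different competitor autofluorescence favours per-competitor thresholds."""
        config = paperlike_config(autofluor_offset={"A": 0.0, "B": 2.5})
        rng = np.random.default_rng(21)
        sa = simulate_intensities("stained", 3.0, 3000, config, rng, competitor="A")
        ua = simulate_intensities("unstained", 0.0, 3000, config, rng, competitor="A")
        sb = simulate_intensities("stained", 0.0, 3000, config, rng, competitor="B")
        ub = simulate_intensities("unstained", 0.0, 3000, config, rng, competitor="B")
        cmp = compare_threshold_strategies(sa, ua, sb, ub)
        assert cmp.separate_mean_accuracy >= cmp.unified_mean_accuracy


class TestRetentionCurve:
    def test_constant_intensities_give_flat_curve(self):
        curve = retention_curve({t: [100.0, 100.0] for t in (0.0, 2.0, 4.0)})
        assert np.ptp(curve["mean"]) == 0.0 and (curve["sd"] == 0).all()

    def test_single_timepoint(self):
        curve = retention_curve({0.0: [1.0, 3.0]})
        assert len(curve) == 1 and curve.loc[0, "mean"] == 2.0

    def test_empty_timepoint_omitted(self):
        curve = retention_curve({0.0: [1.0], 2.0: []})
        assert list(curve["time_h"]) == [0.0]

    def test_mean_log2_intensity_drops_one_per_generation(self):
        """Dye halving per division shows up as a unit log2 decrement per step."""
        config = paperlike_config(autofluor_log_mean=-20.0)  # isolate the dye component
        rng = np.random.default_rng(31)
        curve = retention_curve(
            {
                float(g): np.log2(
                    simulate_intensities("stained", float(g), 50_000, config, rng)
                )
                for g in range(4)
            }
        )
        drops = -np.diff(curve["mean"])
        assert np.allclose(drops, 1.0, atol=0.05)
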