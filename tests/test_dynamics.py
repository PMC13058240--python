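import numpy as np
import pandas as pd
import pytest

from dyetrack import (
    ODSeries,
    SampleMeta,
    Trajectory,
    ValidationError,
    aggregate_trends,
    carrying_capacity,
    fit_frequency_trend,
    propagate_frequency,
)

COND = (0.5, "X", False)


def traj(times, freqs, **kw):
    return Trajectory(condition=COND, replicate=1, time_h=np.asarray(times), freq=np.asarray(freqs), **kw)


def od_series(replicate, values, ratio=0.5):
    meta = SampleMeta(
        sample_id=f"co_rep{replicate}",
        culture_kind="coculture",
        competitor_a="X",
        competitor_b="Y",
        stained_competitor="X",
        initial_ratio=ratio,
        replicate=replicate,
    )
    return ODSeries(meta=meta, points=pd.DataFrame({"time_h": np.arange(len(values), dtype=float), "od600": values}))


class TestFitFrequencyTrend:
    def test_logit_slope_identity(self):
        est = fit_frequency_trend(traj([0.0, 1.0], [0.5, 0.7310585786300049]))
        assert est.s_logit == pytest.approx(1.0, abs=1e-9)

    def test_constant_trajectory_has_zero_trend(self):
        est = fit_frequency_trend(traj([0.0, 2.0, 4.0], [0.4, 0.4, 0.4]))
        assert est.slope == 0.0 and est.s_logit == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(ValidationError):
            fit_frequency_trend(traj([0.0], [0.5]))

    def test_complement_negates_both_slopes(self):
        times = [0.0, 2.0, 4.0, 6.0]
        freqs = [0.2, 0.35, 0.5, 0.7]
        a = fit_frequency_trend(traj(times, freqs))
        b = fit_frequency_trend(traj(times, [1 - f for f in freqs]))
        assert b.slope == pytest.approx(-a.slope)
        assert b.s_logit == pytest.approx(-a.s_logit)

    def test_time_shift_invariance(self):
        times = np.array([0.0, 2.0, 4.0, 8.0])
        freqs = np.array([0.2, 0.3, 0.45, 0.6])
        a = fit_frequency_trend(traj(times, freqs))
        b = fit_frequency_trend(traj(times + 100.0, freqs))
        assert b.slope == pytest.approx(a.slope)
        assert b.s_logit == pytest.approx(a.s_logit)

    def test_noise_free_selection_is_exactly_logit_linear(self):
        w, g_per_h = 0.8, 0.5
        times = np.arange(0.0, 12.0, 2.0)
        freqs = [propagate_frequency(0.6, w, g_per_h * t) for t in times]
        est = fit_frequency_trend(traj(times, np.array(freqs)))
        assert est.s_logit == pytest.approx(g_per_h * np.log(w), abs=1e-12)
        assert est.s_logit_se == pytest.approx(0.0, abs=1e-9)

    def test_pseudocount_used_at_boundary_frequencies(self):
        t = traj(
            [0.0, 2.0],
            [0.0, 1.0],
            n_focal=np.array([0.0, 100.0]),
            n_total=np.array([100.0, 100.0]),
        )
        est = fit_frequency_trend(t)
        expected = (np.log(100.5 / 0.5) - np.log(0.5 / 100.5)) / 2.0
        assert est.s_logit == pytest.approx(expected)

    def test_recovers_programmed_selection_rate_from_noisy_counts(self):
        """Mean s_logit over replicates matches g * ln(w) within 2 SE."""
        w, g_per_h, n = 0.85, 0.4, 2000
        times = np.arange(0.0, 12.0, 2.0)
        rng = np.random.default_rng(23)
        slopes = []
        for _ in range(100):
            f_true = np.array([propagate_frequency(0.5, w, g_per_h * t) for t in times])
            x = rng.binomial(n, f_true)
            est = fit_frequency_trend(
                traj(times, x / n, n_focal=x.astype(float), n_total=np.full(times.size, float(n)))
            )
            slopes.append(est.s_logit)
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert abs(slopes.mean() - g_per_h * np.log(w)) < 2 * se


class TestAggregateTrends:
    def est(self, value):
        from dyetrack import TrendEstimate

        return TrendEstimate(slope=value, slope_se=0.0, s_logit=value, s_logit_se=0.0, n_points=6)

    def test_identical_replicates_have_zero_se(self):
        out = aggregate_trends({COND: [self.est(0.1)] * 3})
        assert out.loc[0, "mean"] == pytest.approx(0.1)
        assert out.loc[0, "se"] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_slopes_average_to_zero(self):
        out = aggregate_trends({COND: [self.est(0.2), self.est(-0.2)]})
        assert out.loc[0, "mean"] == 0.0

    def test_single_replicate_flagged(self):
        out = aggregate_trends({COND: [self.est(0.3)]})
        assert bool(out.loc[0, "flagged_single_replicate"]) and np.isnan(out.loc[0, "se"])

    def test_recovers_programmed_drift_signs_across_conditions(self):
        """12-condition design with 8 negative drifts: every sign recovered."""
        rng = np.random.default_rng(29)
        n, g_per_h = 2000, 0.4
        times = np.arange(0.0, 12.0, 2.0)
        conditions = [
            (ratio, comp, predator)
            for ratio in (0.1, 0.5, 0.9)
            for comp in ("X", "Y")
            for predator in (False, True)
        ]
        w_by_condition = {c: (1.15 if i % 3 == 0 else 0.85) for i, c in enumerate(conditions)}
        assert sum(w < 1 for w in w_by_condition.values()) == 8
        correct = 0
        for _ in range(5):  # independent replicate experiments
            grouped = {}
            for cond, w in w_by_condition.items():
                for rep in range(3):
                    f_true = np.array(
                        [propagate_frequency(cond[0], w, g_per_h * t) for t in times]
                    )
                    x = rng.binomial(n, f_true)
                    grouped.setdefault(cond, []).append(
                        fit_frequency_trend(
                            Trajectory(
                                condition=cond,
                                replicate=rep + 1,
                                time_h=times,
                                freq=x / n,
                                n_focal=x.astype(float),
                                n_total=np.full(times.size, float(n)),
                            )
                        )
                    )
            out = aggregate_trends(grouped)
            for _, row in out.iterrows():
                correct += (row["mean"] < 0) == (w_by_condition[row["condition"]] < 1)
        assert correct >= 0.95 * 5 * len(conditions)


class TestCarryingCapacity:
    def test_max_od_per_culture(self):
        per_culture, _ = carrying_capacity([od_series(1, [0.1, 0.4, 0.35])])
        assert per_culture.loc[0, "max_od"] == pytest.approx(0.4)

    def test_mean_across_replicates(self):
        series = [od_series(r, [0.1, v]) for r, v in zip((1, 2, 3), (0.4, 0.5, 0.6))]
        _, per_condition = carrying_capacity(series)
        assert per_condition.loc[0, "mean_max_od"] == pytest.approx(0.5)
        assert per_condition.loc[0, "k_replicates"] == 3

    def test_recovers_programmed_capacity_from_logistic_curves(self):
        from dyetrack.simulator import logistic_od

        rng = np.random.default_rng(37)
        capacity, noise = 0.42, 0.005
        t = np.arange(0.0, 12.0, 2.0)
        series = []
        for rep in (1, 2, 3):
            od = logistic_od(t, 0.01, 1.2, capacity) + rng.normal(0, noise, t.size)
            series.append(od_series(rep, np.maximum(od, 0.0)))
        _, per_condition = carrying_capacity(series)
        assert per_condition.loc[0, "mean_max_od"] == pytest.approx(capacity, abs=4 * noise)
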