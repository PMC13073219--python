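"""Summaries, strategy comparison, turnout sweep and the density GLM."""

import numpy as np
import pytest
from scipy.stats import t as t_dist

from dualdispatch import (
    ResponseRecord,
    Service,
    Strategy,
    compare_strategies,
    fit_density_glm,
    predict_response,
    summarize,
    turnout_sweep,
)
from dualdispatch.errors import FitError, StatsError
from dualdispatch.stats import GlmFit, sweep_from_travel


def _record(eid, ems_resp, dual_resp, density=100.0):
    return ResponseRecord(
        event_id=eid,
        location=(0.0, 0.0),
        local_density=density,
        ems_travel_min=ems_resp - 2.0,
        fire_travel_min=0.0,
        ems_response_min=ems_resp,
        fire_response_min=dual_resp,
        dual_response_min=dual_resp,
        first_arriver=Service.FIRE if dual_resp < ems_resp else Service.EMS,
    )


class TestSummarize:
    def test_constant_responses(self):
        records = [_record(i, 7.0, 7.0) for i in range(5)]
        s = summarize(records, Strategy.EMS_ONLY)
        assert s.mean_min == 7.0
        assert s.sd_min == 0.0
        assert all(v == 7.0 for v in s.percentiles.values())

    def test_threshold_fraction_is_inclusive_count(self):
        records = [_record(i, r, r) for i, r in enumerate([4.0, 8.0, 12.0])]
        s = summarize(records, Strategy.EMS_ONLY, thresholds=(10.0,))
        assert s.frac_within[10.0] == pytest.approx(2 / 3)

    def test_internal_consistency(self, small_records):
        s = summarize(
            small_records, Strategy.DUAL, thresholds=(5.0, 10.0, 1e9)
        )
        assert s.frac_within[1e9] == 1.0
        assert s.frac_within[5.0] <= s.frac_within[10.0]
        assert s.percentiles[10.0] <= s.percentiles[50.0] <= s.percentiles[90.0]
        assert 0.0 <= s.frac_fire_first <= 1.0

    def test_dual_dominates_ems_only_in_mean(self, small_records):
        mean_dual = summarize(small_records, Strategy.DUAL).mean_min
        mean_ems = summarize(small_records, Strategy.EMS_ONLY).mean_min
        assert mean_dual < mean_ems

    def test_empty_records_rejected(self):
        with pytest.raises(StatsError):
            summarize([], Strategy.DUAL)


class TestComparison:
    def test_identical_strategies_degenerate_to_p_one(self):
        records = [_record(i, 9.0 + i, 9.0 + i) for i in range(10)]
        c = compare_strategies(records)
        assert c.t_statistic == 0.0
        assert c.p_value == 1.0

    def test_clear_separation_is_significant(self):
        rng = np.random.default_rng(0)
        records = [
            _record(i, 10.0 + e, 7.0 + e + 1e-3 * rng.standard_normal())
            for i, e in enumerate(rng.normal(0, 1, size=30))
        ]
        c = compare_strategies(records)
        assert c.p_value < 0.001
        assert c.mean_difference_min == pytest.approx(3.0, abs=0.01)

    def test_matches_closed_form_paired_t(self):
        # independent oracle: t = mean(d) / (sd(d)/sqrt(n)), two-sided p
        rng = np.random.default_rng(42)
        diffs = rng.uniform(0.0, 5.0, size=20)
        records = [_record(i, 10.0 + d, 10.0) for i, d in enumerate(diffs)]
        c = compare_strategies(records)
        n = len(diffs)
        t_oracle = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(n))
        p_oracle = 2.0 * t_dist.sf(abs(t_oracle), df=n - 1)
        assert c.t_statistic == pytest.approx(t_oracle, rel=1e-12)
        assert c.p_value == pytest.approx(p_oracle, rel=1e-12)

    def test_welch_variant_runs(self, small_records):
        c = compare_strategies(small_records, kind="welch")
        assert c.test_kind == "welch"
        assert 0.0 <= c.p_value <= 1.0

    def test_too_few_records_rejected(self):
        with pytest.raises(StatsError):
            compare_strategies([_record(0, 5.0, 4.0)])


class TestSweep:
    def test_dense_fire_coverage_puts_fire_first_at_low_turnout(
        self, small_instance, small_events
    ):
        _, network, stations = small_instance
        sw = turnout_sweep(small_events, stations, network, [2.0], alpha=0.05)
        assert sw.points[0].summary_dual.frac_fire_first > 0.5

    def test_huge_turnout_degenerates_to_p_one(self, small_instance, small_events):
        _, network, stations = small_instance
        sw = turnout_sweep(small_events, stations, network, [1e6], alpha=0.05)
        assert sw.points[0].comparison.p_value == 1.0
        assert sw.threshold_turnout == 1e6

    def test_mean_dual_nondecreasing_along_grid(self, small_instance, small_events):
        _, network, stations = small_instance
        sw = turnout_sweep(
            small_events, stations, network, [5.0, 8.0, 11.0, 14.0, 17.0, 20.0]
        )
        means = [p.summary_dual.mean_min for p in sw.points]
        fracs = [p.summary_dual.frac_fire_first for p in sw.points]
        diffs = [p.comparison.mean_difference_min for p in sw.points]
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(fracs, fracs[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(diffs, diffs[1:]))

    def test_unsorted_grid_rejected(self, small_events):
        with pytest.raises(StatsError):
            sweep_from_travel(
                small_events,
                np.zeros(len(small_events)),
                np.zeros(len(small_events)),
                [5.0, 3.0],
            )


class TestGlm:
    TRUTH = {"intercept": 12.0, "density": -0.001, "strategy": -4.0, "interaction": 0.0005}

    def _records_from_model(self, densities, noise=None):
        b = self.TRUTH
        records = []
        rng = None if noise is None else np.random.default_rng(noise)
        for i, d in enumerate(densities):
            ems = b["intercept"] + b["density"] * d
            dual = ems + b["strategy"] + b["interaction"] * d
            if rng is not None:
                ems += rng.standard_normal()
                dual += rng.standard_normal()
            records.append(_record(i, ems, dual, density=float(d)))
        return records

    def test_noiseless_data_recovers_coefficients_exactly(self):
        densities = np.linspace(5.0, 2000.0, 40)
        fit = fit_density_glm(self._records_from_model(densities))
        for name, value in self.TRUTH.items():
            assert fit.coefficients[name] == pytest.approx(value, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_fit_is_close_and_significant(self):
        rng = np.random.default_rng(1)
        densities = rng.uniform(10.0, 3000.0, size=2000)
        fit = fit_density_glm(self._records_from_model(densities, noise=7))
        assert fit.coefficients["density"] == pytest.approx(-0.001, abs=2e-4)
        assert fit.coefficients["interaction"] == pytest.approx(0.0005, abs=2e-4)
        assert fit.p_values["strategy"] < 0.001
        assert 0.0 <= fit.r_squared <= 1.0

    def test_constant_density_named_in_error(self):
        records = [_record(i, 10.0, 8.0, density=50.0) for i in range(10)]
        with pytest.raises(FitError, match="density"):
            fit_density_glm(records)

    def test_pipeline_fit_shows_rural_advantage_pattern(self, small_records):
        fit = fit_density_glm(small_records)
        assert fit.coefficients["density"] < 0
        assert fit.coefficients["interaction"] > 0

    def test_prediction_arithmetic(self):
        flat = GlmFit(
            coefficients={"intercept": 10.0, "density": 0.0, "strategy": 0.0, "interaction": 0.0},
            standard_errors={}, p_values={}, r_squared=0.0, n_obs=0,
        )
        assert predict_response(flat, 5000.0, Strategy.DUAL) == 10.0
        fit = GlmFit(
            coefficients=dict(
                intercept=12.0, density=-0.001, strategy=-4.0, interaction=0.0005
            ),
            standard_errors={}, p_values={}, r_squared=0.5, n_obs=10,
        )
        assert predict_response(fit, 1000.0, 1) == pytest.approx(7.5)

    def test_positive_interaction_shrinks_dual_advantage_with_density(self):
        fit = GlmFit(
            coefficients=dict(
                intercept=12.0, density=-0.001, strategy=-4.0, interaction=0.0005
            ),
            standard_errors={}, p_values={}, r_squared=0.5, n_obs=10,
        )
        gain_low = predict_response(fit, 100.0, 0) - predict_response(fit, 100.0, 1)
        gain_high = predict_response(fit, 10_000.0, 0) - predict_response(fit, 10_000.0, 1)
        assert gain_low > gain_high
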