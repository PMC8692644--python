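import numpy as np
import pytest

from polarfoodweb.calibrate import (
    AnnealSchedule,
    ParameterSample,
    TargetDataset,
    credible_intervals,
    log_likelihood,
    simulated_anneal,
    summary_quantity,
)
from polarfoodweb.errors import OptimizationError, ParameterError, StructuralError


def targets(rows):
    return TargetDataset.from_records(rows)


class TestLogLikelihood:
    def test_perfect_fit_is_zero(self, baseline_run):
        t = targets([("npp", "whole", baseline_run.npp, 10.0)])
        assert log_likelihood(baseline_run, t) == pytest.approx(0.0)

    def test_one_sd_off_is_minus_half(self, baseline_run):
        t = targets([("npp", "whole", baseline_run.npp + 10.0, 10.0)])
        assert log_likelihood(baseline_run, t) == pytest.approx(-0.5)

    def test_two_targets_at_one_and_two_sd(self, baseline_run):
        b = baseline_run.annual_mean("fish_p")
        t = targets([("npp", "whole", baseline_run.npp + 5.0, 5.0),
                     ("fish_p", "whole", b + 0.2, 0.1)])
        assert log_likelihood(baseline_run, t) == pytest.approx(-2.5)

    def test_row_order_invariant(self, baseline_run):
        rows = [("npp", "whole", 800.0, 50.0),
                ("fish_p", "whole", 3.0, 0.5),
                ("catch_fish_d", "whole", 0.3, 0.05)]
        a = log_likelihood(baseline_run, targets(rows))
        b = log_likelihood(baseline_run, targets(rows[::-1]))
        assert a == pytest.approx(b)

    def test_unknown_quantity_named_in_error(self, baseline_run):
        t = targets([("chlorophyll_max", "whole", 1.0, 0.1)])
        with pytest.raises(StructuralError, match="chlorophyll_max"):
            log_likelihood(baseline_run, t)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ParameterError):
            targets([("npp", "whole", 800.0, 0.0)])

    def test_catch_quantities_resolve(self, baseline_run):
        assert summary_quantity(baseline_run, "catch_fish_d") > 0


class TestSimulatedAnneal:
    @staticmethod
    def bowl(x):
        return float((x[0] - 0.3) ** 2 + 2 * (x[1] + 0.4) ** 2)

    def test_zero_iterations_returns_initial(self):
        x0 = np.array([1.0, 1.0])
        best, trace = simulated_anneal(self.bowl, x0, [(-2, 2), (-2, 2)],
                                       AnnealSchedule(iterations=0))
        assert np.array_equal(best, x0)

    def test_quadratic_bowl_recovered(self):
        sched = AnnealSchedule(iterations=4000, seed=42, step_scale=0.05,
                               initial_temperature=1.0)
        best, _ = simulated_anneal(self.bowl, [1.5, 1.5],
                                   [(-2, 2), (-2, 2)], sched)
        assert np.allclose(best, [0.3, -0.4], atol=1e-2)

    def test_best_trace_monotone_nonincreasing(self):
        sched = AnnealSchedule(iterations=500, seed=3)
        _, trace = simulated_anneal(self.bowl, [1.5, -1.5],
                                    [(-2, 2), (-2, 2)], sched)
        best = trace["best"]
        assert all(b2 <= b1 + 1e-15 for b1, b2 in zip(best, best[1:]))

    def test_zero_temperature_is_greedy(self):
        sched = AnnealSchedule(iterations=400, seed=5,
                               initial_temperature=0.0)
        _, trace = simulated_anneal(self.bowl, [1.0, 1.0],
                                    [(-2, 2), (-2, 2)], sched)
        obj = trace["objective"]
        accepted_uphill = [
            a and obj[i + 1] > obj[i] + 1e-15
            for i, a in enumerate(trace["accepted"])
        ]
        assert not any(accepted_uphill)

    def test_reproducible_per_seed(self):
        sched = AnnealSchedule(iterations=300, seed=11)
        b1, _ = simulated_anneal(self.bowl, [1, 1], [(-2, 2), (-2, 2)], sched)
        b2, _ = simulated_anneal(self.bowl, [1, 1], [(-2, 2), (-2, 2)], sched)
        assert np.array_equal(b1, b2)

    def test_infinite_initial_objective_rejected(self):
        with pytest.raises(OptimizationError):
            simulated_anneal(lambda x: float("inf"), [0.0], [(-1, 1)],
                             AnnealSchedule(iterations=10))


def make_samples(values, loglik):
    return [ParameterSample(values=np.array([v]), log_likelihood=ll)
            for v, ll in zip(values, loglik)]


class TestCredibleIntervals:
    def test_equal_weights_reduce_to_empirical_quantiles(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=200)
        samples = make_samples(vals, np.zeros(200))
        out = credible_intervals(samples, lambda s: s.values[0],
                                 quantiles=(0.25, 0.5, 0.75))
        sorted_vals = np.sort(vals)
        cdf = np.arange(1, 201) / 200
        for q, v in out.items():
            # allow one-sample slack for floating-point ties in the CDF
            j = int(np.searchsorted(cdf, q))
            neighbourhood = sorted_vals[max(0, j - 1):j + 2]
            assert any(v == pytest.approx(e, abs=1e-12)
                       for e in neighbourhood)

    def test_dominant_sample_collapses_interval(self):
        samples = make_samples([1.0, 2.0, 3.0], [0.0, -500.0, -500.0])
        with pytest.warns(UserWarning):
            out = credible_intervals(samples, lambda s: s.values[0])
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_weights_normalised(self):
        samples = make_samples([1, 2, 3, 4], [-1.0, -2.0, -0.5, -3.0])
        credible_intervals(samples, lambda s: s.values[0])
        assert sum(s.weight for s in samples) == pytest.approx(1.0)

    def test_quantiles_monotone(self):
        rng = np.random.default_rng(1)
        samples = make_samples(rng.normal(size=50), rng.normal(size=50))
        out = credible_intervals(samples, lambda s: s.values[0],
                                 quantiles=(0.005, 0.25, 0.5, 0.75, 0.995))
        vals = [out[q] for q in sorted(out)]
        assert vals == sorted(vals)

    def test_needs_two_samples(self):
        with pytest.raises(ParameterError):
            credible_intervals(make_samples([1.0], [0.0]),
                               lambda s: s.values[0])
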