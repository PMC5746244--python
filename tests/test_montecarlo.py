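"""Monte Carlo sampling, summaries, reproducibility and convergence."""

import numpy as np
import pytest

from cpbsim.montecarlo import (
    QalyRateEstimate,
    convergence_trace,
    normal_from_uniform,
    run_simulation,
    sample_draw,
    summarize,
)
from cpbsim.params import (
    DistributionKind,
    ParameterKind,
    ParameterRange,
    SimulationConfig,
)
from cpbsim.synth import collapse_to_midpoints, make_product_chain

U, N = DistributionKind.UNIFORM, DistributionKind.NORMAL_MATCHED


class TestNormalFromUniform:
    @pytest.mark.parametrize(
        "low, high, mean, sd",
        [
            (0.0, 1.0, 0.5, 1 / np.sqrt(12)),  # sd of U(0,1) is 1/sqrt(12)
            (3.0, 3.0, 3.0, 0.0),
            (9.4, 15.6, 12.5, 6.2 / np.sqrt(12)),  # 1.78978...
        ],
    )
    def test_matched_moments(self, low, high, mean, sd):
        m, s = normal_from_uniform(low, high)
        assert m == pytest.approx(mean)
        assert s == pytest.approx(sd)

    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            normal_from_uniform(2.0, 1.0)


class TestSampleDraw:
    def test_point_mass_always_returns_the_point(self):
        rng = np.random.default_rng(0)
        draw = sample_draw([ParameterRange("c", 0.5, 0.5)], U, rng, size=100)
        assert np.all(draw["c"] == 0.5)

    def test_uniform_within_bounds_with_correct_mean(self):
        rng = np.random.default_rng(0)
        r = ParameterRange("eff", 0.35, 0.55)
        v = sample_draw([r], U, rng, size=100_000)["eff"]
        assert v.min() >= 0.35 and v.max() <= 0.55
        se = r.width / np.sqrt(12) / np.sqrt(v.size)
        assert v.mean() == pytest.approx(0.45, abs=3 * se)

    def test_fixed_seed_reproduces_draws_exactly(self):
        ranges = [ParameterRange("a", 0.1, 0.9), ParameterRange("b", 0.2, 0.4)]
        d1 = sample_draw(ranges, U, np.random.default_rng(42), size=1000)
        d2 = sample_draw(ranges, U, np.random.default_rng(42), size=1000)
        for k in d1:
            assert np.array_equal(d1[k], d2[k])

    def test_normal_draws_clamped_to_physical_domain(self):
        rng = np.random.default_rng(1)
        wide = ParameterRange("p", 0.0, 1.0, kind=ParameterKind.PROBABILITY)
        v = sample_draw([wide], N, rng, size=50_000)["p"]
        assert v.min() >= 0.0 and v.max() <= 1.0
        rate = ParameterRange("r", 0.0, 2.0, kind=ParameterKind.RATE_PER_100K)
        v = sample_draw([rate], N, rng, size=50_000)["r"]
        assert v.min() >= 0.0


class TestRunSimulation:
    def test_point_mass_set_gives_constant_sample(self):
        model, ranges, mean, _ = make_product_chain(3, seed=5)
        point = collapse_to_midpoints(ranges)
        sample = run_simulation(model, point, SimulationConfig(n_iterations=1000, seed=0))
        assert sample.shape == (1000,)
        assert np.all(sample == sample[0])
        assert sample[0] == pytest.approx(mean)  # product of midpoints

    def test_single_iteration_equals_deterministic_evaluation(self):
        model, ranges, mean, _ = make_product_chain(2, seed=9)
        point = collapse_to_midpoints(ranges)
        sample = run_simulation(model, point, SimulationConfig(n_iterations=1, seed=3))
        assert sample[0] == pytest.approx(mean)

    def test_seed_gives_bit_identical_samples(self, influenza):
        model, ranges = influenza
        cfg = SimulationConfig(n_iterations=5000, seed=123)
        assert np.array_equal(
            run_simulation(model, ranges, cfg), run_simulation(model, ranges, cfg)
        )

    def test_missing_model_parameter_raises(self, influenza):
        model, ranges = influenza
        with pytest.raises(KeyError, match="adherence"):
            run_simulation(model, [r for r in ranges if r.name != "adherence"],
                           SimulationConfig(n_iterations=10))

    def test_product_chain_mean_matches_closed_form(self):
        # q = a*b with a, b ~ U(0,1): E[q] = 1/4, sd = sqrt(1/9 - 1/16)
        ranges = [ParameterRange("a", 0, 1), ParameterRange("b", 0, 1)]
        from cpbsim.synth import ProductChainModel

        model = ProductChainModel("ab", ("a", "b"))
        sample = run_simulation(
            model, ranges, SimulationConfig(n_iterations=200_000, seed=11)
        )
        sd = np.sqrt(1 / 9 - 1 / 16)
        assert sd == pytest.approx(0.220479, abs=1e-6)
        assert sample.mean() == pytest.approx(0.25, abs=3 * sd / np.sqrt(sample.size))
        assert sample.std(ddof=1) == pytest.approx(sd, rel=0.02)

    def test_sample_extremes_bounded_by_corner_evaluations(self):
        # the product model is monotone in every factor, so the sample lies
        # between the all-low and all-high corner products
        model, ranges, _, _ = make_product_chain(4, seed=2)
        sample = run_simulation(
            model, ranges, SimulationConfig(n_iterations=20_000, seed=8)
        )
        lo = np.prod([r.low for r in ranges])
        hi = np.prod([r.high for r in ranges])
        assert sample.min() >= lo and sample.max() <= hi

    def test_uniform_and_matched_normal_means_agree(self, influenza):
        model, ranges = influenza
        n = 50_000
        su = run_simulation(model, ranges,
                            SimulationConfig(n_iterations=n, seed=21, input_distribution=U))
        sn = run_simulation(model, ranges,
                            SimulationConfig(n_iterations=n, seed=22, input_distribution=N))
        se = np.sqrt(su.var(ddof=1) / n + sn.var(ddof=1) / n)
        assert abs(su.mean() - sn.mean()) < 3 * se


class TestSummarize:
    def test_constant_sample(self):
        est = summarize(np.full(50, 2.5), intervention="const")
        assert (est.mean, est.sd) == (2.5, 0.0)
        assert (est.qi_low, est.qi_high) == (2.5, 2.5)

    def test_linear_interpolation_quantile_rule(self):
        est = summarize(np.arange(1, 1001, dtype=float))
        assert est.qi_low == pytest.approx(25.975)
        assert est.qi_high == pytest.approx(975.025)

    def test_sd_uses_sample_denominator(self):
        x = np.array([1.0, 2.0, 3.0])
        assert summarize(x).sd == pytest.approx(x.std(ddof=1))

    def test_qi_covers_the_nominal_mass(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40_000)
        est = summarize(x)
        inside = np.mean((x >= est.qi_low) & (x <= est.qi_high))
        assert inside == pytest.approx(0.95, abs=0.005)

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            summarize(np.array([]))

    def test_estimate_invariants_enforced(self):
        with pytest.raises(ValueError):
            QalyRateEstimate("x", mean=1.0, sd=-0.1)
        with pytest.raises(ValueError):
            QalyRateEstimate("x", mean=1.0, sd=0.1, qi_low=2.0, qi_high=1.0)


class TestConvergenceTrace:
    def test_final_checkpoint_equals_full_summary(self, influenza):
        model, ranges = influenza
        cfg = SimulationConfig(n_iterations=20_000, seed=4)
        trace = convergence_trace(model, ranges, cfg, [100, 20_000])
        full = summarize(run_simulation(model, ranges, cfg), cfg.quantile_levels,
                         intervention=model.name)
        assert trace[-1] == full

    def test_point_mass_trace_is_constant(self):
        model, ranges, mean, _ = make_product_chain(2, seed=1)
        cfg = SimulationConfig(n_iterations=1000, seed=0)
        trace = convergence_trace(model, collapse_to_midpoints(ranges), cfg,
                                  [10, 100, 1000])
        # sd of a constant sample is zero up to summation roundoff
        assert all(
            t.mean == pytest.approx(mean) and t.sd == pytest.approx(0.0, abs=1e-12)
            for t in trace
        )

    def test_checkpoints_must_increase(self, influenza):
        model, ranges = influenza
        with pytest.raises(ValueError):
            convergence_trace(model, ranges, SimulationConfig(n_iterations=100, seed=0),
                              [50, 50])

    def test_error_shrinks_with_more_iterations(self, influenza):
        # Monte Carlo error scales as 1/sqrt(n): the 10^4-iteration estimate
        # should sit much closer to the full-run mean than the 10^2 one.
        model, ranges = influenza
        closer = 0
        errs_small, errs_big = [], []
        for seed in range(5):
            cfg = SimulationConfig(n_iterations=100_000, seed=seed)
            t100, t10k, tfull = convergence_trace(model, ranges, cfg,
                                                  [100, 10_000, 100_000])
            e_small = abs(t10k.mean - tfull.mean)
            e_big = abs(t100.mean - tfull.mean)
            errs_small.append(e_small)
            errs_big.append(e_big)
            closer += e_small < e_big
        assert closer >= 3
        assert np.median(errs_small) < np.median(errs_big)
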