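"""Single-model ABC-SMC: likelihood approximation, perturbation kernel,
importance weights, tolerance schedule and the full sampler."""

import numpy as np
import pytest
from scipy.stats import kstwobign

from pinabc import (
    ABCConfig,
    KernelConfig,
    ModelId,
    ParameterVector,
    Population,
    PriorSpec,
    UndirectedGraph,
    adaptive_epsilon,
    approximate_likelihood,
    marginal_interval,
    populations_to_table,
    run_abc_smc,
    table_to_populations,
    weighted_quantile,
)
from pinabc.abc_smc import Particle, compute_weight, perturb_parameters


DA_PRIOR = PriorSpec({"delta": (0.0, 1.0), "alpha": (0.0, 1.0)})


def make_population(params_weights, epsilon=1.0, t=1, model=ModelId.DA):
    parts = tuple(
        Particle(model, pv, w, 1, 0.5) for pv, w in params_weights
    )
    return Population(parts, epsilon, t)


class TestApproximateLikelihood:
    def test_infinite_tolerance_accepts_all_repeats(self, rng):
        data = UndirectedGraph(20, frozenset({(0, 1)}))
        cfg = ABCConfig(n_particles=2, n_populations=1, n_repeats=5)
        s = approximate_likelihood(
            ModelId.DA, ParameterVector(delta=0.5, alpha=0.5), data, np.inf, cfg, rng
        )
        assert s == 5

    def test_zero_tolerance_rejects_unmatched_data(self, rng):
        data = UndirectedGraph(20, frozenset({(0, 1), (2, 3), (4, 5)}))
        cfg = ABCConfig(n_particles=2, n_populations=1, n_repeats=5)
        s = approximate_likelihood(
            ModelId.DA, ParameterVector(delta=0.0, alpha=1.0), data, 0.0, cfg, rng
        )
        assert s == 0

    def test_deterministic_degenerate_model_matches_exactly(self, rng):
        # DA with delta=1, alpha=0 always yields one edge plus isolated
        # nodes, so the spectrum coincides with data from the same model
        pv = ParameterVector(delta=1.0, alpha=0.0)
        data = UndirectedGraph(30, frozenset({(4, 9)}))
        cfg = ABCConfig(n_particles=2, n_populations=1, n_repeats=4)
        s = approximate_likelihood(ModelId.DA, pv, data, 0.0, cfg, rng)
        assert s == 4


class TestPerturbation:
    def test_tiny_bandwidth_is_identity_limit(self, rng):
        pv = ParameterVector(delta=0.5, alpha=0.5)
        out = perturb_parameters(pv, {"delta": 1e-15, "alpha": 1e-15}, DA_PRIOR, rng)
        assert out.delta == pytest.approx(0.5, abs=1e-12)
        assert out.alpha == pytest.approx(0.5, abs=1e-12)

    def test_gaussian_moments(self, rng):
        pv = ParameterVector(delta=0.5, alpha=0.5)
        bw = {"delta": 0.05, "alpha": 0.1}
        draws = np.array(
            [perturb_parameters(pv, bw, DA_PRIOR, rng).delta for _ in range(100_000)]
        )
        assert draws.mean() == pytest.approx(0.5, abs=3 * 0.05 / np.sqrt(100_000))
        assert draws.std() == pytest.approx(0.05, rel=0.02)

    def test_proposals_stay_inside_prior(self, rng):
        pv = ParameterVector(delta=0.99, alpha=0.01)
        bw = {"delta": 0.5, "alpha": 0.5}
        for _ in range(500):
            out = perturb_parameters(pv, bw, DA_PRIOR, rng)
            assert out is None or DA_PRIOR.contains(out)


class TestComputeWeight:
    def test_first_generation_weight_is_s(self):
        # Algorithm's t=1 branch assigns w <- s directly; exercised through
        # the sampler in test_first_population_weights_are_uniform below;
        # here check the general formula is positive and finite
        prev = make_population(
            [(ParameterVector(delta=0.5, alpha=0.5), 1.0)]
        )
        w = compute_weight(
            ParameterVector(delta=0.5, alpha=0.5), 3, prev,
            {"delta": 0.1, "alpha": 0.1}, DA_PRIOR,
        )
        assert w > 0

    def test_equal_proposals_get_equal_weights(self):
        prev = make_population(
            [
                (ParameterVector(delta=0.4, alpha=0.5), 0.5),
                (ParameterVector(delta=0.6, alpha=0.5), 0.5),
            ]
        )
        bw = {"delta": 0.1, "alpha": 0.1}
        w1 = compute_weight(ParameterVector(delta=0.45, alpha=0.5), 2, prev, bw, DA_PRIOR)
        w2 = compute_weight(ParameterVector(delta=0.55, alpha=0.5), 2, prev, bw, DA_PRIOR)
        assert w1 == pytest.approx(w2)

    def test_weight_scales_linearly_in_s(self):
        prev = make_population([(ParameterVector(delta=0.5, alpha=0.5), 1.0)])
        bw = {"delta": 0.1, "alpha": 0.1}
        pv = ParameterVector(delta=0.52, alpha=0.5)
        assert compute_weight(pv, 4, prev, bw, DA_PRIOR) == pytest.approx(
            4 * compute_weight(pv, 1, prev, bw, DA_PRIOR)
        )

    def test_rejected_particles_are_never_weighted(self):
        prev = make_population([(ParameterVector(delta=0.5, alpha=0.5), 1.0)])
        with pytest.raises(ValueError, match="s > 0"):
            compute_weight(
                ParameterVector(delta=0.5, alpha=0.5), 0, prev,
                {"delta": 0.1, "alpha": 0.1}, DA_PRIOR,
            )

    def test_empty_previous_population_rejected(self):
        empty = Population((), 1.0, 1)
        with pytest.raises(ValueError, match="empty"):
            compute_weight(
                ParameterVector(delta=0.5, alpha=0.5), 1, empty,
                {"delta": 0.1, "alpha": 0.1}, DA_PRIOR,
            )


class TestAdaptiveEpsilon:
    def _pop_with_distances(self, dists, epsilon=10.0):
        parts = tuple(
            Particle(ModelId.DA, ParameterVector(delta=0.5, alpha=0.5), 1.0, 1, d)
            for d in dists
        )
        return Population(parts, epsilon, 1)

    def test_constant_distances(self):
        assert adaptive_epsilon(self._pop_with_distances([3.0] * 5)) == 3.0

    def test_median_uses_midpoint_convention(self):
        assert adaptive_epsilon(self._pop_with_distances([1, 2, 3, 4])) == 2.5

    def test_never_exceeds_previous_epsilon(self, rng):
        for _ in range(100):
            dists = rng.uniform(0, 20, size=rng.integers(2, 30))
            eps_prev = float(rng.uniform(1, 15))
            pop = self._pop_with_distances(dists, epsilon=eps_prev)
            assert adaptive_epsilon(pop, float(rng.uniform(0.1, 0.9))) < eps_prev

    def test_invalid_quantile_rejected(self):
        with pytest.raises(ValueError, match="quantile"):
            adaptive_epsilon(self._pop_with_distances([1.0]), 1.5)


@pytest.fixture(scope="module")
def small_run():
    data = UndirectedGraph(30, frozenset({(0, 1), (1, 2), (2, 3)}))
    cfg = ABCConfig(n_particles=40, n_populations=3)
    return run_abc_smc(data, ModelId.DA, DA_PRIOR, cfg, np.random.default_rng(17))


class TestRunAbcSmc:
    def test_first_population_weights_are_uniform(self):
        # T=1 with an infinite first tolerance: an iid prior sample, every
        # proposal accepted with s = R, so weights normalize to 1/N
        data = UndirectedGraph(20, frozenset({(0, 1)}))
        cfg = ABCConfig(n_particles=25, n_populations=1, n_repeats=2)
        (pop,) = run_abc_smc(data, ModelId.DA, DA_PRIOR, cfg, np.random.default_rng(2))
        np.testing.assert_allclose(pop.weights(), 1 / 25)
        assert all(p.accepted_count == 2 for p in pop.particles)

    def test_weights_normalized_every_generation(self, small_run):
        for pop in small_run:
            assert abs(pop.weights().sum() - 1.0) < 1e-12

    def test_tolerance_strictly_decreasing(self, small_run):
        eps = [pop.epsilon for pop in small_run]
        assert all(a > b for a, b in zip(eps, eps[1:]))

    def test_particles_stay_in_prior_support(self, small_run):
        for pop in small_run:
            for part in pop.particles:
                assert DA_PRIOR.contains(part.params)

    def test_bit_identical_trace_under_fixed_seed(self):
        data = UndirectedGraph(25, frozenset({(0, 1), (2, 3)}))
        cfg = ABCConfig(n_particles=20, n_populations=2)
        t1 = populations_to_table(
            run_abc_smc(data, ModelId.DA, DA_PRIOR, cfg, np.random.default_rng(5))
        )
        t2 = populations_to_table(
            run_abc_smc(data, ModelId.DA, DA_PRIOR, cfg, np.random.default_rng(5))
        )
        assert t1.equals(t2)

    def test_stalled_acceptance_aborts_with_diagnostic(self):
        data = UndirectedGraph(20, frozenset({(0, 1), (2, 3), (4, 5)}))
        cfg = ABCConfig(
            n_particles=5, n_populations=1,
            epsilon_schedule=(1e-9,), max_attempts_factor=3,
        )
        with pytest.raises(RuntimeError, match="tolerance"):
            run_abc_smc(data, ModelId.DA, DA_PRIOR, cfg, np.random.default_rng(0))

    def test_huge_tolerance_marginals_match_the_prior(self):
        # with epsilon effectively infinite and R=1 the target at every
        # generation is the prior itself; check the weighted final marginal
        # against U(0,1) with a weighted KS statistic at alpha=0.01
        data = UndirectedGraph(12, frozenset({(0, 1), (1, 2)}))
        cfg = ABCConfig(
            n_particles=1000, n_populations=2,
            epsilon_schedule=(1e9, 1e8),
        )
        pops = run_abc_smc(data, ModelId.DA, DA_PRIOR, cfg, np.random.default_rng(23))
        final = pops[-1]
        for name in ("delta", "alpha"):
            values = np.array([p.params.get(name) for p in final.particles])
            w = final.weights()
            order = np.argsort(values)
            ecdf_jumps = np.cumsum(w[order])
            d_stat = np.max(np.abs(ecdf_jumps - values[order]))
            ess = 1.0 / np.sum(w**2)
            crit = kstwobign.ppf(0.99) / np.sqrt(ess)
            assert d_stat < crit, f"{name}: D={d_stat:.4f} crit={crit:.4f}"

    def test_dac_recovers_divergence_and_heterodimer_rates(self):
        # self-consistency: DAC data at known parameters; 90% credible
        # intervals of the final population should cover the truth
        data_rng = np.random.default_rng(2012)
        from pinabc import grow_dac

        data = grow_dac(150, 0.35, 0.3, data_rng)
        cfg = ABCConfig(n_particles=80, n_populations=4)
        pops = run_abc_smc(data, ModelId.DAC, DA_PRIOR, cfg, np.random.default_rng(1))
        lo_d, hi_d = marginal_interval(pops[-1], "delta", 0.9)
        lo_a, hi_a = marginal_interval(pops[-1], "alpha", 0.9)
        assert lo_d <= 0.35 <= hi_d
        assert lo_a <= 0.3 <= hi_a


class TestTraceTable:
    def test_round_trip(self):
        data = UndirectedGraph(20, frozenset({(0, 1)}))
        cfg = ABCConfig(n_particles=10, n_populations=2)
        pops = run_abc_smc(data, ModelId.DA, DA_PRIOR, cfg, np.random.default_rng(9))
        back = table_to_populations(populations_to_table(pops))
        assert len(back) == len(pops)
        for a, b in zip(pops, back):
            assert a.epsilon == b.epsilon
            for pa, pb in zip(a.particles, b.particles):
                assert pa.model is pb.model
                assert pa.weight == pb.weight
                assert pa.params == pb.params


class TestConfigValidation:
    def test_non_decreasing_schedule_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            ABCConfig(n_populations=3, epsilon_schedule=(5.0, 5.0, 4.0))

    def test_schedule_length_must_match(self):
        with pytest.raises(ValueError, match="entries"):
            ABCConfig(n_populations=2, epsilon_schedule=(5.0,))

    def test_kernel_bandwidths_must_be_positive(self):
        with pytest.raises(ValueError, match="bandwidth"):
            KernelConfig(bandwidths={"delta": 0.0})


def test_weighted_quantile_matches_plain_quantile_for_uniform_weights():
    values = np.array([4.0, 1.0, 3.0, 2.0, 5.0])
    w = np.ones(5)
    assert weighted_quantile(values, w, 0.5) == 3.0
    assert weighted_quantile(values, w, 0.05) == 1.0
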