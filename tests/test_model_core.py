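"""Unit tests for the within-population dynamics."""

import math

import numpy as np
import pytest

from culturesim import (
    ConfigurationError,
    MetaPopulation,
    PopulationState,
    SimParams,
    ToolRegistry,
    apply_loss,
    draw_selection_coefficient,
    innovate,
    run,
    step,
)


def clamped_exponential_mean(beta: float) -> float:
    """E[min(Exp(beta), 1)] = beta * (1 - exp(-1/beta))."""
    return beta * (1.0 - math.exp(-1.0 / beta))


class TestSelectionCoefficient:
    def test_mean_matches_beta(self, default_params, rng):
        """Sample mean of 1e6 draws is within 3 SE of E(s) = beta."""
        n = 1_000_000
        draws = np.array(
            [draw_selection_coefficient(default_params, rng) for _ in range(n)]
        )
        se = draws.std(ddof=1) / math.sqrt(n)
        assert abs(draws.mean() - default_params.beta) < 3 * se

    def test_draws_in_unit_interval(self, default_params, rng):
        draws = [draw_selection_coefficient(default_params, rng) for _ in range(2000)]
        assert all(0.0 < s <= 1.0 for s in draws)

    def test_clamp_tail_fraction(self, default_params, rng):
        """The raw exponential exceeds 1 with probability exp(-1/beta)."""
        n = 1_000_000
        clamped = sum(
            draw_selection_coefficient(default_params, rng) == 1.0 for _ in range(n)
        )
        p = math.exp(-1.0 / default_params.beta)  # exp(-10) ~ 4.54e-5
        se = math.sqrt(p * (1 - p) / n)
        assert abs(clamped / n - p) < 3 * se

    def test_invalid_beta_rejected(self):
        with pytest.raises(ConfigurationError):
            SimParams(beta=0.0)


class TestInnovate:
    def test_zero_rate_is_inert(self, rng):
        params = SimParams(p_inv=0.0)
        pop = PopulationState(index=0, n=200, repertoire={1, 2})
        registry = ToolRegistry()
        assert innovate(pop, params, registry, 0, rng) == []
        assert pop.repertoire == {1, 2}

    def test_establishment_rate_matches_analytic(self, rng):
        """Established tools accrue at rate N * P_inv * E[min(s, 1)]."""
        params = SimParams(p_inv=0.01, t_max=0)
        pop = PopulationState(index=0, n=200)
        registry = ToolRegistry()
        steps = 100_000
        for t in range(steps):
            innovate(pop, params, registry, t, rng)
        expected_rate = 200 * params.p_inv * clamped_exponential_mean(params.beta)
        total = len(registry)
        # per-step establishment count is a compound binomial; bound its SD
        # by sqrt(attempt rate * E[s]) per step (Poisson-like)
        sd = math.sqrt(steps * 200 * params.p_inv * params.beta)
        assert abs(total - steps * expected_rate) < 4 * sd

    def test_bookkeeping(self, default_params, rng):
        """Established ids land in the repertoire and resolve in the registry."""
        params = default_params.replace(p_inv=1.0, beta=5.0, t_max=0)  # s ~ 1 mostly
        pop = PopulationState(index=3, n=50)
        registry = ToolRegistry()
        added = innovate(pop, params, registry, t=7, rng=rng)
        assert added
        assert set(added) <= pop.repertoire
        for tool_id in added:
            tool = registry.get(tool_id)
            assert tool.t_invented == 7
            assert tool.origin_pop == 3
            assert 0 < tool.s <= 1

    def test_failed_inventions_not_registered(self, rng):
        """Tools that fail establishment leave no trace."""
        params = SimParams(p_inv=1.0, beta=1e-12, t_max=0)  # s ~ 0: all fail
        pop = PopulationState(index=0, n=500)
        registry = ToolRegistry()
        added = innovate(pop, params, registry, 0, rng)
        assert added == []
        assert len(registry) == 0
        assert pop.repertoire == set()


class TestApplyLoss:
    def test_zero_rate_never_removes(self, rng):
        params = SimParams(p_loss=0.0)
        pop = PopulationState(index=0, n=10, repertoire=set(range(100)))
        for _ in range(1000):
            assert apply_loss(pop, params, rng) == []
        assert len(pop.repertoire) == 100

    def test_loss_frequency_matches_scaled_model(self, default_params, rng):
        """Per-tool loss frequency over a frozen repertoire is p_loss/n.

        A repertoire of 40 tools in a population of 200 loses on average
        40 * (0.1/200) = 0.02 tools per step.
        """
        pop = PopulationState(index=0, n=200, repertoire=set(range(40)))
        steps = 200_000
        removed_total = 0
        for _ in range(steps):
            removed = apply_loss(pop, default_params, rng)
            removed_total += len(removed)
            pop.repertoire.update(removed)  # freeze the repertoire
        p = default_params.p_loss / 200
        trials = steps * 40
        se = math.sqrt(trials * p * (1 - p))
        assert abs(removed_total - trials * p) < 3 * se

    def test_loss_prob_halves_when_size_doubles(self, default_params):
        p_n = default_params.per_tool_loss_prob(200)
        p_2n = default_params.per_tool_loss_prob(400)
        assert p_2n == pytest.approx(p_n / 2)

    def test_independent_model_loss_prob(self):
        params = SimParams(loss_model="independent_individuals", p_ind=0.5)
        assert params.per_tool_loss_prob(10) == pytest.approx(9.765625e-4)


class TestStepAndRun:
    def test_null_dynamics_leave_state_unchanged(self, rng):
        params = SimParams(p_inv=0.0, p_loss=0.0, p_mig=0.0)
        meta = MetaPopulation.two_populations(10, 20)
        meta.populations[0].repertoire = {1, 2}
        registry = ToolRegistry()
        for tid in range(3):
            registry.register(0.5, 0, 0)
        before = [set(p.repertoire) for p in meta.populations]
        step(meta, params, registry, 0, rng)
        assert [p.repertoire for p in meta.populations] == before

    def test_same_seed_is_bit_identical(self):
        params = SimParams(
            t_max=3000, window_start=1000, window_end=3000, p_mig=1e-4, seed=99
        )
        runs = []
        for _ in range(2):
            meta = MetaPopulation.two_populations(50, 100)
            runs.append(run(meta, params))
        a, b = runs
        assert np.array_equal(a.sizes, b.sizes)
        assert np.array_equal(a.unique_counts, b.unique_counts)
        assert a.final_repertoires == b.final_repertoires
        assert len(a.registry) == len(b.registry)

    def test_t_max_zero_returns_empty_trajectory(self):
        params = SimParams(t_max=0)
        traj = run(MetaPopulation.isolated(100), params)
        assert traj.sizes.shape == (0, 1)
        assert traj.sample_times.size == 0
        assert traj.final_repertoires == [set()]

    def test_set_semantics_and_registry_resolution(self):
        """After a run every repertoire id resolves in the registry."""
        params = SimParams(
            t_max=4000, window_start=1000, window_end=4000, p_mig=1e-3, seed=5
        )
        traj = run(MetaPopulation.two_populations(50, 100), params)
        for rep in traj.final_repertoires:
            for tool_id in rep:
                assert tool_id in traj.registry
        # census sizes untouched by migration
        assert traj.pop_sizes == [50, 100]


@pytest.mark.parametrize(
    "kwargs",
    [
        {"p_inv": -0.1},
        {"p_inv": 1.5},
        {"p_loss": 2.0},
        {"f": -0.5},
        {"beta": -1.0},
        {"payload_mode": "bogus"},
        {"payload_k": -1},
        {"loss_model": "bogus"},
        {"loss_model": "independent_individuals"},  # missing p_ind
        {"t_max": -5},
        {"window_start": 500, "window_end": 100},
        {"window_end": 300_000},
        {"unique_sample_every": 0},
        {"record_every": 0},
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        SimParams(**kwargs)


def test_population_size_must_be_positive():
    with pytest.raises(ConfigurationError):
        PopulationState(index=0, n=0)
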