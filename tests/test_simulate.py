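"""Death-birth simulation machinery: payoffs, steps, estimators, oracle."""

import numpy as np
import pytest

from edgegames import (
    DegreeProfile,
    SimConfig,
    SimState,
    death_birth_step,
    estimate_delta_p,
    estimate_fixation,
    evaluate_payoffs,
    exact_fixation,
    generate_typed_graph,
    neighborhood_config,
    pairwise_tensor,
)
from edgegames.payoffs import dol_tensor


class TestEvaluatePayoffs:
    def test_uniform_population_payoffs(self, small_typed_graph):
        g = small_typed_graph
        t = dol_tensor(g.profile, 2.0, 1.0)
        all_A = np.ones(g.N, dtype=int)
        pays = evaluate_payoffs(g, all_A, t)
        assert pays == pytest.approx(np.full(g.N, t.a[g.profile.g]))

    def test_focal_defector_reads_its_configuration(self, small_typed_graph):
        g = small_typed_graph
        t = dol_tensor(g.profile, 2.0, 1.0)
        # make node 0 a B-player whose type-1 neighbors are A,A and type-2 B
        strategies = np.zeros(g.N, dtype=int)
        for v, ty in g.neighbors(0):
            if ty == 1:
                strategies[v] = 1
        assert neighborhood_config(g, 0, strategies) == (2, 0)
        assert evaluate_payoffs(g, strategies, t)[0] == t.b[(2, 0)]

    def test_incremental_updates_match_recount(self, small_typed_graph, rng):
        """One strategy flip changes payoffs exactly as a full recount."""
        from edgegames.simulate import _graph_tensor_arrays, _init_configs

        g = small_typed_graph
        t = dol_tensor(g.profile, 2.0, 1.0)
        nbr, typ, strides, atab, btab = _graph_tensor_arrays(g, t)
        strat = rng.integers(0, 2, g.N).astype(np.int8)
        cfg = np.empty(g.N, dtype=np.int64)
        _init_configs(nbr, typ, strides, strat, cfg)
        flip = 3
        strat[flip] ^= 1
        delta = 1 if strat[flip] else -1
        for j in range(g.profile.k):
            cfg[nbr[flip, j]] += delta * strides[typ[flip, j]]
        fresh = np.empty(g.N, dtype=np.int64)
        _init_configs(nbr, typ, strides, strat, fresh)
        assert np.array_equal(cfg, fresh)


class TestDeathBirthStep:
    def test_single_node_updated(self, k4_graph, donation_tensor_k3, rng):
        state = SimState(np.array([1, 0, 0, 1]))
        before = state.strategies.copy()
        i = death_birth_step(k4_graph, state, donation_tensor_k3, 0.01, rng)
        changed = np.nonzero(before != state.strategies)[0]
        assert len(changed) <= 1
        if len(changed):
            assert changed[0] == i

    def test_adoption_frequencies_match_fitness_shares(
        self, k4_graph, donation_tensor_k3
    ):
        """Empirical flip-to-A rate equals mean_i F_A(i) / F_tot(i)."""
        base = np.array([1, 1, 0, 0])
        omega = 0.1  # strong enough to detect the payoff bias
        pays = evaluate_payoffs(k4_graph, base, donation_tensor_k3)
        fit = 1 - omega + omega * pays
        expected = np.mean(
            [
                sum(fit[u] for u, _ in k4_graph.neighbors(i) if base[u] == 1)
                / sum(fit[u] for u, _ in k4_graph.neighbors(i))
                for i in range(4)
            ]
        )
        rng = np.random.default_rng(77)
        reps = 20_000
        hits = 0
        for _ in range(reps):
            state = SimState(base.copy())
            i = death_birth_step(
                k4_graph, state, donation_tensor_k3, omega, rng
            )
            hits += int(state.strategies[i] == 1)
        phat = hits / reps
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(phat - expected) < 3 * se

    def test_neutral_step_ignores_payoffs(self, k4_graph, donation_tensor_k3):
        """omega = 0: adoption is a uniform copy of a random neighbor."""
        rng = np.random.default_rng(5)
        base = np.array([1, 0, 0, 0])
        hits = 0
        reps = 10_000
        for _ in range(reps):
            state = SimState(base.copy())
            i = death_birth_step(k4_graph, state, donation_tensor_k3, 0.0, rng)
            hits += int(state.strategies[i] == 1)
        # each of 4 focal choices sees 1 or 0 A's among its 3 neighbors:
        # P = (3 * 1/3 + 0) / 4
        se = np.sqrt(0.25 * 0.75 / reps)
        assert abs(hits / reps - 0.25) < 3 * se


class TestFixationEstimation:
    def test_neutral_drift_gives_one_over_N(self, small_typed_graph):
        g = small_typed_graph
        t = dol_tensor(g.profile, 2.0, 1.0)
        est = estimate_fixation(g, t, SimConfig(omega=0.0, runs=20_000, seed=1))
        for rho, se in ((est.rho_A, est.se_A), (est.rho_B, est.se_B)):
            assert abs(rho - 1 / g.N) < 3 * se

    def test_reproducible(self, k4_graph, donation_tensor_k3):
        cfg = SimConfig(omega=0.01, runs=2000, seed=9)
        a = estimate_fixation(k4_graph, donation_tensor_k3, cfg)
        b = estimate_fixation(k4_graph, donation_tensor_k3, cfg)
        assert a == b

    def test_fitness_positivity_guard(self, k4_graph):
        t = pairwise_tensor([(-80.0, -80.0, 0.0, 0.0)], DegreeProfile((3,)))
        with pytest.raises(ValueError, match="fitness positivity"):
            estimate_fixation(k4_graph, t, SimConfig(omega=0.01, runs=10))


class TestDriftEstimation:
    def test_neutral_drift_is_zero(self, small_typed_graph):
        g = small_typed_graph
        t = dol_tensor(g.profile, 2.0, 1.0)
        out = estimate_delta_p(
            g, t, SimConfig(omega=0.0, seed=3), [0.3, 0.6], reps=2000
        )
        for d in out:
            assert abs(d.delta_p) < 3 * d.se

    def test_records_realized_starting_frequency(self, small_typed_graph):
        g = small_typed_graph
        t = dol_tensor(g.profile, 2.0, 1.0)
        (d,) = estimate_delta_p(
            g, t, SimConfig(omega=0.0, seed=3), [0.5], reps=500
        )
        assert 0.2 < d.p_before < 0.8 and d.reps == 500


class TestExactOracle:
    def test_neutral_fixation_exactly_one_over_N(
        self, k4_graph, small_typed_graph, donation_tensor_k3
    ):
        rA, rB = exact_fixation(k4_graph, donation_tensor_k3, 0.0)
        assert rA == pytest.approx(0.25, abs=1e-10)
        assert rB == pytest.approx(0.25, abs=1e-10)
        t = dol_tensor(small_typed_graph.profile, 2.0, 1.0)
        rA, rB = exact_fixation(small_typed_graph, t, 0.0)
        assert rA == pytest.approx(1 / 8, abs=1e-10)

    def test_strategy_relabeling_symmetry(self, k4_graph, donation_tensor_k3):
        """Swapping strategy labels (and the payoff tables accordingly)
        exchanges the two fixation probabilities exactly."""
        rA, rB = exact_fixation(k4_graph, donation_tensor_k3, 0.02)
        swapped = pairwise_tensor([(0.0, 2.0, -1.0, 1.0)], DegreeProfile((3,)))
        sA, sB = exact_fixation(k4_graph, swapped, 0.02)
        assert sB == pytest.approx(rA, abs=1e-10)
        assert sA == pytest.approx(rB, abs=1e-10)

    def test_weight_scaling_preserves_selection_direction(self, small_typed_graph):
        g = small_typed_graph
        t = dol_tensor(g.profile, 3.0, 1.0, accumulative=False)
        r1A, r1B = exact_fixation(g, t, 0.01)
        r2A, r2B = exact_fixation(g, t.scaled(2.0), 0.01)
        assert np.sign(r1A - r1B) == np.sign(r2A - r2B)
        assert abs(r2A - r2B) > abs(r1A - r1B)  # stronger ties amplify

    def test_size_limit(self):
        g = generate_typed_graph(14, DegreeProfile((2, 1)), seed=0)
        with pytest.raises(ValueError, match="N <= 12"):
            exact_fixation(g, dol_tensor(g.profile, 2.0, 1.0), 0.01)

    def test_monte_carlo_agrees_with_oracle(self, k4_graph, donation_tensor_k3):
        rA, rB = exact_fixation(k4_graph, donation_tensor_k3, 0.02)
        est = estimate_fixation(
            k4_graph, donation_tensor_k3, SimConfig(omega=0.02, runs=20_000, seed=17)
        )
        assert abs(est.rho_A - rA) < 3 * est.se_A
        assert abs(est.rho_B - rB) < 3 * est.se_B
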