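"""Chebyshev map oracles, whale moves, optimizer loop, feature selection."""

import numpy as np
import pytest

from cxrtriad.chwo import (
    ChwoConfig,
    SelectionMask,
    chebyshev_step,
    chwo_minimize,
    chwo_step,
    init_population,
    knn_cv_error,
    select_features,
    whale_move,
    woa_minimize,
)


class ScriptedRNG:
    """Replays preset draws so branch arithmetic can be checked by hand."""

    def __init__(self, randoms=(), uniforms=(), integers=()):
        self._randoms = list(randoms)
        self._uniforms = list(uniforms)
        self._integers = list(integers)

    def random(self):
        return self._randoms.pop(0)

    def uniform(self, lo, hi):
        return self._uniforms.pop(0)

    def integers(self, lo, hi):
        return self._integers.pop(0)


def sphere(x):
    return float(np.sum(x**2))


class TestChebyshevStep:
    def test_fixed_point_at_one(self):
        for X in (2.0, 3.0, 7.5):
            assert chebyshev_step(1.0, X) == pytest.approx(1.0)

    def test_endpoint_minus_one(self):
        assert chebyshev_step(-1.0, 2.0) == pytest.approx(1.0)  # cos(2*pi)

    def test_closed_form_single_step(self):
        assert chebyshev_step(np.cos(0.3), 4.0) == pytest.approx(np.cos(1.2), abs=1e-12)

    def test_stays_in_unit_interval(self, rng):
        q = rng.uniform(-1, 1, size=1000)
        out = chebyshev_step(q, 4.0)
        assert np.all(np.abs(out) <= 1.0)

    def test_iterated_map_equals_cos_of_power(self, rng):
        """n Chebyshev steps from cos(theta) equal cos(X^n * theta).

        The map is chaotic: round-off grows like X^n (Lyapunov exponent
        ln X), so the comparison is only meaningful while X^n stays below
        the double-precision horizon; draws are restricted accordingly.
        """
        for _ in range(50):
            theta = rng.uniform(0, np.pi)
            X = int(rng.integers(2, 6))
            n = min(int(rng.integers(1, 10)), int(np.log(2**19) / np.log(X)))
            q = np.cos(theta)
            for _ in range(n):
                q = chebyshev_step(q, X)
            assert q == pytest.approx(np.cos(X**n * theta), abs=1e-9)

    def test_domain_violation_rejected(self):
        with pytest.raises(ValueError):
            chebyshev_step(1.5, 3.0)


class TestWhaleMove:
    def test_encircle_at_best_with_zero_m_coefficient(self):
        """g=0.5, m=1 gives M=0, R=1; sitting on the prey stays on the prey."""
        pos = best = np.array([0.5])
        rng = ScriptedRNG(randoms=[0.5, 0.9])  # g=0.5, branch draw -> encircle
        out, spiral = whale_move(pos, best, m=1.0, rng=rng)
        assert not spiral
        assert out == pytest.approx([0.5])

    def test_spiral_at_best_is_fixed_for_any_q(self):
        pos = best = np.array([0.2, -0.7])
        rng = ScriptedRNG(randoms=[0.3, 0.1], uniforms=[0.83])  # branch draw -> spiral
        out, spiral = whale_move(pos, best, m=1.0, rng=rng)
        assert spiral
        assert np.allclose(out, best)

    def test_spiral_arithmetic_frozen_case(self):
        """Q*=0.5, Q=0, k=1, q=-0.5: 0.5 e^{-1/2} cos(-pi) + 0.5 = 0.196735."""
        rng = ScriptedRNG(randoms=[0.3, 0.1], uniforms=[-0.5])
        out, _ = whale_move(np.array([0.0]), np.array([0.5]), m=1.0, rng=rng, spiral_k=1.0)
        assert out[0] == pytest.approx(0.196735, abs=1e-6)

    def test_blend_composition_frozen_case(self):
        """Chaos 0 -> chebyshev 1 -> identity map on [-1,1]; 0.5/0.5 blend."""
        chaotic = chebyshev_step(0.0, 4.0)
        assert chaotic == pytest.approx(1.0)
        blended = 0.5 * chaotic + 0.5 * 0.196735
        assert blended == pytest.approx(0.598368, abs=1e-6)

    def test_m_domain_checked(self):
        with pytest.raises(ValueError):
            whale_move(np.zeros(2), np.zeros(2), m=2.5, rng=ScriptedRNG())


class TestOptimizerLoop:
    def test_constant_objective_keeps_constant_best(self):
        _, best, history = chwo_minimize(lambda x: 4.2, 3, ChwoConfig(pop_size=5, max_iters=20, seed=0))
        assert best == 4.2
        assert all(h == 4.2 for h in history)

    def test_best_fitness_is_monotone_nonincreasing(self):
        _, _, history = chwo_minimize(sphere, 4, ChwoConfig(pop_size=8, max_iters=100, seed=2))
        assert all(b <= a for a, b in zip(history, history[1:]))

    def test_positions_respect_bounds(self):
        cfg = ChwoConfig(pop_size=6, max_iters=30, seed=1, bounds=(0.25, 0.75))
        rng = np.random.default_rng(cfg.seed)
        popn = init_population(sphere, 3, cfg, rng)
        for _ in range(cfg.max_iters):
            chwo_step(popn, sphere, cfg, rng)
            assert np.all(popn.positions >= 0.25) and np.all(popn.positions <= 0.75)
            assert np.all(np.abs(popn.chaos_states) <= 1.0)

    def test_sphere_reaches_tolerance(self):
        _, best, _ = chwo_minimize(sphere, 5, ChwoConfig(pop_size=20, max_iters=100, seed=0))
        assert best <= 1e-2

    def test_1d_quadratic_localizes_optimum(self):
        pos, _, _ = chwo_minimize(lambda x: float((x[0] - 0.5) ** 2), 1,
                                  ChwoConfig(pop_size=10, max_iters=200, seed=0))
        assert abs(pos[0] - 0.5) <= 1e-3

    def test_degenerate_box_collapses_to_bound(self):
        eps = 1e-12
        pos, _, _ = chwo_minimize(sphere, 1, ChwoConfig(pop_size=5, max_iters=10, seed=0,
                                                        bounds=(0.3, 0.3 + eps)))
        assert pos[0] == pytest.approx(0.3, abs=1e-9)

    def test_zero_blend_reduces_to_vanilla_woa_bitwise(self):
        cfg = ChwoConfig(pop_size=10, max_iters=50, seed=3, blend_weight=0.0)
        a = chwo_minimize(sphere, 4, cfg)
        b = woa_minimize(sphere, 4, ChwoConfig(pop_size=10, max_iters=50, seed=3))
        assert np.array_equal(a[0], b[0])
        assert a[1] == b[1] and a[2] == b[2]

    def test_fitness_target_stops_early(self):
        _, _, history = chwo_minimize(sphere, 3, ChwoConfig(pop_size=10, max_iters=500, seed=0),
                                      fitness_target=1e-3)
        assert len(history) < 500

    def test_nonfinite_objective_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            chwo_minimize(lambda x: float("nan"), 2, ChwoConfig(pop_size=4, max_iters=5, seed=0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ChwoConfig(pop_size=1)
        with pytest.raises(ValueError):
            ChwoConfig(chaos_X=1.0)
        with pytest.raises(ValueError):
            ChwoConfig(blend_weight=1.5)


class TestFeatureSelection:
    def test_single_predictive_feature_is_forced(self, rng):
        F = rng.standard_normal((40, 1))
        y = (F[:, 0] > 0).astype(int)
        mask = select_features(F, y, ChwoConfig(pop_size=5, max_iters=5, seed=0))
        assert tuple(mask.mask) == (1,)

    def test_informative_pair_recovered(self, rng):
        hits = 0
        for seed in range(2):
            gen = np.random.default_rng(100 + seed)
            F = gen.standard_normal((120, 20))
            y = (F[:, 0] + F[:, 1] > 0).astype(int)
            mask = select_features(F, y, ChwoConfig(pop_size=20, max_iters=30, seed=seed))
            hits += {0, 1} <= set(mask.indices().tolist())
        assert hits == 2

    def test_informative_pair_minimizes_size_two_fitness(self):
        """Exhaustive oracle: among all size-2 masks, (f1, f2) scores best."""
        gen = np.random.default_rng(42)
        F = gen.standard_normal((120, 8))
        y = (F[:, 0] + F[:, 1] > 0).astype(int)
        errors = {
            (i, j): knn_cv_error(F, y, np.array([i, j]), seed=0)
            for i in range(8) for j in range(i + 1, 8)
        }
        assert min(errors, key=errors.get) == (0, 1)

    def test_pure_noise_keeps_selection_sparse_and_near_chance(self, rng):
        """On label-free noise the mask stays sparse and does not transfer.

        The in-sample CV error of the *selected* subset is biased low by the
        search itself, so chance-level behavior is assessed on an independent
        replicate of the null distribution (permutation-style oracle).
        """
        from sklearn.neighbors import KNeighborsClassifier

        F = rng.standard_normal((60, 10))
        y = rng.integers(0, 2, 60)
        mask = select_features(F, y, ChwoConfig(pop_size=10, max_iters=15, seed=0))
        assert mask.selected_count / 10 < 0.5
        F2 = rng.standard_normal((60, 10))
        y2 = rng.integers(0, 2, 60)
        knn = KNeighborsClassifier(1).fit(F[:, mask.indices()], y)
        err = 1.0 - knn.score(F2[:, mask.indices()], y2)
        chance = 1.0 - max(np.mean(y2), 1 - np.mean(y2))
        assert abs(err - chance) <= 3 * np.sqrt(0.25 / 60)

    def test_single_class_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            select_features(rng.standard_normal((30, 4)), np.zeros(30, dtype=int))

    def test_mask_invariants(self):
        mask = SelectionMask(np.array([1, 0, 1, 1]))
        assert mask.selected_count == 3
        assert list(mask.indices()) == [0, 2, 3]
        with pytest.raises(ValueError):
            SelectionMask(np.array([0, 2]))
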