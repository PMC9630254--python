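"""Weight grid enumeration, fusion algebra and grid-search guarantees."""

from itertools import product

import numpy as np
import pytest

from emseg.ensemble import (EnsembleModel, EnsembleWeights,
                            enumerate_weight_grid, evaluate_weights,
                            grid_search_weights, weighted_average_predict_maps)
from emseg.synthetic import simulate_predictor


class _MapMember:
    """Test double whose prediction is a fixed probability map."""

    def __init__(self, prob_map, name="sim"):
        self.prob_map = prob_map
        self.name = name

    def predict_proba(self, image):
        return self.prob_map


class TestEnsembleWeights:
    def test_must_sum_to_one(self):
        with pytest.raises(ValueError):
            EnsembleWeights((0.5, 0.4))
        with pytest.raises(ValueError):
            EnsembleWeights((1.2, -0.2))

    def test_rounding_largest_remainder(self):
        w = EnsembleWeights((1 / 3, 1 / 3, 1 / 3))
        rounded = w.rounded(2)
        assert sorted(rounded, reverse=True) == [0.34, 0.33, 0.33]
        assert sum(rounded) == pytest.approx(1.0)

    def test_rounding_exact_values_untouched(self):
        assert EnsembleWeights((0.5, 0.5, 0.0)).rounded() == (0.5, 0.5, 0.0)


class TestGridEnumeration:
    def test_single_member_degenerate(self):
        grid = enumerate_weight_grid(1, 0.1)
        assert len(grid) == 1
        assert grid[0].weights == (1.0,)

    def test_two_members_step_half(self):
        grid = {w.weights for w in enumerate_weight_grid(2, 0.5)}
        expected = {(1.0, 0.0), (0.0, 1.0), (0.5, 0.5),
                    (1 / 3, 2 / 3), (2 / 3, 1 / 3)}
        assert {tuple(np.round(w, 9)) for w in grid} == \
            {tuple(np.round(w, 9)) for w in expected}

    def test_contains_one_hot_and_uniform(self):
        grid = {tuple(np.round(w.weights, 9))
                for w in enumerate_weight_grid(3, 0.1)}
        assert (1.0, 0.0, 0.0) in grid
        assert (0.0, 1.0, 0.0) in grid
        assert (0.0, 0.0, 1.0) in grid
        third = tuple(np.round([1 / 3] * 3, 9))
        assert third in grid

    def test_matches_brute_force_oracle(self):
        """Independent enumeration by nested loops, for 3 members, step 0.1."""
        raw = [np.array(v, float) for v in product(range(11), repeat=3)
               if sum(v) > 0]
        oracle = {tuple(np.round(v / v.sum(), 9)) for v in raw}
        grid = {tuple(np.round(w.weights, 9))
                for w in enumerate_weight_grid(3, 0.1)}
        assert grid == oracle

    def test_invalid_step(self):
        with pytest.raises(ValueError):
            enumerate_weight_grid(2, 0.3)


class TestFusion:
    def test_one_hot_weight_returns_that_member(self, rng):
        maps = [rng.dirichlet(np.ones(3), size=(4, 4)) for _ in range(3)]
        fused = weighted_average_predict_maps(maps,
                                              EnsembleWeights((1.0, 0.0, 0.0)))
        assert np.allclose(fused, maps[0])

    def test_identical_members_idempotent(self, rng):
        m = rng.dirichlet(np.ones(3), size=(4, 4))
        fused = weighted_average_predict_maps([m, m, m],
                                              EnsembleWeights((0.2, 0.5, 0.3)))
        assert np.allclose(fused, m)

    def test_hand_computed_blend(self):
        a = np.zeros((1, 1, 2))
        a[..., 1] = 0.8
        a[..., 0] = 0.2
        b = np.zeros((1, 1, 2))
        b[..., 1] = 0.2
        b[..., 0] = 0.8
        fused = weighted_average_predict_maps([a, b],
                                              EnsembleWeights((0.6, 0.4)))
        assert fused[0, 0, 1] == pytest.approx(0.56)

    def test_convexity_bounds_and_simplex(self, rng):
        maps = [rng.dirichlet(np.ones(3), size=(5, 5)) for _ in range(3)]
        w = EnsembleWeights((0.5, 0.3, 0.2))
        fused = weighted_average_predict_maps(maps, w)
        stack = np.stack(maps)
        assert np.all(fused >= stack.min(axis=0) - 1e-12)
        assert np.all(fused <= stack.max(axis=0) + 1e-12)
        assert np.allclose(fused.sum(axis=2), 1.0)

    def test_permutation_equivariance(self, rng):
        maps = [rng.dirichlet(np.ones(3), size=(4, 4)) for _ in range(3)]
        w = (0.5, 0.3, 0.2)
        a = weighted_average_predict_maps(maps, EnsembleWeights(w))
        b = weighted_average_predict_maps([maps[2], maps[0], maps[1]],
                                          EnsembleWeights((0.2, 0.5, 0.3)))
        assert np.allclose(a, b)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            weighted_average_predict_maps([rng.dirichlet(np.ones(3), (2, 2))],
                                          EnsembleWeights((0.5, 0.5)))


class TestGridSearch:
    def _search(self, member_maps, truths, scheme, step=0.1):
        val = [(None, t) for t in truths]
        return grid_search_weights([None] * len(member_maps), val, step=step,
                                   scheme=scheme, member_maps=member_maps)

    def test_oracle_member_gets_full_weight(self, phantom_samples, scheme3):
        truths = [s.mask for s in phantom_samples[:5]]
        mm = [[simulate_predictor(t, eta, seed=37 * j + i)
               for i, t in enumerate(truths)]
              for j, eta in enumerate((0.0, 1.0, 1.0))]
        w, score = self._search(mm, truths, scheme3)
        assert w.weights == (1.0, 0.0, 0.0)
        assert score == 1.0

    def test_identical_members_uniform_by_entropy(self, phantom_samples,
                                                  scheme3):
        truths = [s.mask for s in phantom_samples[:3]]
        maps = [simulate_predictor(t, 0.3, seed=i) for i, t in enumerate(truths)]
        mm = [maps, maps, maps]
        w, _ = self._search(mm, truths, scheme3)
        assert np.allclose(w.weights, 1 / 3)

    def test_never_below_any_member_or_uniform(self, phantom_samples, scheme3):
        """Guaranteed by grid membership of one-hot and uniform vectors."""
        rng = np.random.default_rng(5)
        truths = [s.mask for s in phantom_samples[:4]]
        for trial in range(5):
            etas = rng.uniform(0.1, 0.9, 3)
            mm = [[simulate_predictor(t, e, seed=1000 * trial + 10 * j + i)
                   for i, t in enumerate(truths)]
                  for j, e in enumerate(etas)]
            w, score = self._search(mm, truths, scheme3)
            assert sum(w.weights) == pytest.approx(1.0)
            for j in range(3):
                onehot = EnsembleWeights(tuple(1.0 if i == j else 0.0
                                               for i in range(3)))
                assert score >= evaluate_weights(mm, truths, onehot, scheme3)
            uniform = EnsembleWeights((1 / 3, 1 / 3, 1 / 3))
            assert score >= evaluate_weights(mm, truths, uniform, scheme3)

    def test_best_member_gets_largest_weight(self, phantom_samples, scheme3):
        truths = [s.mask for s in phantom_samples[:5]]
        mm = [[simulate_predictor(t, eta, seed=91 * j + i)
               for i, t in enumerate(truths)]
              for j, eta in enumerate((0.05, 0.6, 0.9))]
        w, _ = self._search(mm, truths, scheme3)
        assert w.weights[0] >= max(w.weights[1:])

    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            grid_search_weights([], [])


class TestEnsembleModel:
    def test_zero_weight_members_dropped(self, rng):
        maps = [rng.dirichlet(np.ones(3), size=(4, 4)) for _ in range(3)]
        members = [_MapMember(m, str(i)) for i, m in enumerate(maps)]
        from emseg.data_io import ClassScheme
        scheme = ClassScheme(("background", "cytoplasm", "nucleus"))
        model = EnsembleModel(members, EnsembleWeights((0.5, 0.5, 0.0)), scheme)
        assert len(model.members) == 2
        assert model.weights.weights == (0.5, 0.5)

    def test_single_member_equals_member_argmax(self, rng, scheme3):
        m = rng.dirichlet(np.ones(3), size=(4, 4))
        model = EnsembleModel([_MapMember(m)], EnsembleWeights((1.0,)), scheme3)
        assert np.array_equal(model.predict_labels(None), m.argmax(axis=2))

    def test_argmax_tie_breaks_to_lower_class(self, scheme3):
        m = np.zeros((1, 1, 3))
        m[..., 0] = 0.5
        m[..., 1] = 0.5
        model = EnsembleModel([_MapMember(m)], EnsembleWeights((1.0,)), scheme3)
        assert model.predict_labels(None)[0, 0] == 0
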