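"""Encoding, hamming ranking, strategy weights and the weighted ensemble."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flms import (
    PanelValidationError,
    PredictionCube,
    RankRecord,
    aggregate_mean,
    compute_weights,
    encode_change,
    hamming_distance,
    rank_candidates,
    weighted_ensemble,
)


def _cube(pred, mask, strategy="ATU"):
    return PredictionCube(
        strategy=strategy,
        fusion=("m",),
        pred=np.where(mask, np.asarray(pred, dtype=float), np.nan),
        mask=np.asarray(mask, dtype=bool),
    )


class TestEncodeChange:
    @pytest.mark.parametrize(
        "value,expected", [(-2.0, 0), (0.0, 0), (3.5, 1), (0.001, 1), (-27, 0)]
    )
    def test_zero_or_negative_is_no_increase(self, value, expected):
        assert encode_change(value) == expected

    def test_non_finite_errors(self):
        for bad in (np.nan, np.inf, -np.inf):
            with pytest.raises(PanelValidationError):
                encode_change(bad)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=20))
    def test_idempotent_on_binary(self, bits):
        once = encode_change(np.array(bits, dtype=float))
        np.testing.assert_array_equal(encode_change(once.astype(float)), once)


class TestHammingDistance:
    def test_identical_vectors(self):
        assert hamming_distance(np.array([0, 1, 1]), np.array([0, 1, 1])) == 0

    def test_complement_vectors(self):
        assert hamming_distance(np.array([0, 0, 0]), np.array([1, 1, 1])) == 3

    def test_shape_mismatch_errors(self):
        with pytest.raises(PanelValidationError, match="shape"):
            hamming_distance(np.zeros(3), np.zeros(4))

    @given(st.integers(0, 10_000))
    def test_matches_slot_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        enc = rng.integers(0, 2, size=(45, 24))
        truth = rng.integers(0, 2, size=(45, 24))
        mask = rng.random((45, 24)) < 0.6
        oracle = sum(
            int(enc[i, j] != truth[i, j])
            for i in range(45)
            for j in range(24)
            if mask[i, j]
        )
        assert hamming_distance(enc, truth, mask) == oracle


class TestAggregateMean:
    def test_mean_of_identical_cubes(self):
        mask = np.array([[True, True]])
        cubes = [_cube([[1.0, 2.0]], mask) for _ in range(4)]
        out = aggregate_mean(cubes)
        np.testing.assert_array_equal(out.pred, [[1.0, 2.0]])

    def test_arithmetic_mean(self):
        mask = np.array([[True, True]])
        out = aggregate_mean([_cube([[0.0, 2.0]], mask), _cube([[2.0, 0.0]], mask)])
        np.testing.assert_array_equal(out.pred, [[1.0, 1.0]])

    def test_mixed_strategy_rejected(self):
        mask = np.array([[True]])
        with pytest.raises(PanelValidationError):
            aggregate_mean([_cube([[1.0]], mask, "ATU"), _cube([[1.0]], mask, "LOPO")])

    @given(st.integers(0, 10_000))
    def test_matches_elementwise_oracle_and_convex_hull(self, seed):
        rng = np.random.default_rng(seed)
        cubes = [
            _cube(rng.normal(size=(4, 6)), rng.random((4, 6)) < 0.7)
            for _ in range(3)
        ]
        out = aggregate_mean(cubes)
        for i in range(4):
            for j in range(6):
                vals = [c.pred[i, j] for c in cubes if c.mask[i, j]]
                if not vals:
                    assert not out.mask[i, j]
                    continue
                assert np.isclose(out.pred[i, j], np.mean(vals))
                assert min(vals) - 1e-12 <= out.pred[i, j] <= max(vals) + 1e-12


class TestRankCandidates:
    @staticmethod
    def _record(strategy, scope, cardinality, distance, n=500):
        mask = np.ones((25, 20), dtype=bool)
        enc = np.zeros((25, 20), dtype=int)
        enc.flat[:distance] = 1  # distance vs all-zero truth
        return RankRecord(
            strategy=strategy, scope=scope, cardinality=cardinality,
            encoded=enc, mask=mask, distance=distance,
        )

    def test_strategy_order_by_min_distance(self):
        # reference distances: forecasting 226 < within-person LOO 267
        # < leave-participant-out 350 < leave-week-out 378
        records = [
            self._record("LTXO", "a+b", 2, 378),
            self._record("LOPO", "a", 1, 350),
            self._record("ATU", "a+b+c+d+e+f", 6, 226),
            self._record("LOTPO", "a+b+c+d+e+f", 6, 267),
        ]
        ranked = rank_candidates(records)
        assert [r.strategy for r in ranked] == ["ATU", "LOTPO", "LOPO", "LTXO"]
        assert all(r.chosen for r in ranked)

    def test_tie_prefers_smaller_cardinality(self):
        records = [
            self._record("ATU", "a+b", 2, 10),
            self._record("ATU", "c", 1, 10),
        ]
        ranked = rank_candidates(records)
        assert ranked[0].scope == "c"
        assert ranked[0].chosen and not ranked[1].chosen

    @given(st.integers(0, 10_000))
    def test_matches_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        records = [
            self._record("ATU", f"s{k}", int(rng.integers(1, 7)),
                         int(rng.integers(0, 400)))
            for k in range(8)
        ]
        ranked = rank_candidates(records)
        oracle = sorted(records, key=lambda r: (r.distance, r.cardinality, r.scope))
        assert [r.scope for r in ranked] == [r.scope for r in oracle]
        assert sum(r.chosen for r in ranked) == 1
        assert ranked[0].chosen


class TestComputeWeights:
    def test_equal_distances_give_uniform_weights(self):
        w = compute_weights({"a": 7, "b": 7, "c": 7, "d": 7})
        np.testing.assert_allclose(list(w.values()), 0.25)

    def test_zero_distance_dominates(self):
        w = compute_weights({"a": 0, "b": 10, "c": 20})
        assert w["a"] == pytest.approx(1.0, abs=1e-6)

    def test_inverse_normalization_hand_oracle(self):
        dists = {"ATU": 226, "LOTPO": 267, "LOPO": 350, "LTXO": 378}
        inv = {k: 1.0 / v for k, v in dists.items()}
        total = sum(inv.values())
        w = compute_weights(dists)
        for k in dists:
            assert w[k] == pytest.approx(inv[k] / total, rel=1e-6)
        assert w["ATU"] > w["LOTPO"] > w["LOPO"] > w["LTXO"]

    def test_negative_distance_errors(self):
        with pytest.raises(PanelValidationError, match="negative"):
            compute_weights({"a": -1, "b": 2})

    @given(
        st.lists(st.integers(0, 500), min_size=2, max_size=6),
        st.integers(0, 100),
    )
    def test_sum_one_and_permutation_equivariance(self, dists, seed):
        names = [f"s{i}" for i in range(len(dists))]
        w = compute_weights(dict(zip(names, dists)))
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)
        perm = np.random.default_rng(seed).permutation(len(dists))
        w2 = compute_weights({names[i]: dists[i] for i in perm})
        for n in names:
            assert w2[n] == pytest.approx(w[n], abs=1e-12)


class TestWeightedEnsemble:
    def test_degenerate_weight_copies_strategy(self):
        mask = np.ones((1, 2), dtype=bool)
        layers = {
            "a": (np.array([[1, 0]]), mask),
            "b": (np.array([[0, 1]]), mask),
        }
        out = weighted_ensemble(layers, {"a": 1.0, "b": 0.0})
        np.testing.assert_array_equal(out.final, [[1, 0]])

    def test_half_vote_rounds_up(self):
        mask = np.ones((1, 2), dtype=bool)
        layers = {
            n: (np.array([[v, 0]]), mask)
            for n, v in zip("abcd", (1, 1, 0, 0))
        }
        weights = {n: 0.25 for n in "abcd"}
        up = weighted_ensemble(layers, weights, tie_rule="half_up")
        down = weighted_ensemble(layers, weights, tie_rule="half_down")
        assert up.fused[0, 0] == pytest.approx(0.5)
        assert up.final[0, 0] == 1
        assert down.final[0, 0] == 0

    def test_identical_layers_fixed_point(self):
        rng = np.random.default_rng(2)
        enc = rng.integers(0, 2, size=(5, 7))
        mask = rng.random((5, 7)) < 0.8
        layers = {n: (enc, mask) for n in ("a", "b", "c")}
        out = weighted_ensemble(layers, {"a": 0.6, "b": 0.3, "c": 0.1})
        np.testing.assert_array_equal(out.final[mask], enc[mask])

    def test_coverage_renormalization(self):
        full = np.ones((1, 1), dtype=bool)
        empty = np.zeros((1, 1), dtype=bool)
        layers = {"a": (np.array([[1]]), full), "b": (np.array([[0]]), empty)}
        out = weighted_ensemble(layers, {"a": 0.2, "b": 0.8})
        # only "a" covers the slot, so its vote is renormalized to 1
        assert out.fused[0, 0] == pytest.approx(1.0)
        assert out.final[0, 0] == 1

    @given(st.integers(0, 10_000))
    def test_matches_weighted_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        names = ["a", "b", "c", "d"]
        raw = rng.random(4)
        weights = dict(zip(names, raw / raw.sum()))
        layers = {
            n: (rng.integers(0, 2, size=(6, 8)), rng.random((6, 8)) < 0.7)
            for n in names
        }
        out = weighted_ensemble(layers, weights)
        for i in range(6):
            for j in range(8):
                cover = [n for n in names if layers[n][1][i, j]]
                if not cover:
                    assert not out.mask[i, j]
                    continue
                denom = sum(weights[n] for n in cover)
                expect = sum(weights[n] * layers[n][0][i, j] for n in cover) / denom
                assert out.fused[i, j] == pytest.approx(expect)
                assert out.final[i, j] == (1 if expect >= 0.5 else 0)

    @given(st.integers(0, 10_000))
    def test_perfect_strategy_dominates_on_its_slots(self, seed):
        rng = np.random.default_rng(seed)
        truth = rng.integers(0, 2, size=(6, 8))
        perfect_mask = rng.random((6, 8)) < 0.7
        layers = {"perfect": (truth.copy(), perfect_mask)}
        for n in ("x", "y", "z"):
            layers[n] = (rng.integers(0, 2, size=(6, 8)), rng.random((6, 8)) < 0.7)
        dists = {
            n: int(((layers[n][0] != truth) & layers[n][1]).sum()) for n in layers
        }
        assert dists["perfect"] == 0
        out = weighted_ensemble(layers, compute_weights(dists))
        np.testing.assert_array_equal(out.final[perfect_mask], truth[perfect_mask])
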