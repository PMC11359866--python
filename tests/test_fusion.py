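"""Confidence extraction and the two decision-level fusion schemes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uwbfall.fusion import (
    ClassifierOutput,
    MapAccuracies,
    adaptive_weighted_fuse,
    confidence,
    decision_fuse,
    fuse_batch,
    normalize_confidences,
    softmax_probs,
)


def output_with(pred: int, smax: float, k: int = 10) -> ClassifierOutput:
    """Construct logits whose softmax peaks at `pred` with value ~smax."""
    rest = (1.0 - smax) / (k - 1)
    z = np.log(np.full(k, rest))
    z[pred] = np.log(smax)
    out = ClassifierOutput(z)
    assert out.imax == pred
    assert out.smax == pytest.approx(smax, abs=1e-12)
    return out


class TestSoftmax:
    def test_uniform_logits(self):
        s = softmax_probs(np.zeros(10))
        assert np.allclose(s, 0.1)

    def test_two_class_value(self):
        s = softmax_probs(np.array([1.0, 0.0]))
        e = np.e
        assert s[0] == pytest.approx(e / (e + 1.0), abs=1e-12)
        assert s[1] == pytest.approx(1.0 / (e + 1.0), abs=1e-12)

    def test_shift_invariance(self):
        z = np.array([3.0, -1.0, 0.5, 2.0])
        assert np.allclose(softmax_probs(z), softmax_probs(z + 100.0))

    def test_large_logits_stable(self):
        s = softmax_probs(np.array([1000.0, 999.0]))
        assert np.isfinite(s).all() and s.sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            softmax_probs(np.array([]))

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=12))
    @settings(deadline=None, max_examples=200)
    def test_simplex_property(self, zs):
        s = softmax_probs(np.array(zs))
        assert s.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(s >= 0.0)


class TestConfidence:
    def test_tie_breaks_to_lowest_index(self):
        smax, imax = confidence(np.full(10, 0.1))
        assert (smax, imax) == (0.1, 0)

    def test_direct_max(self):
        assert confidence(np.array([0.05, 0.9, 0.05])) == (0.9, 1)

    def test_pigeonhole_lower_bound(self):
        for k in (2, 5, 10):
            s = softmax_probs(np.random.default_rng(k).normal(size=k))
            smax, _ = confidence(s)
            assert smax >= 1.0 / k


class TestDecisionFuse:
    def test_majority_wins(self):
        outs = [output_with(3, 0.5), output_with(3, 0.4), output_with(7, 0.99)]
        assert decision_fuse(outs) == 3

    def test_all_different_highest_confidence(self):
        outs = [output_with(1, 0.5), output_with(2, 0.9), output_with(3, 0.7)]
        assert decision_fuse(outs) == 2

    def test_unanimity(self):
        outs = [output_with(4, 0.5), output_with(4, 0.6), output_with(4, 0.7)]
        assert decision_fuse(outs) == 4

    def test_k_mismatch_rejected(self):
        outs = [output_with(0, 0.5, k=10), output_with(0, 0.5, k=10),
                output_with(0, 0.5, k=5)]
        with pytest.raises(ValueError):
            decision_fuse(outs)


class TestNormalizeConfidences:
    def test_symmetry(self):
        m = normalize_confidences([0.5, 0.5, 0.5]).m
        assert np.allclose(m, 1 / 3)

    def test_direct_division(self):
        m = normalize_confidences([0.9, 0.6, 0.3]).m
        assert np.allclose(m, [0.5, 1 / 3, 1 / 6])

    def test_scale_invariance(self):
        a = normalize_confidences([0.9, 0.6, 0.3]).m
        b = normalize_confidences([0.45, 0.3, 0.15]).m
        assert np.allclose(a, b)


class TestAdaptiveWeightedFuse:
    def test_unanimous_prediction_wins(self):
        n = MapAccuracies((0.3, 0.9, 0.5))
        outs = [output_with(5, 0.4), output_with(5, 0.8), output_with(5, 0.6)]
        assert adaptive_weighted_fuse(n, outs).fused_class == 5

    def test_accuracy_weighted_pair_overrides_confident_single(self):
        """Two accurate-but-hesitant maps outweigh one confident outlier."""
        n = MapAccuracies((0.94, 0.94, 0.96))
        outs = [output_with(2, 0.99), output_with(8, 0.6), output_with(8, 0.6)]
        score = adaptive_weighted_fuse(n, outs)
        m = np.array([0.99, 0.6, 0.6]) / 2.19
        assert np.allclose(score.w, np.array([0.94, 0.94, 0.96]) * m)
        assert score.w_prime[2] == pytest.approx(0.94 * m[0])
        assert score.w_prime[8] == pytest.approx(0.94 * m[1] + 0.96 * m[2])
        assert score.fused_class == 8

    def test_uniform_n_matches_decision_fuse_all_different(self):
        n = MapAccuracies((1.0, 1.0, 1.0))
        outs = [output_with(1, 0.5), output_with(2, 0.9), output_with(3, 0.7)]
        assert adaptive_weighted_fuse(n, outs).fused_class == 2
        assert adaptive_weighted_fuse(n, outs).fused_class == decision_fuse(outs)


def brute_force_adaptive(n, outputs):
    """Independent scorer: materialize w' over all classes, scan for max."""
    s = np.array([o.smax for o in outputs])
    m = s / s.sum()
    w = np.array(n) * m
    k = outputs[0].n_classes
    best_c, best_v = 0, -1.0
    for c in range(k):
        v = sum(w[i] for i in range(3) if outputs[i].imax == c)
        if v > best_v:
            best_c, best_v = c, v
    return best_c


def random_output(rng, k=10):
    return ClassifierOutput(rng.normal(scale=2.0, size=k))


class TestFusionProperties:
    def test_oracle_equivalence_1000_triples(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            outs = [random_output(rng) for _ in range(3)]
            n = MapAccuracies(tuple(rng.uniform(0.1, 1.0, 3)))
            assert (
                adaptive_weighted_fuse(n, outs).fused_class
                == brute_force_adaptive(n.n, outs)
            )

    def test_unanimity_dominance(self):
        """When all maps agree, both fusion rules return that class."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            c = int(rng.integers(0, 10))
            outs = [output_with(c, float(rng.uniform(0.2, 0.99)))
                    for _ in range(3)]
            n = MapAccuracies(tuple(rng.uniform(0.01, 1.0, 3)))
            assert decision_fuse(outs) == c
            assert adaptive_weighted_fuse(n, outs).fused_class == c

    def test_weight_monotonicity(self):
        """Raising a winning map's accuracy never costs it the decision."""
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 300:
            outs = [random_output(rng) for _ in range(3)]
            n = rng.uniform(0.1, 0.9, 3)
            fused = adaptive_weighted_fuse(MapAccuracies(tuple(n)), outs)
            for i in range(3):
                if outs[i].imax == fused.fused_class:
                    n2 = n.copy()
                    n2[i] = min(1.0, n2[i] + rng.uniform(0.0, 1.0 - n2[i]))
                    fused2 = adaptive_weighted_fuse(
                        MapAccuracies(tuple(n2)), outs
                    )
                    assert fused2.fused_class == fused.fused_class
                    checked += 1
                    break

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(13)
        tried = 0
        while tried < 200:
            outs = [random_output(rng) for _ in range(3)]
            n = rng.uniform(0.1, 1.0, 3)
            w_prime = adaptive_weighted_fuse(
                MapAccuracies(tuple(n)), outs
            ).w_prime
            top = np.sort(w_prime)[::-1]
            if np.isclose(top[0], top[1]):  # skip tie configurations
                continue
            base = adaptive_weighted_fuse(MapAccuracies(tuple(n)), outs)
            perm = rng.permutation(3)
            permuted = adaptive_weighted_fuse(
                MapAccuracies(tuple(n[perm])), [outs[i] for i in perm]
            )
            assert permuted.fused_class == base.fused_class
            tried += 1


class TestFuseBatch:
    def test_batch_matches_single(self):
        rng = np.random.default_rng(3)
        zs = [rng.normal(size=(20, 10)) for _ in range(3)]
        accs = [0.9, 0.8, 0.7]
        fused = fuse_batch("adaptive", zs, val_accuracies=accs)
        for i in range(20):
            outs = [ClassifierOutput(z[i]) for z in zs]
            assert fused[i] == adaptive_weighted_fuse(
                MapAccuracies(tuple(accs)), outs
            ).fused_class

    def test_adaptive_requires_accuracies(self):
        zs = [np.zeros((2, 10))] * 3
        with pytest.raises(ValueError):
            fuse_batch("adaptive", zs)
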