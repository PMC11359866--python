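"""Confidence-based decision-level fusion of the three radar-map classifiers.

Two schemes are provided for combining the per-sample outputs of the
range–time, time–Doppler and range–Doppler classifiers:

* **decision fusion** — majority vote over the three predicted classes;
  if all three disagree, the prediction with the highest softmax
  confidence smax wins;
* **adaptive weighted fusion** — each map's per-sample confidence smax
  is normalized across the three maps (m, summing to 1) and multiplied
  element-wise by that map's validation accuracy (n): w = n ∘ m.  The
  weights of maps predicting the same class are summed into a per-class
  score w', and the fused class is argmax w'.  A map with a strong
  validation record can thus overrule a single over-confident outlier.

All ties (argmax of s, of smax, of w') break to the lowest index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np


@dataclass
class ClassifierOutput:
    """One classifier's output for one sample."""

    logits: np.ndarray
    probs: np.ndarray = field(init=False)
    smax: float = field(init=False)
    imax: int = field(init=False)

    def __post_init__(self) -> None:
        self.logits = np.asarray(self.logits, dtype=float)
        self.probs = softmax_probs(self.logits)
        self.smax, self.imax = confidence(self.probs)

    @property
    def n_classes(self) -> int:
        return len(self.logits)


@dataclass(frozen=True)
class MapAccuracies:
    """Per-map validation accuracies n = [n1, n2, n3]."""

    n: Tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.n) != 3:
            raise ValueError("need exactly three per-map accuracies")
        if not all(np.isfinite(v) and 0.0 <= v <= 1.0 for v in self.n):
            raise ValueError(f"accuracies must lie in [0, 1], got {self.n}")


@dataclass(frozen=True)
class NormalizedConfidences:
    """Per-sample confidences normalized to sum to 1 across the maps."""

    m: Tuple[float, float, float]


@dataclass(frozen=True)
class FusionScore:
    """Adaptive-fusion weights and the per-class aggregated scores."""

    w: Tuple[float, float, float]
    w_prime: np.ndarray
    fused_class: int


def softmax_probs(z: np.ndarray) -> np.ndarray:
    """Softmax s_i = exp(z_i) / Σ_j exp(z_j), computed shift-invariantly."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("empty logits vector")
    e = np.exp(z - z.max())
    return e / e.sum()


def confidence(s: np.ndarray) -> Tuple[float, int]:
    """(smax, imax) of a probability vector; ties break to lowest index."""
    s = np.asarray(s, dtype=float)
    imax = int(np.argmax(s))
    return float(s[imax]), imax


def decision_fuse(outputs: Sequence[ClassifierOutput]) -> int:
    """Majority vote; all-different falls back to the highest confidence.

    With three voters a class predicted by at least two maps wins
    outright; otherwise the class of the most confident map is used
    (smax ties break to the lowest map index).
    """
    if len(outputs) != 3:
        raise ValueError("decision fusion expects exactly three outputs")
    k = outputs[0].n_classes
    if any(o.n_classes != k for o in outputs):
        raise ValueError("outputs disagree on the number of classes")
    preds = [o.imax for o in outputs]
    for p in preds:
        if preds.count(p) >= 2:
            return p
    smax = [o.smax for o in outputs]
    return preds[int(np.argmax(smax))]


def normalize_confidences(
    smax_triple: Sequence[float],
) -> NormalizedConfidences:
    """Sum-normalize three confidences: m_i = smax_i / Σ_j smax_j."""
    s = np.asarray(smax_triple, dtype=float)
    if s.shape != (3,):
        raise ValueError("need exactly three confidences")
    if np.any(s <= 0.0) or np.any(s > 1.0):
        raise ValueError(f"confidences must lie in (0, 1], got {s}")
    m = s / s.sum()
    return NormalizedConfidences(m=tuple(float(v) for v in m))


def adaptive_weighted_fuse(
    n: MapAccuracies, outputs: Sequence[ClassifierOutput]
) -> FusionScore:
    """Adaptive weighted fusion: w = n ∘ m, class scores summed over maps.

    ``w_prime[c]`` is the sum of w_i over the maps predicting class c
    (zero for classes no map predicts); the fused class is its argmax,
    ties breaking to the lowest class index.
    """
    if len(outputs) != 3:
        raise ValueError("adaptive fusion expects exactly three outputs")
    k = outputs[0].n_classes
    if any(o.n_classes != k for o in outputs):
        raise ValueError("outputs disagree on the number of classes")
    m = normalize_confidences([o.smax for o in outputs]).m
    w = tuple(float(ni * mi) for ni, mi in zip(n.n, m))
    w_prime = np.zeros(k)
    for wi, o in zip(w, outputs):
        w_prime[o.imax] += wi
    fused = int(np.argmax(w_prime))
    return FusionScore(w=w, w_prime=w_prime, fused_class=fused)


def fuse_batch(
    method: str,
    logits_per_map: Sequence[np.ndarray],
    val_accuracies: Sequence[float] | None = None,
) -> np.ndarray:
    """Fuse aligned (N, K) logit arrays from the three maps.

    ``method`` is ``"decision"`` or ``"adaptive"``; the latter requires
    ``val_accuracies``.  Returns the (N,) fused class labels.
    """
    if len(logits_per_map) != 3:
        raise ValueError("expected logits from exactly three maps")
    zs = [np.asarray(z) for z in logits_per_map]
    n_samples = zs[0].shape[0]
    if any(z.shape != zs[0].shape for z in zs):
        raise ValueError("per-map logit arrays must have identical shapes")
    if method == "adaptive":
        if val_accuracies is None:
            raise ValueError("adaptive fusion needs validation accuracies")
        acc = MapAccuracies(tuple(float(a) for a in val_accuracies))
    elif method != "decision":
        raise ValueError(f"unknown fusion method {method!r}")
    fused = np.empty(n_samples, dtype=int)
    for i in range(n_samples):
        outs = [ClassifierOutput(z[i]) for z in zs]
        if method == "decision":
            fused[i] = decision_fuse(outs)
        else:
            fused[i] = adaptive_weighted_fuse(acc, outs).fused_class
    return fused
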