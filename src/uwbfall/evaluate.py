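"""Dataset partitioning, classification metrics, and the experiment driver.

Splits are stratified by class: a 6:2:2 train/validation/test partition
and stratified k-fold cross-validation.  Metrics are accuracy plus
one-vs-rest precision, recall and F1 per class; the headline numbers are
macro averages (micro averages available by flag).  The experiment
driver runs the full pipeline — simulate echoes, build the three maps,
train one SE-RCNet per map, measure validation accuracies, and fuse the
test predictions with both decision-level schemes — and emits a report
with per-map and fused metrics, improvement rows, and confusion
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import echo_sim, fusion, preprocess, sercnet
from .params import RadarParams


@dataclass
class SplitPlan:
    """Index lists of a stratified train/validation/test partition."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        allidx = np.concatenate([self.train, self.val, self.test])
        if len(np.unique(allidx)) != len(allidx):
            raise ValueError("split partitions overlap")


@dataclass
class ConfusionMatrix:
    """K × K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Accuracy and averaged precision/recall/F1 with per-class detail."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: Dict[str, np.ndarray]
    average: str = "macro"

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "average": self.average,
        }


def split_622(labels: Sequence[int], seed: int) -> SplitPlan:
    """Stratified 60/20/20 train/validation/test split, seeded.

    Raises
    ------
    ValueError
        If any class has fewer than 5 samples (a 6:2:2 split cannot give
        every partition at least one of them).
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    for c, n in zip(classes, counts):
        if n < 5:
            raise ValueError(
                f"class {c} has only {n} samples; need >= 5 for a 6:2:2 split"
            )
    idx = np.arange(len(y))
    trainval, test = train_test_split(
        idx, test_size=0.2, stratify=y, random_state=seed % (2**31)
    )
    train, val = train_test_split(
        trainval,
        test_size=0.25,
        stratify=y[trainval],
        random_state=(seed + 1) % (2**31),
    )
    return SplitPlan(
        train=np.sort(train), val=np.sort(val), test=np.sort(test), seed=seed
    )


def kfold(labels: Sequence[int], k: int = 5, seed: int = 0) -> List[SplitPlan]:
    """Stratified k-fold plans; each sample is held out exactly once.

    Each plan's ``test`` is the held-out fold and ``train`` the rest
    (``val`` is empty — cross-validation has no third partition).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(labels, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs >= {k} samples for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    plans = []
    for tr, te in skf.split(np.zeros(len(y)), y):
        plans.append(
            SplitPlan(
                train=tr, val=np.array([], dtype=int), test=te, seed=seed
            )
        )
    return plans


def confusion(
    true_labels: Sequence[int], predicted_labels: Sequence[int], n_classes: int
) -> ConfusionMatrix:
    """Count matrix: entry (i, j) = samples with true class i predicted j."""
    yt = np.asarray(true_labels, dtype=int)
    yp = np.asarray(predicted_labels, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("label arrays differ in length")
    if yt.size and (
        min(yt.min(), yp.min()) < 0 or max(yt.max(), yp.max()) >= n_classes
    ):
        raise ValueError("labels out of range")
    cm = _sk_confusion(yt, yp, labels=np.arange(n_classes))
    return ConfusionMatrix(cm)


def metrics(cm: ConfusionMatrix, average: str = "macro") -> MetricsReport:
    """Accuracy and one-vs-rest precision/recall/F1 from a confusion matrix.

    accuracy = trace/total; per class c: precision = TP/(TP+FP),
    recall = TP/(TP+FN), F1 = 2PR/(P+R).  Classes never predicted get
    precision 0 (and F1 0 when also unrecalled).  ``average`` is
    ``"macro"`` (unweighted class mean; the headline convention here) or
    ``"micro"`` (pooled counts; equals accuracy for single-label data).
    """
    c = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(c).astype(float)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    acc = float(tp.sum() / total)
    if average == "macro":
        p, r, f = float(prec.mean()), float(rec.mean()), float(f1.mean())
    elif average == "micro":
        tp_s, fp_s, fn_s = tp.sum(), fp.sum(), fn.sum()
        p = float(tp_s / (tp_s + fp_s)) if tp_s + fp_s else 0.0
        r = float(tp_s / (tp_s + fn_s)) if tp_s + fn_s else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
    else:
        raise ValueError(f"unknown average {average!r}")
    return MetricsReport(
        accuracy=acc,
        precision=p,
        recall=r,
        f1=f,
        per_class={"precision": prec, "recall": rec, "f1": f1},
        average=average,
    )


# ---------------------------------------------------------------------------
# experiment driver


@dataclass
class ExperimentConfig:
    """Everything needed to run the simulate→train→fuse pipeline."""

    radar: RadarParams = field(default_factory=RadarParams)
    per_class: int = 50
    clutter_amp: float = 2.0
    noise_sigma: float = 0.15
    model: sercnet.SercnetConfig = field(default_factory=sercnet.SercnetConfig)
    stft: preprocess.StftConfig = field(default_factory=preprocess.StftConfig)
    image_size: int = 80
    seed: int = 0
    #: map kind to degrade with extra image-domain noise (or None)
    degrade_map: Optional[str] = None
    degrade_sigma: float = 0.35
    average: str = "macro"


def simulate_map_dataset(
    cfg: ExperimentConfig,
) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    """Simulate echoes and preprocess them into per-kind image stacks.

    Echo matrices are rendered one at a time and discarded after their
    three maps are computed, keeping memory flat.  Returns
    ({kind: (N, S, S) float32}, labels).  If ``cfg.degrade_map`` names a
    kind, seeded Gaussian pixel noise of std ``cfg.degrade_sigma`` is
    added to that kind's images (clipped back to [0, 1]).
    """
    ss = np.random.SeedSequence([cfg.seed, 0xDA7A])
    seeds = ss.generate_state(2 * cfg.per_class * echo_sim.N_CLASSES).reshape(
        -1, 2
    )
    stacks: Dict[str, list] = {k: [] for k in preprocess.MAP_KINDS}
    labels = []
    k = 0
    for _rep in range(cfg.per_class):
        for cid in range(echo_sim.N_CLASSES):
            prof_seed, echo_seed = seeds[k]
            k += 1
            prof = echo_sim.make_profile(
                cid, cfg.radar, int(prof_seed % (2**31))
            )
            pm = echo_sim.synthesize_pulses(
                prof,
                cfg.radar,
                clutter_amp=cfg.clutter_amp,
                noise_sigma=cfg.noise_sigma,
                rng_seed=int(echo_seed % (2**31)),
            )
            images = preprocess.pulse_matrix_to_images(
                pm, cfg.stft, size=cfg.image_size
            )
            for kind, im in images.items():
                stacks[kind].append(im.pixels)
            labels.append(cid)
    out = {k: np.stack(v).astype(np.float32) for k, v in stacks.items()}
    y = np.asarray(labels, dtype=int)
    if cfg.degrade_map is not None:
        if cfg.degrade_map not in out:
            raise ValueError(f"unknown map kind {cfg.degrade_map!r}")
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 0xBAD]).generate_state(1)[0]
        )
        noisy = out[cfg.degrade_map] + rng.normal(
            0.0, cfg.degrade_sigma, out[cfg.degrade_map].shape
        )
        out[cfg.degrade_map] = np.clip(noisy, 0.0, 1.0).astype(np.float32)
    return out, y


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Full protocol: simulate → split 6:2:2 → train per-map → fuse → report.

    The report contains, per map kind, the validation accuracy (the
    fusion weight n) and test metrics; fused test metrics for both
    decision and adaptive weighted fusion; improvement rows against the
    best single map in both absolute percentage points and relative
    percent; and all confusion matrices.  Deterministic given
    ``cfg.seed``.
    """
    stacks, y = simulate_map_dataset(cfg)
    plan = split_622(y, seed=cfg.seed)
    kinds = list(preprocess.MAP_KINDS)
    n_classes = cfg.model.n_classes

    report: dict = {"maps": {}, "fusion": {}, "config_seed": cfg.seed}
    val_accs = []
    test_logits = []
    for i, kind in enumerate(kinds):
        x = stacks[kind]
        mcfg = sercnet.SercnetConfig(
            **{**vars(cfg.model), "seed": cfg.model.seed + i}
        )
        model = sercnet.build_model(mcfg)
        tm = sercnet.train(
            model,
            (x[plan.train], y[plan.train]),
            (x[plan.val], y[plan.val]),
            mcfg,
        )
        val_logits = sercnet.predict(tm, (x[plan.val], None))
        n_k = float((val_logits.argmax(axis=1) == y[plan.val]).mean())
        logits = sercnet.predict(tm, (x[plan.test], None))
        preds = logits.argmax(axis=1)
        cm = confusion(y[plan.test], preds, n_classes)
        rep = metrics(cm, average=cfg.average)
        report["maps"][kind] = {
            "val_accuracy": n_k,
            "metrics": rep.as_dict(),
            "confusion": cm.counts.tolist(),
            "history": tm.history,
        }
        val_accs.append(n_k)
        test_logits.append(logits)

    y_test = y[plan.test]
    best_single = max(
        report["maps"][k]["metrics"]["accuracy"] for k in kinds
    )
    for method in ("decision", "adaptive"):
        fused = fusion.fuse_batch(
            method, test_logits,
            val_accuracies=val_accs if method == "adaptive" else None,
        )
        cm = confusion(y_test, fused, n_classes)
        rep = metrics(cm, average=cfg.average)
        entry = {
            "metrics": rep.as_dict(),
            "confusion": cm.counts.tolist(),
        }
        # improvement over the best single map, both conventions
        improvement = {}
        for name in ("accuracy", "precision", "recall", "f1"):
            best = max(report["maps"][k]["metrics"][name] for k in kinds)
            fused_v = rep.as_dict()[name]
            improvement[name] = {
                "absolute_points": 100.0 * (fused_v - best),
                "relative_percent": (
                    100.0 * (fused_v - best) / best if best > 0 else float("nan")
                ),
            }
        entry["improvement_over_best_map"] = improvement
        report["fusion"][method] = entry
    report["val_accuracies"] = dict(zip(kinds, val_accs))
    report["best_single_map_accuracy"] = best_single
    return report


def render_report(report: dict) -> str:
    """Plain-text table of per-map and fused results."""
    lines = []
    hdr = f"{'':34s} {'Acc':>7s} {'Prec':>7s} {'Rec':>7s} {'F1':>7s}"
    lines.append(hdr)
    for kind, entry in report["maps"].items():
        m = entry["metrics"]
        lines.append(
            f"{kind + ' (before fusion)':34s} {m['accuracy']:7.3f} "
            f"{m['precision']:7.3f} {m['recall']:7.3f} {m['f1']:7.3f}"
        )
    for method, entry in report["fusion"].items():
        m = entry["metrics"]
        lines.append(
            f"{method + ' fusion':34s} {m['accuracy']:7.3f} "
            f"{m['precision']:7.3f} {m['recall']:7.3f} {m['f1']:7.3f}"
        )
        imp = entry["improvement_over_best_map"]
        lines.append(
            f"{'  improvement (rel %)':34s} "
            + " ".join(
                f"{imp[k]['relative_percent']:7.2f}"
                for k in ("accuracy", "precision", "recall", "f1")
            )
        )
    return "\n".join(lines)
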