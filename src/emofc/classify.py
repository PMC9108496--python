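"""Classifier training, fivefold cross-validation, and confusion-count metrics.

The positive class is HVA throughout, so sensitivity is the HVA recall and
specificity the LVA recall. Metrics are percentages:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F1          = 2 * precision * recall / (precision + recall)

Any metric whose denominator is zero is reported as undefined (None), never
as zero. Cross-validation rotates five equal per-class parts through
train (3 parts) / validation (1 part) / test (1 part), so every sample is
tested exactly once across the five folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .containers import CLASSES, HVA, ConfusionCounts, ImageSample, MetricsReport
from .nn import SoftmaxClassifier, build_model, resize_nearest

__all__ = [
    "ModelConfig",
    "FoldAssignment",
    "images_to_arrays",
    "make_folds",
    "train_cnn",
    "train_baseline",
    "evaluate",
    "compute_metrics",
    "cross_validate",
    "summarize_folds",
]

#: label -> integer class used by every classifier (HVA is the positive class, 1)
CLASS_INDEX = {"LVA": 0, "HVA": 1}


@dataclass
class ModelConfig:
    """Training configuration for the CNN scales.

    ``full`` is the full-size architecture (14 residual modules; 3
    standard + 33 depthwise-separable convolution layers) and requires inputs
    resized to at least ``input_size``; ``mini`` (a stem convolution plus 2
    separable residual modules) accepts native channels x points images and is
    the scale exercised at desk size.
    """

    scale: str = "mini"
    input_size: int = 71
    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale not in ("mini", "full"):
            raise ValueError(f"unknown scale {self.scale!r}")


def images_to_arrays(samples: list[ImageSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack image samples into (N, 3, H, W) float inputs in [0, 1] and int labels."""
    X = np.stack([s.planes for s in samples]) / 255.0
    y = np.array([CLASS_INDEX[s.label] for s in samples])
    return X, y


@dataclass
class FoldAssignment:
    """Index sets of one cross-validation fold."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def make_folds(
    labels: np.ndarray | list[str],
    k: int = 5,
    seed: int = 0,
    groups: np.ndarray | list | None = None,
) -> list[FoldAssignment]:
    """Stratified k-fold rotation with disjoint train/validation/test roles.

    Per class the shuffled samples are split into k near-equal parts; fold i
    tests part i, validates part i+1 (mod k), and trains on the remaining
    k - 2 parts. Across folds every sample appears in the test role exactly
    once.

    Sample-level splitting is the default but leaks subject
    identity across roles when samples share a subject; pass ``groups`` (e.g.
    subject ids) to keep each group's samples in a single role per fold.
    """
    if k < 3:
        raise ValueError("k must be >= 3 so train/validation/test parts are disjoint")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts_by_class = {}
    if groups is None:
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            parts_by_class[cls] = np.array_split(idx, k)
    else:
        # one global group partition: a group (subject) contributes both
        # classes, so its role must be decided once, not per class
        groups = np.asarray(groups)
        unique_groups = np.unique(groups)
        rng.shuffle(unique_groups)
        group_parts = np.array_split(unique_groups, k)
        for cls in np.unique(labels):
            parts_by_class[cls] = [
                np.flatnonzero((labels == cls) & np.isin(groups, part))
                for part in group_parts
            ]
    folds = []
    for i in range(k):
        test, val, train = [], [], []
        for parts in parts_by_class.values():
            test.append(parts[i])
            val.append(parts[(i + 1) % k])
            train += [parts[j] for j in range(k) if j not in (i, (i + 1) % k)]
        folds.append(
            FoldAssignment(
                train=np.sort(np.concatenate(train)),
                val=np.sort(np.concatenate(val)),
                test=np.sort(np.concatenate(test)),
            )
        )
    return folds


def train_cnn(
    X_train: np.ndarray,
    y_train: np.ndarray,
    cfg: ModelConfig,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> SoftmaxClassifier:
    """Train the depthwise-separable CNN; returns the fitted model.

    Full-scale inputs are upscaled by nearest-neighbor to
    ``input_size x input_size``; the mini scale trains on native image size.
    """
    if len(X_train) == 0:
        raise ValueError("empty training set")
    model = build_model(cfg.scale, in_channels=X_train.shape[1], seed=cfg.seed)
    resize = (lambda X: resize_nearest(X, (cfg.input_size, cfg.input_size))) if cfg.scale == "full" else (lambda X: X)
    model.fit(
        resize(X_train),
        y_train,
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        rng=np.random.default_rng(cfg.seed),
        X_val=resize(X_val) if X_val is not None else None,
        y_val=y_val,
    )
    if cfg.scale == "full":
        inner_predict = model.predict
        model.predict = lambda X: inner_predict(resize(X))  # type: ignore[method-assign]
    return model


class _SklearnWrapper:
    """Adapts a fitted sklearn estimator to the flattened-image interface."""

    def __init__(self, est):
        self.est = est

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.est.predict(X.reshape(len(X), -1))


def train_baseline(kind: str, X_train: np.ndarray, y_train: np.ndarray, seed: int = 0):
    """Fit a traditional baseline on flattened image vectors.

    ``svm`` is an RBF support-vector machine, ``rf`` a random forest, and
    ``logreg`` an L2 logistic regression (the fast evaluator used inside the
    channel search).
    """
    if len(X_train) == 0:
        raise ValueError("empty training set")
    X2 = X_train.reshape(len(X_train), -1)
    if not np.isfinite(X2).all():
        raise ValueError("training vectors must be finite")
    if kind == "svm":
        est = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    elif kind == "rf":
        est = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif kind == "logreg":
        est = LogisticRegression(max_iter=500, random_state=seed)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    est.fit(X2, y_train)
    return _SklearnWrapper(est)


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray, positive_class: str = HVA) -> ConfusionCounts:
    """Tally confusion counts on a held-out set (positive class HVA)."""
    y_test = np.asarray(y_test)
    if y_test.dtype.kind in "US":
        unknown = set(y_test) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown labels {sorted(unknown)}")
        y_test = np.array([CLASS_INDEX[lb] for lb in y_test])
    pred = np.asarray(model.predict(X_test))
    pos = CLASS_INDEX[positive_class]
    return ConfusionCounts(
        TP=int(((pred == pos) & (y_test == pos)).sum()),
        TN=int(((pred != pos) & (y_test != pos)).sum()),
        FP=int(((pred == pos) & (y_test != pos)).sum()),
        FN=int(((pred != pos) & (y_test == pos)).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return 100.0 * num / den if den else None


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Percentage metrics from confusion counts; zero denominators -> None."""
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    sens = _ratio(c.TP, c.TP + c.FN)
    prec = _ratio(c.TP, c.TP + c.FP)
    f1 = None
    if sens is not None and prec is not None and (sens + prec) > 0:
        f1 = 2.0 * sens * prec / (sens + prec)
    return MetricsReport(
        accuracy=_ratio(c.TP + c.TN, c.total),
        sensitivity=sens,
        specificity=_ratio(c.TN, c.TN + c.FP),
        precision=prec,
        f1=f1,
    )


@dataclass
class CVResult:
    """Per-fold confusion counts and metrics plus mean +/- SD summaries."""

    folds: list[ConfusionCounts]
    metrics: list[MetricsReport]
    summary: dict[str, tuple[float, float]] = field(default_factory=dict)


def summarize_folds(metrics: list[MetricsReport]) -> dict[str, tuple[float, float]]:
    """Mean +/- SD of each defined metric across folds."""
    out = {}
    for name in ("accuracy", "sensitivity", "specificity", "precision", "f1"):
        vals = [getattr(m, name) for m in metrics if getattr(m, name) is not None]
        if vals:
            out[name] = (float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
    return out


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    model_factory,
    k: int = 5,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> CVResult:
    """Run the k-fold rotation with a ``(X_tr, y_tr, X_val, y_val) -> model`` factory."""
    folds = make_folds(y, k=k, seed=seed, groups=groups)
    counts, metrics = [], []
    for fold in folds:
        if len(fold.test) == 0 or len(fold.train) == 0:
            raise ValueError(
                f"fold with empty train/test part: too few samples for k={k} folds"
            )
        model = model_factory(X[fold.train], y[fold.train], X[fold.val], y[fold.val])
        c = evaluate(model, X[fold.test], y[fold.test])
        counts.append(c)
        metrics.append(compute_metrics(c))
    return CVResult(folds=counts, metrics=metrics, summary=summarize_folds(metrics))
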