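"""Sequential backward selection of EEG channels with a pluggable evaluator.

Starting from the eight frontal channels, each level evaluates every
leave-one-out subset of the current set with a classifier evaluator
(fivefold cross-validated accuracy by default), keeps the best-scoring
removal, and recurses until only ``min_size`` channels remain. The search is
greedy without backtracking; the best subset reported may come from any
level, since a mid-search subset can outperform both endpoints.

From 8 channels down to 2 the search makes 8+7+6+5+4+3 = 33 evaluator calls.
The full accuracy grid (rows = current subset, columns = removed-channel
candidate) is retained as a :class:`SelectionTrace`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .classify import ModelConfig, cross_validate, train_baseline, train_cnn
from .containers import ConfigurationError
from .montage import FRONTAL_8

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelSubset",
    "SelectionTrace",
    "frontal_subset",
    "backward_select",
    "exhaustive_select",
    "make_cv_evaluator",
]


@dataclass(frozen=True)
class ChannelSubset:
    """An ordered, unique, non-empty list of channel labels."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if not self.labels:
            raise ConfigurationError("channel subset must be non-empty")
        if len(set(self.labels)) != len(self.labels):
            raise ConfigurationError("channel subset labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def without(self, label: str) -> "ChannelSubset":
        return ChannelSubset(tuple(ch for ch in self.labels if ch != label))


def frontal_subset(montage_labels) -> ChannelSubset:
    """The eight frontal-region channels, in fixed order."""
    montage = set(montage_labels)
    missing = [ch for ch in FRONTAL_8 if ch not in montage]
    if missing:
        raise ConfigurationError(f"montage is missing frontal channel(s): {', '.join(missing)}")
    return ChannelSubset(FRONTAL_8)


@dataclass
class LevelRecord:
    """One level of the search: the current subset and each removal's accuracy."""

    current: tuple[str, ...]
    candidate_accuracy: dict[str, float]
    chosen_removal: str


@dataclass
class SelectionTrace:
    """Complete record of a backward search."""

    levels: list[LevelRecord] = field(default_factory=list)
    best_subset: tuple[str, ...] = ()
    best_accuracy: float = -np.inf
    aborted: bool = False

    @property
    def n_evaluations(self) -> int:
        return sum(len(lvl.candidate_accuracy) for lvl in self.levels)

    def to_frame(self) -> pd.DataFrame:
        """Accuracy grid: one row per level, one column per removed channel."""
        rows = []
        for lvl in self.levels:
            row = {"current_subset": "_".join(lvl.current)}
            row.update({f"remove_{ch}": acc for ch, acc in lvl.candidate_accuracy.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def backward_select(
    start: ChannelSubset,
    evaluator,
    min_size: int = 2,
    montage_order: tuple[str, ...] | None = None,
) -> SelectionTrace:
    """Greedy leave-one-out channel elimination down to ``min_size`` channels.

    ``evaluator`` maps a tuple of channel labels to an accuracy and must be
    deterministic under its own fixed seed so subsets compare on shared folds.
    Ties between removals are broken toward removing the channel with the
    larger montage index. If the evaluator raises, the partial trace is
    returned with ``aborted=True``.
    """
    if len(start) <= min_size:
        raise ConfigurationError("start subset must be larger than min_size")
    order = tuple(montage_order) if montage_order is not None else start.labels
    rank = {ch: i for i, ch in enumerate(order)}

    trace = SelectionTrace()
    current = start
    while len(current) > min_size:
        accs: dict[str, float] = {}
        for ch in current.labels:
            try:
                accs[ch] = float(evaluator(current.without(ch).labels))
            except Exception:
                logger.exception("evaluator failed on %s minus %s; aborting", current.labels, ch)
                trace.aborted = True
                return trace
        best_acc = max(accs.values())
        tied = [ch for ch, a in accs.items() if a == best_acc]
        if len(tied) > 1:
            logger.info("tie between removals %s at accuracy %.4f", tied, best_acc)
        removal = max(tied, key=lambda ch: rank.get(ch, -1))
        trace.levels.append(
            LevelRecord(current=current.labels, candidate_accuracy=accs, chosen_removal=removal)
        )
        for ch, acc in accs.items():
            if acc > trace.best_accuracy:
                trace.best_accuracy = acc
                trace.best_subset = current.without(ch).labels
        current = current.without(removal)
    return trace


def exhaustive_select(
    start: ChannelSubset, evaluator, min_size: int = 2
) -> tuple[tuple[str, ...], float]:
    """Evaluate every subset of size >= ``min_size`` (test oracle; <= 8 channels)."""
    if len(start) > 8:
        raise ConfigurationError("exhaustive search is a small-scale oracle (<= 8 channels)")
    best: tuple[str, ...] = ()
    best_acc = -np.inf
    for size in range(min_size, len(start)):
        for combo in combinations(start.labels, size):
            acc = float(evaluator(combo))
            if acc > best_acc:
                best_acc = acc
                best = combo
    return best, best_acc


def make_cv_evaluator(
    tensor: np.ndarray,
    labels: np.ndarray,
    channel_order: tuple[str, ...],
    kind: str = "logreg",
    k: int = 5,
    seed: int = 0,
    model_config: ModelConfig | None = None,
):
    """Build a ``subset -> mean CV accuracy`` evaluator over a sample tensor.

    ``tensor`` is (n_samples, n_channels, n_points) of raw per-second windows;
    for each candidate subset the matching rows are selected, min-max scaled
    per image, and classified with fivefold cross-validation. The same fold
    seed is reused for every subset so all comparisons share folds. ``kind``
    is ``mini`` (the CNN), a pixel-level baseline (``logreg``, ``svm``,
    ``rf``), or ``var`` — logistic regression on per-channel log-variance
    features, the classic band-power-style wrapper evaluator. ``var`` is the
    fast evaluator of choice when the class signal is an oscillation-power
    contrast: pixel-level linear models are blind to a pure variance
    difference, whereas log-variance features expose it directly.
    """
    index = {ch: i for i, ch in enumerate(channel_order)}
    y = np.asarray(labels)

    def encode(subset: tuple[str, ...]) -> np.ndarray:
        sub = tensor[:, [index[ch] for ch in subset], :]
        if kind == "var":
            return np.log(sub.var(axis=2) + 1e-12)
        lo = sub.min(axis=(1, 2), keepdims=True)
        hi = sub.max(axis=(1, 2), keepdims=True)
        scaled = np.floor((sub - lo) * 255.0 / np.where(hi > lo, hi - lo, 1.0) + 0.5)
        return np.repeat(scaled[:, None], 3, axis=1) / 255.0

    def factory_for(kind: str):
        if kind == "mini":
            cfg = model_config or ModelConfig(scale="mini", epochs=8, seed=seed)
            return lambda Xt, yt, Xv, yv: train_cnn(Xt, yt, cfg, Xv, yv)
        inner = "logreg" if kind == "var" else kind
        return lambda Xt, yt, Xv, yv: train_baseline(inner, Xt, yt, seed=seed)

    factory = factory_for(kind)

    def evaluator(subset: tuple[str, ...]) -> float:
        X = encode(tuple(subset))
        result = cross_validate(X, y, factory, k=k, seed=seed)
        return float(np.mean([m.accuracy for m in result.metrics]))

    return evaluator
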