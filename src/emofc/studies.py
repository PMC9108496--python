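"""Preconfigured desk-scale synthetic studies.

These functions bundle the study conditions used to validate the pipeline's
scientific claims on a workstation: each fixes a protocol, a plant, and an
analysis route, and returns the measured quantity. The full reference protocol
(15 subjects, 32 channels, 500 Hz) is used where the claim is about
protocol arithmetic; the statistical studies run on reduced montages and
sampling rates chosen so that repeated replication finishes in minutes while
the planted effects keep the same population values (coherence targets and
power contrasts are sampling-rate-free).
"""

from __future__ import annotations

import numpy as np

from .channel_select import (
    backward_select,
    exhaustive_select,
    frontal_subset,
    make_cv_evaluator,
)
from .classify import ModelConfig, make_folds, train_cnn
from .connectivity import (
    FCStatistics,
    compare_states,
    dynamic_classification_curve,
    trial_fc_matrix,
)
from .containers import HVA, LVA
from .image_features import segments_to_tensor, window_per_second
from .montage import FRONTAL_8, PREFRONTAL_3
from .preprocess import segment_and_baseline
from .synthetic import PlantSpec, ProtocolConfig, generate_subject

__all__ = [
    "count_per_class_samples",
    "fold_sizes_per_class",
    "planted_coherence_recovery_error",
    "fc_contrast_replicate",
    "fc_contrast_detection_rate",
    "sbs_planted_study",
    "dynamic_fc_accuracy_curve",
]

#: prefrontal coherence targets: LVA couples 0.05 above HVA
_PAIR_TARGETS = {HVA: 0.25, LVA: 0.30}


def _prefrontal_pairs() -> list[tuple[str, str, dict[str, float]]]:
    return [
        (a, b, dict(_PAIR_TARGETS))
        for a, b in (("Fp1", "Fp2"), ("Fp1", "Fpz"), ("Fpz", "Fp2"))
    ]


# ---------------------------------------------------------------------------
# Protocol arithmetic at full reference-protocol size
# ---------------------------------------------------------------------------


def count_per_class_samples(cfg: ProtocolConfig | None = None, plant: PlantSpec | None = None) -> dict[str, int]:
    """Per-second samples per class under the full protocol (one subject at a
    time to bound memory)."""
    cfg = cfg or ProtocolConfig()
    plant = plant or PlantSpec()
    counts = {HVA: 0, LVA: 0}
    for subject in range(cfg.n_subjects):
        rec = generate_subject(cfg, plant, subject)
        segs = segment_and_baseline(rec, stim_s=cfg.stim_s, baseline_s=cfg.rest_s)
        for seg in segs:
            counts[seg.label] += len(window_per_second(seg))
    return counts


def fold_sizes_per_class(n_per_class: int = 1800, k: int = 5) -> dict[str, int]:
    """Train/validation/test sizes per class under the k-fold rotation."""
    labels = np.array([HVA] * n_per_class + [LVA] * n_per_class)
    fold = make_folds(labels, k=k, seed=0)[0]
    hva = np.flatnonzero(labels == HVA)
    return {
        "train": int(np.isin(fold.train, hva).sum()),
        "val": int(np.isin(fold.val, hva).sum()),
        "test": int(np.isin(fold.test, hva).sum()),
    }


# ---------------------------------------------------------------------------
# Coherence parameter recovery
# ---------------------------------------------------------------------------


def planted_coherence_recovery_error(target: float = 0.8, dur_s: float = 200.0, seed: int = 29) -> float:
    """|estimate - target| for a planted pair on a long single-state realization."""
    from scipy import signal

    fs = 250.0
    cfg = ProtocolConfig(
        n_subjects=1, n_trials_per_class=1, rest_s=0.0, stim_s=dur_s, fs=fs,
        channel_labels=("Fp1", "Fpz", "Fp2", "F7"), seed=seed,
    )
    plant = PlantSpec(
        discriminative_channels=(),
        amplitude_effect=0.0,
        coherent_pairs=[("Fp1", "Fp2", {HVA: target, LVA: target})],
    )
    rec = generate_subject(cfg, plant, 0)
    f, cxy = signal.coherence(
        rec.data[0].astype(float), rec.data[2].astype(float), fs=fs, nperseg=int(fs)
    )
    band = (f >= 1.0) & (f <= 40.0)
    return float(abs(np.sqrt(cxy[band]).mean() - target))


# ---------------------------------------------------------------------------
# State contrast of prefrontal functional connectivity
# ---------------------------------------------------------------------------


def _fc_matrices_by_subject(seed: int, channels: tuple[str, ...], montage: tuple[str, ...],
                            fs: float = 128.0) -> dict[int, dict[str, list]]:
    cfg = ProtocolConfig(
        n_subjects=15, n_trials_per_class=6, rest_s=1.0, stim_s=20.0, fs=fs,
        channel_labels=montage, seed=seed,
    )
    plant = PlantSpec(
        discriminative_channels=(), amplitude_effect=0.0, coherent_pairs=_prefrontal_pairs()
    )
    mats: dict[int, dict[str, list]] = {}
    for s in range(cfg.n_subjects):
        rec = generate_subject(cfg, plant, s)
        segs = segment_and_baseline(rec, stim_s=cfg.stim_s, baseline_s=cfg.rest_s)
        mats[s] = {HVA: [], LVA: []}
        for seg in segs:
            mats[s][seg.label].append(trial_fc_matrix(seg, channels))
    return mats


def fc_contrast_replicate(seed: int) -> FCStatistics:
    """One 15-subject replicate of the prefrontal LVA-vs-HVA FC comparison."""
    mats = _fc_matrices_by_subject(seed, PREFRONTAL_3, ("Fp1", "Fpz", "Fp2", "F7"))
    return compare_states(mats)


def fc_contrast_detection_rate(n_replicates: int = 100, seed: int = 0) -> float:
    """Fraction of replicates detecting the planted LVA > HVA contrast (p < 0.05)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31))
        stats = fc_contrast_replicate(rep_seed)
        hits += (stats.p < 0.05) and (stats.mean_coherence[LVA] > stats.mean_coherence[HVA])
    return hits / n_replicates


# ---------------------------------------------------------------------------
# Backward channel selection on planted data
# ---------------------------------------------------------------------------

SBS_PLANTED = ("Fp1", "Fp2", "F7")


def sbs_planted_tensor(seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-second windows from a frontal montage with a strong power contrast
    (quadrupled oscillation power) confined to the planted channels."""
    cfg = ProtocolConfig(
        n_subjects=6, n_trials_per_class=5, rest_s=1.0, stim_s=20.0, fs=100.0,
        channel_labels=FRONTAL_8, seed=seed,
    )
    plant = PlantSpec(discriminative_channels=SBS_PLANTED, amplitude_effect=3.0, coherent_pairs=[])
    segments = []
    for s in range(cfg.n_subjects):
        rec = generate_subject(cfg, plant, s)
        segments += segment_and_baseline(rec, stim_s=cfg.stim_s, baseline_s=cfg.rest_s)
    tensor, labels = segments_to_tensor(segments, points_per_second=20)
    y = np.array([1 if lb == HVA else 0 for lb in labels])
    return tensor, y


def sbs_planted_study(seed: int, evaluator_kind: str = "var") -> dict:
    """Greedy backward search vs the exhaustive oracle on one planted dataset."""
    tensor, y = sbs_planted_tensor(seed)
    ev = make_cv_evaluator(tensor, y, FRONTAL_8, kind=evaluator_kind, k=5, seed=seed)
    trace = backward_select(frontal_subset(FRONTAL_8), ev, min_size=2, montage_order=FRONTAL_8)
    _, exhaustive_best = exhaustive_select(frontal_subset(FRONTAL_8), ev, min_size=2)
    return {
        "trace": trace,
        "exhaustive_best_accuracy": exhaustive_best,
        "matches_exhaustive": bool(abs(trace.best_accuracy - exhaustive_best) < 1e-9),
        "contains_planted": set(SBS_PLANTED) <= set(trace.best_subset),
    }


# ---------------------------------------------------------------------------
# Dynamic functional-connectivity classification curve
# ---------------------------------------------------------------------------


def dynamic_fc_accuracy_curve(seed: int, ks: tuple[int, ...] = (1, 6)) -> dict[int, float]:
    """Mean CV accuracy of the mini CNN on k-trial concatenated FC features."""
    mats = _fc_matrices_by_subject(seed, FRONTAL_8, FRONTAL_8)
    cfg_m = ModelConfig(scale="mini", epochs=40, learning_rate=3e-3, batch_size=8, seed=seed)
    curve = dynamic_classification_curve(
        mats, ks=ks,
        model_factory=lambda Xt, yt, Xv, yv: train_cnn(Xt, yt, cfg_m, Xv, yv),
        k_folds=5, seed=seed,
    )
    return {k: float(result.summary["accuracy"][0]) for k, result in curve.items()}
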