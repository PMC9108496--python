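"""Magnitude-coherence functional connectivity and its state comparison.

Coherence between channels x and y is estimated segment-wise: the trial is
cut into Hann-tapered segments (default 1 s, 50% overlap), each segment k
yields amplitude A(f, k) and phase phi(f, k) via the DFT, and

    Coh_xy(f) = | (1/n) sum_k A_x A_y exp(i (phi_x - phi_y)) |
                / sqrt( (1/n sum_k A_x^2) (1/n sum_k A_y^2) )

i.e. the magnitude of the averaged cross-spectrum normalized by the square
root of the product of the averaged power spectra. The scalar functional
connectivity of a pair is this quantity averaged over the analysis band
(default 1-40 Hz); it lies in [0, 1] by Cauchy-Schwarz and is invariant to
rescaling either signal.

Note the magnitude (not squared) coherence is used throughout, and the
Fisher r-to-z transform ``z = atanh(coh)`` is applied before averaging and
paired testing of the two emotion states, coherence being treated as a
correlation-like quantity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import CLASSES, CoherenceMatrix, ImageSample, TrialSegment
from .image_features import encode_fc_image

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralParams",
    "FCStatistics",
    "coherence_pair",
    "coherence_matrix_from_array",
    "trial_fc_matrix",
    "dynamic_fc_features",
    "dynamic_classification_curve",
    "compare_states",
]

_Z_CLIP = float(np.arctanh(1.0 - 1e-12))


@dataclass(frozen=True)
class SpectralParams:
    """Segmentation scheme behind the coherence estimator."""

    seg_len_s: float = 1.0
    overlap: float = 0.5
    band: tuple[float, float] = (1.0, 40.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")
        if self.seg_len_s <= 0:
            raise ValueError("seg_len_s must be positive")


def _segment_spectra(x: np.ndarray, nper: int, step: int) -> np.ndarray:
    """Hann-tapered DFT of each overlapping segment; rows are segments."""
    n_segs = 1 + (x.size - nper) // step
    window = np.hanning(nper)
    segs = np.stack([x[k * step : k * step + nper] for k in range(n_segs)])
    segs = (segs - segs.mean(axis=1, keepdims=True)) * window
    return np.fft.rfft(segs, axis=1)


def _coherence_spectrum(
    x: np.ndarray, y: np.ndarray, fs: float, params: SpectralParams
) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("signals must be equal-length 1-D arrays")
    nper = int(round(params.seg_len_s * fs))
    step = max(int(round(nper * (1.0 - params.overlap))), 1)
    if x.size < nper + step:
        raise ValueError(
            "signal too short for at least 2 segments; single-segment coherence is identically 1"
        )
    X = _segment_spectra(x, nper, step)
    Y = _segment_spectra(y, nper, step)
    cross = (X * np.conj(Y)).mean(axis=0)
    px = (np.abs(X) ** 2).mean(axis=0)
    py = (np.abs(Y) ** 2).mean(axis=0)
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(cross) / np.sqrt(px * py)
    coh = np.nan_to_num(coh, nan=0.0)
    return freqs, np.clip(coh, 0.0, 1.0)


def coherence_pair(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    seg_len_s: float = 1.0,
    overlap: float = 0.5,
    band: tuple[float, float] = (1.0, 40.0),
) -> float:
    """Band-averaged magnitude coherence of two equal-length signals."""
    params = SpectralParams(seg_len_s=seg_len_s, overlap=overlap, band=band)
    freqs, coh = _coherence_spectrum(x, y, fs, params)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError("analysis band contains no DFT frequency")
    return float(coh[mask].mean())


def coherence_matrix_from_array(
    data: np.ndarray,
    fs: float,
    channels: tuple[str, ...],
    params: SpectralParams = SpectralParams(),
    *,
    trial_index: int = 0,
    subject_id: int | None = None,
    label: str = "HVA",
) -> CoherenceMatrix:
    """All-pairs band-averaged coherence of a channels x samples array."""
    n = data.shape[0]
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            c = coherence_pair(
                data[i], data[j], fs,
                seg_len_s=params.seg_len_s, overlap=params.overlap, band=params.band,
            )
            values[i, j] = values[j, i] = c
    return CoherenceMatrix(
        values=values, channels=channels, band=params.band,
        trial_index=trial_index, subject_id=subject_id, label=label,
    )


def trial_fc_matrix(
    seg: TrialSegment,
    channels: tuple[str, ...],
    params: SpectralParams = SpectralParams(),
) -> CoherenceMatrix:
    """Per-trial functional-connectivity matrix over the requested channels."""
    data = seg.get_channels(channels)
    return coherence_matrix_from_array(
        data, seg.fs, tuple(channels), params,
        trial_index=seg.trial_index, subject_id=seg.subject_id, label=seg.label,
    )


def dynamic_fc_features(
    matrices_by_subject: dict[int, dict[str, list[CoherenceMatrix]]],
    k: int,
) -> list[ImageSample]:
    """Concatenate each subject/state's first ``k`` trials into one feature image.

    ``matrices_by_subject[subject][state]`` must list that subject's coherence
    matrices in chronological trial order. Subjects with fewer than ``k``
    trials for a state are skipped with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    features: list[ImageSample] = []
    for subject in sorted(matrices_by_subject):
        for state in CLASSES:
            mats = matrices_by_subject[subject].get(state, [])
            if len(mats) < k:
                logger.warning(
                    "subject %s has %d %s trials (< k=%d); skipped", subject, len(mats), state, k
                )
                continue
            features.append(encode_fc_image(mats[:k]))
    return features


def dynamic_classification_curve(
    matrices_by_subject: dict[int, dict[str, list[CoherenceMatrix]]],
    ks: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    model_factory=None,
    k_folds: int = 5,
    seed: int = 0,
) -> dict[int, "CVResult"]:
    """Cross-validated classification of k-trial concatenated FC features.

    For each k, the features from :func:`dynamic_fc_features` are classified
    under the k-fold rotation and the per-fold metrics returned. The default
    classifier is a logistic regression on the encoded pixels;
    ``model_factory(X_tr, y_tr, X_val, y_val) -> model`` overrides it. Fold
    counts are clamped to the per-class feature count.
    """
    from .classify import CVResult, cross_validate, images_to_arrays, train_baseline

    if model_factory is None:
        model_factory = lambda Xt, yt, Xv, yv: train_baseline("logreg", Xt, yt, seed=seed)
    out: dict[int, CVResult] = {}
    for k in ks:
        feats = dynamic_fc_features(matrices_by_subject, k)
        X, y = images_to_arrays(feats)
        per_class = min(int((y == c).sum()) for c in set(y))
        out[k] = cross_validate(
            X, y, model_factory, k=max(3, min(k_folds, per_class)), seed=seed
        )
    return out


@dataclass
class FCStatistics:
    """Paired comparison of mean functional connectivity between states."""

    subject_mean_z: dict[str, np.ndarray]
    mean_coherence: dict[str, float]
    sd_coherence: dict[str, float]
    t: float
    p: float


def _fisher_z(values: np.ndarray) -> np.ndarray:
    clipped = np.clip(values, 0.0, 1.0 - 1e-12)
    if np.any(values >= 1.0):
        logger.warning("coherence of 1 encountered; clipping before Fisher z")
    return np.minimum(np.arctanh(clipped), _Z_CLIP)


def compare_states(
    matrices_by_subject: dict[int, dict[str, list[CoherenceMatrix]]],
) -> FCStatistics:
    """Fisher-z mean FC per subject and state, compared by paired t-test.

    For each subject and state, every trial's upper-triangle coherences are
    Fisher-transformed and averaged into one scalar; the two per-subject
    scalars are compared across subjects with a paired t-test. Displayed
    means/SDs are back-transformed (tanh) to the coherence scale.
    """
    subjects = sorted(matrices_by_subject)
    per_state: dict[str, list[float]] = {s: [] for s in CLASSES}
    for subject in subjects:
        for state in CLASSES:
            mats = matrices_by_subject[subject].get(state)
            if not mats:
                raise ValueError(f"subject {subject} lacks {state} trials for a paired design")
            zs = np.concatenate([_fisher_z(m.upper_triangle()) for m in mats])
            per_state[state].append(float(zs.mean()))
    z = {s: np.asarray(v) for s, v in per_state.items()}
    if len(subjects) >= 2 and not np.allclose(z["HVA"], z["LVA"]):
        t, p = stats.ttest_rel(z["LVA"], z["HVA"])
    else:
        t, p = 0.0, 1.0
    back = {s: np.tanh(z[s]) for s in CLASSES}
    return FCStatistics(
        subject_mean_z=z,
        mean_coherence={s: float(back[s].mean()) for s in CLASSES},
        sd_coherence={s: float(back[s].std(ddof=1)) if len(subjects) > 1 else 0.0 for s in CLASSES},
        t=float(t),
        p=float(p),
    )
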