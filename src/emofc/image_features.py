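"""EEG-to-image encoding: per-second windows scaled to 8-bit pixel matrices.

Each stimulation second of a trial yields one channels x 20 matrix of evenly
spaced signal samples; min-max scaling maps it onto [0, 255] so the global
minimum becomes pixel 0 and the global maximum pixel 255. The grayscale
matrix is replicated into three identical planes where an RGB input is
expected. Scaling is per image over the whole matrix, so the encoding is
invariant to any positive affine transform of the underlying signal.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import CoherenceMatrix, ImageSample, SampleMatrix, TrialSegment

logger = logging.getLogger(__name__)

__all__ = ["window_per_second", "encode_image", "encode_fc_image", "segments_to_images"]


def window_per_second(
    seg: TrialSegment, points_per_second: int = 20, channels: tuple[str, ...] | None = None
) -> list[SampleMatrix]:
    """Split a stimulation epoch into per-second channels x points matrices.

    Within each one-second window, ``points_per_second`` samples are taken at a
    uniform stride of ``fs / points_per_second`` starting at the window's first
    sample (stride 25 at 500 Hz and 20 points). A non-integer stride falls back
    to nearest-sample indexing.
    """
    data = seg.get_channels(channels) if channels is not None else seg.data
    fs = seg.fs
    n_seconds = int(data.shape[1] / fs)
    stride = fs / points_per_second
    if abs(stride - round(stride)) > 1e-9:
        logger.info(
            "fs=%g not divisible by %d points/s; using nearest-sample indexing", fs, points_per_second
        )
    out = []
    for sec in range(n_seconds):
        base = sec * fs
        idx = np.rint(base + stride * np.arange(points_per_second)).astype(int)
        out.append(
            SampleMatrix(
                X=data[:, idx],
                label=seg.label,
                subject_id=seg.subject_id,
                trial_index=seg.trial_index,
                second=sec,
                channels=channels if channels is not None else seg.labels,
            )
        )
    return out


def _scale_to_pixels(X: np.ndarray) -> np.ndarray:
    lo, hi = float(X.min()), float(X.max())
    if hi == lo:
        logger.warning("constant-valued matrix: encoding to an all-zero image")
        return np.zeros(X.shape, dtype=np.uint8)
    # round half away from zero; arguments are >= 0 after the shift
    return np.floor((X - lo) * 255.0 / (hi - lo) + 0.5).astype(np.uint8)


def encode_image(sample: SampleMatrix) -> ImageSample:
    """Min-max scale a sample matrix onto integer pixels in [0, 255]."""
    X = np.asarray(sample.X, dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValueError("sample matrix contains non-finite values")
    return ImageSample(
        Y=_scale_to_pixels(X),
        label=sample.label,
        subject_id=sample.subject_id,
        trial_index=sample.trial_index,
        second=sample.second,
    )


def encode_fc_image(matrices: list[CoherenceMatrix]) -> ImageSample:
    """Concatenate per-trial coherence matrices side by side and pixel-scale.

    ``k`` chronological n x n matrices become one n x (n*k) image, the dynamic
    functional-connectivity feature of a subject/state.
    """
    if not matrices:
        raise ValueError("need at least one coherence matrix")
    channels = matrices[0].channels
    for m in matrices:
        if m.channels != channels:
            raise ValueError("coherence matrices have heterogeneous channel sets")
    wide = np.concatenate([m.values for m in matrices], axis=1)
    first = matrices[0]
    return ImageSample(
        Y=_scale_to_pixels(wide),
        label=first.label,
        subject_id=first.subject_id,
        trial_index=first.trial_index,
    )


def segments_to_tensor(
    segments: list[TrialSegment],
    points_per_second: int = 20,
    channels: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack all per-second windows into a raw (n, channels, points) tensor.

    Returns the unencoded tensor plus the per-window class labels; the tensor
    feeds evaluators that apply their own per-image scaling.
    """
    windows = [sm for seg in segments for sm in window_per_second(seg, points_per_second, channels)]
    X = np.stack([w.X for w in windows])
    labels = np.array([w.label for w in windows])
    return X, labels


def segments_to_images(
    segments: list[TrialSegment],
    points_per_second: int = 20,
    channels: tuple[str, ...] | None = None,
) -> list[ImageSample]:
    """Window every segment per second and encode each window to an image."""
    return [
        encode_image(sm)
        for seg in segments
        for sm in window_per_second(seg, points_per_second, channels)
    ]
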