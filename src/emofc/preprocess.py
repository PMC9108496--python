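"""Preprocessing chain: notch, bandpass, common average reference, segmentation.

The canonical order is notch -> bandpass -> CAR -> (optional artifact
regression) -> segment/baseline. Both filters are zero-phase (forward-backward
4th-order Butterworth), which preserves cross-channel phase relations and
therefore downstream coherence estimates.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import signal

from .containers import ConfigurationError, EEGRecording, TrialSegment
from .montage import ANALYSIS_30

logger = logging.getLogger(__name__)

__all__ = [
    "notch_filter",
    "bandpass_filter",
    "common_average_reference",
    "segment_and_baseline",
    "remove_artifact",
    "preprocess_recording",
]


def _filtfilt(rec: EEGRecording, sos: np.ndarray) -> EEGRecording:
    filtered = signal.sosfiltfilt(sos, rec.data.astype(np.float64), axis=-1)
    return rec.copy_with(filtered)


def notch_filter(rec: EEGRecording, stop_band: tuple[float, float] = (49.0, 51.0), order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-stop removing powerline interference."""
    lo, hi = stop_band
    if rec.fs <= 2 * hi:
        raise ConfigurationError(f"fs={rec.fs} too low for a {lo}-{hi} Hz notch")
    sos = signal.butter(order, [lo, hi], btype="bandstop", fs=rec.fs, output="sos")
    return _filtfilt(rec, sos)


def bandpass_filter(rec: EEGRecording, band: tuple[float, float] = (1.0, 40.0), order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass confining the signal to the analysis band."""
    lo, hi = band
    if rec.fs <= 2 * hi:
        raise ConfigurationError(f"fs={rec.fs} too low for a {lo}-{hi} Hz bandpass")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    return _filtfilt(rec, sos)


def common_average_reference(
    rec: EEGRecording, analysis_labels: Sequence[str] | None = None
) -> EEGRecording:
    """Re-reference each analysis channel against the instantaneous scalp mean.

    The mean is taken over the analysis channels only (reference electrodes
    such as M1/M2 are not scalp signals); non-analysis channels pass through
    unchanged.
    """
    if analysis_labels is None:
        analysis_labels = [ch for ch in ANALYSIS_30 if ch in rec.labels]
    analysis_labels = list(analysis_labels)
    if not analysis_labels:
        raise ConfigurationError("analysis_labels must be non-empty")
    idx = [rec.channel_index(ch) for ch in analysis_labels]
    data = rec.data.astype(np.float64).copy()
    data[idx] -= data[idx].mean(axis=0, keepdims=True)
    return rec.copy_with(data)


def segment_and_baseline(
    rec: EEGRecording, stim_s: float, baseline_s: float = 5.0
) -> list[TrialSegment]:
    """Cut one stimulation epoch per event and subtract its pre-stimulus mean.

    Events whose baseline or stimulation window would run off the recording
    edge are skipped with a warning rather than zero-padded.
    """
    n_stim = int(round(stim_s * rec.fs))
    n_base = int(round(baseline_s * rec.fs))
    segments: list[TrialSegment] = []
    for ev in rec.events:
        start, stop = ev.sample - n_base, ev.sample + n_stim
        if start < 0 or stop > rec.n_samples:
            logger.warning(
                "skipping trial %d of subject %s: window [%d, %d) exceeds recording bounds",
                ev.trial_index, rec.subject_id, start, stop,
            )
            continue
        baseline = rec.data[:, start:ev.sample].astype(np.float64)
        stim = rec.data[:, ev.sample:stop].astype(np.float64)
        mean = baseline.mean(axis=1, keepdims=True) if n_base else np.zeros((rec.n_channels, 1))
        segments.append(
            TrialSegment(
                data=stim - mean,
                baseline=baseline - mean,
                label=ev.label,
                subject_id=rec.subject_id,
                trial_index=ev.trial_index,
                fs=rec.fs,
                labels=rec.labels,
            )
        )
    return segments


def remove_artifact(rec: EEGRecording, reference_artifact: np.ndarray) -> EEGRecording:
    """Regress a recorded artifact waveform out of every channel.

    Each channel has its least-squares projection onto the (demeaned) artifact
    regressor removed, leaving residuals orthogonal to the artifact. This is an
    optional stage for ocular-artifact suppression when a reference waveform
    (e.g. an EOG channel) is available.
    """
    a = np.asarray(reference_artifact, dtype=np.float64)
    if a.ndim != 1 or a.size != rec.n_samples:
        raise ConfigurationError("artifact regressor length must match the recording")
    if np.var(a) == 0.0:
        raise ConfigurationError("artifact regressor has zero variance")
    # intercept + regressor, so a channel equal to the artifact regresses to zero
    design = np.column_stack([np.ones_like(a), a])
    data = rec.data.astype(np.float64)
    beta, *_ = np.linalg.lstsq(design, data.T, rcond=None)
    return rec.copy_with(data - (design @ beta).T)


def preprocess_recording(
    rec: EEGRecording,
    notch_band: tuple[float, float] = (49.0, 51.0),
    band: tuple[float, float] = (1.0, 40.0),
    analysis_labels: Sequence[str] | None = None,
    stim_s: float = 20.0,
    baseline_s: float = 5.0,
    artifact: np.ndarray | None = None,
) -> list[TrialSegment]:
    """Run the full chain on one recording and return its trial segments."""
    rec = notch_filter(rec, notch_band)
    rec = bandpass_filter(rec, band)
    rec = common_average_reference(rec, analysis_labels)
    if artifact is not None:
        rec = remove_artifact(rec, artifact)
    return segment_and_baseline(rec, stim_s=stim_s, baseline_s=baseline_s)
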