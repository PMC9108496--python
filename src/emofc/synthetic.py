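"""Synthetic music-evoked EEG with planted, analytically controlled structure.

The generator emulates a two-state (HVA vs LVA valence-arousal) musical
stimulation protocol: each subject receives ``2 * n_trials_per_class`` trials,
each a rest / stimulation / rest sequence, recorded on a 32-electrode 10-20
montage. Two kinds of class structure are planted into the stimulation
windows:

* an **amplitude contrast** — band-limited oscillations on a chosen channel
  subset carry more power under one emotion state than the other, giving the
  image classifier and the channel search something to find;
* a **coherence contrast** — selected channel pairs share a band-limited
  source whose mixing weight is solved in closed form so that the population
  magnitude coherence of the pair equals a per-class target, giving the
  functional-connectivity stage a known ground truth.

Signals are synthesized in the frequency domain: every window is an inverse
FFT of independent complex-Gaussian spectra with prescribed one-sided PSDs,
so band powers and pairwise coherences are exact population quantities rather
than byproducts of a time-domain recipe.

Closed form for the planted coherence: write channel ``a`` during stimulation
as ``a(t) = n_a(t) + w_a s(t)`` with ``s`` a shared unit-PSD source confined
to the analysis band and ``n_a`` everything else on the channel (1/f noise,
oscillations, other pairs' sources). With ``u = c / (1 - c)`` and

    w_a(f)^2 = u * N_a(f),    w_b(f)^2 = u * N_b(f),

where ``N_a`` is the PSD of ``n_a``, the magnitude coherence of the pair is

    Coh_ab(f) = w_a w_b / sqrt((N_a + w_a^2)(N_b + w_b^2))
              = u / (1 + u) = c

at every in-band frequency, regardless of any asymmetry between the two
channels' background PSDs. When several pairs share an endpoint the ``N``
terms depend on the other pairs' weights; a fixed-point iteration (a
contraction for c < 1) solves the coupled system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CLASSES, HVA, LVA, ConfigurationError, EEGRecording, Event
from .montage import FRONTAL_8, MONTAGE_32, PREFRONTAL_3

__all__ = [
    "ProtocolConfig",
    "PlantSpec",
    "SyntheticDataset",
    "generate_subject",
    "generate_dataset",
    "solve_pair_weights",
    "default_coherent_pairs",
]


@dataclass
class ProtocolConfig:
    """Experimental-protocol parameters of the synthetic recording session."""

    n_subjects: int = 15
    n_trials_per_class: int = 6
    rest_s: float = 5.0
    stim_s: float = 20.0
    fs: float = 500.0
    channel_labels: tuple[str, ...] = MONTAGE_32
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.n_trials_per_class < 1:
            raise ConfigurationError("n_trials_per_class must be >= 1")
        if self.fs <= 80:
            raise ConfigurationError(
                "fs must exceed 80 Hz to keep the 40 Hz analysis band below Nyquist"
            )
        if self.rest_s < 0 or self.stim_s <= 0:
            raise ConfigurationError("rest_s must be >= 0 and stim_s > 0")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ConfigurationError("channel_labels must be unique")

    @property
    def n_trials(self) -> int:
        return 2 * self.n_trials_per_class

    @property
    def trial_s(self) -> float:
        return 2 * self.rest_s + self.stim_s

    @property
    def duration_s(self) -> float:
        return self.n_trials * self.trial_s


def default_coherent_pairs() -> list[tuple[str, str, dict[str, float]]]:
    """Prefrontal pairs with stronger planted coherence under LVA than HVA."""
    return [
        (a, b, {HVA: 0.25, LVA: 0.35})
        for a, b in (("Fp1", "Fp2"), ("Fp1", "Fpz"), ("Fpz", "Fp2"))
    ]


@dataclass
class PlantSpec:
    """What class structure is planted into the stimulation windows.

    amplitude_effect is the multiplicative power contrast: oscillation power on
    discriminative channels is ``(1 + amplitude_effect)`` times larger under
    ``boosted_class`` than under the other state. coherent_pairs lists
    ``(label_a, label_b, {state: target coherence})`` triples; targets are
    band-averaged population magnitude coherences over ``coherence_band``.
    """

    discriminative_channels: tuple[str, ...] = FRONTAL_8
    amplitude_effect: float = 1.0
    boosted_class: str = HVA
    coherent_pairs: list[tuple[str, str, dict[str, float]]] = field(
        default_factory=default_coherent_pairs
    )
    noise_exponent: float = 1.0
    noise_std_uv: float = 10.0
    osc_bands: tuple[tuple[float, float, float], ...] = ((8.0, 13.0, 1.0), (18.0, 25.0, 0.5))
    osc_power_uv2: float = 25.0
    coherence_band: tuple[float, float] = (1.0, 40.0)
    eog_amplitude_uv: float = 0.0

    def __post_init__(self) -> None:
        self.discriminative_channels = tuple(self.discriminative_channels)
        if self.boosted_class not in CLASSES:
            raise ConfigurationError(f"boosted_class must be one of {CLASSES}")
        if self.amplitude_effect < 0:
            raise ConfigurationError("amplitude_effect must be >= 0")
        for a, b, targets in self.coherent_pairs:
            if a == b:
                raise ConfigurationError(f"coherent pair ({a}, {b}) is degenerate")
            for state, c in targets.items():
                if state not in CLASSES:
                    raise ConfigurationError(f"unknown state {state!r} in pair targets")
                if not 0.0 <= c < 1.0:
                    raise ConfigurationError(
                        f"target coherence {c} for pair ({a}, {b}) must lie in [0, 1)"
                    )

    def validate_against(self, cfg: ProtocolConfig) -> None:
        labels = set(cfg.channel_labels)
        missing = [ch for ch in self.discriminative_channels if ch not in labels]
        for a, b, _ in self.coherent_pairs:
            missing += [ch for ch in (a, b) if ch not in labels]
        if missing:
            raise ConfigurationError(
                f"plant references channels absent from the montage: {sorted(set(missing))}"
            )


# ---------------------------------------------------------------------------
# Spectral building blocks
# ---------------------------------------------------------------------------


def _noise_psd(freqs: np.ndarray, plant: PlantSpec, fs: float, n: int) -> np.ndarray:
    """One-sided 1/f background PSD calibrated to plant.noise_std_uv total RMS."""
    shape = np.zeros_like(freqs)
    pos = freqs > 0
    shape[pos] = 1.0 / np.maximum(freqs[pos], 1.0) ** plant.noise_exponent
    df = fs / n
    total = shape.sum() * df
    return shape * (plant.noise_std_uv**2 / total)


def _osc_psd(freqs: np.ndarray, plant: PlantSpec) -> np.ndarray:
    """One-sided PSD of the band-limited oscillations at unit class multiplier."""
    psd = np.zeros_like(freqs)
    for lo, hi, rel in plant.osc_bands:
        mask = (freqs >= lo) & (freqs <= hi)
        if mask.any():
            psd[mask] += rel * plant.osc_power_uv2 / (hi - lo)
    return psd


def _channel_background_psds(
    cfg: ProtocolConfig, plant: PlantSpec, label: str, freqs: np.ndarray, n: int
) -> np.ndarray:
    """Per-channel PSD of everything except the shared pair sources."""
    noise = _noise_psd(freqs, plant, cfg.fs, n)
    osc = _osc_psd(freqs, plant)
    mult = 1.0 + (plant.amplitude_effect if label == plant.boosted_class else 0.0)
    psds = np.empty((len(cfg.channel_labels), len(freqs)))
    disc = set(plant.discriminative_channels)
    for i, ch in enumerate(cfg.channel_labels):
        psds[i] = noise + osc * (mult if ch in disc else 1.0)
    return psds


def solve_pair_weights(
    cfg: ProtocolConfig, plant: PlantSpec, label: str, freqs: np.ndarray, n: int
) -> dict[int, dict[str, np.ndarray]]:
    """Solve the per-frequency mixing weights that realize the planted coherences.

    Returns one ``{channel_label: w(f)}`` dict per coherent pair, in pair
    order. For pairs that do not share an endpoint the closed form is exact
    after one iteration; shared endpoints couple the equations and are
    resolved by fixed-point iteration.
    """
    lo, hi = plant.coherence_band
    band = (freqs >= lo) & (freqs <= hi) & (freqs > 0)
    background = _channel_background_psds(cfg, plant, label, freqs, n)
    idx = {ch: i for i, ch in enumerate(cfg.channel_labels)}

    w2: list[dict[str, np.ndarray]] = [
        {a: np.zeros_like(freqs), b: np.zeros_like(freqs)}
        for a, b, _ in plant.coherent_pairs
    ]
    for _ in range(60):
        for p, (a, b, targets) in enumerate(plant.coherent_pairs):
            c = targets.get(label, 0.0)
            u = c / (1.0 - c)
            for ch in (a, b):
                other = np.zeros_like(freqs)
                for q, (qa, qb, _) in enumerate(plant.coherent_pairs):
                    if q != p and ch in (qa, qb):
                        other += w2[q][ch]
                w2[p][ch] = np.where(band, u * (background[idx[ch]] + other), 0.0)
    return [
        {ch: np.sqrt(w2[p][ch]) for ch in (a, b)}
        for p, (a, b, _) in enumerate(plant.coherent_pairs)
    ]


def _complex_spectrum(psd: np.ndarray, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Draw an rfft spectrum with ``E|Z_k|^2 = psd(f_k) * n * fs / 2``.

    ``irfft`` of the result is a real Gaussian signal whose one-sided PSD is
    ``psd`` (checked against Welch estimates in the test suite).
    """
    sigma = np.sqrt(psd * n * fs / 2.0)
    z = sigma * (rng.standard_normal(psd.shape) + 1j * rng.standard_normal(psd.shape))
    z /= np.sqrt(2.0)
    z[..., 0] = 0.0
    if n % 2 == 0:
        z[..., -1] = sigma[..., -1] * rng.standard_normal(psd.shape[:-1] or None)
    return z


def _synthesize_window(
    cfg: ProtocolConfig,
    plant: PlantSpec,
    label: str | None,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One window (rest: label None, or stimulation: class label) for all channels."""
    freqs = np.fft.rfftfreq(n, 1.0 / cfg.fs)
    n_ch = len(cfg.channel_labels)
    noise_psd = _noise_psd(freqs, plant, cfg.fs, n)

    if label is None:
        spectra = _complex_spectrum(np.broadcast_to(noise_psd, (n_ch, freqs.size)).copy(), n, cfg.fs, rng)
        return np.fft.irfft(spectra, n=n, axis=-1)

    background = _channel_background_psds(cfg, plant, label, freqs, n)
    spectra = _complex_spectrum(background, n, cfg.fs, rng)

    weights = solve_pair_weights(cfg, plant, label, freqs, n)
    idx = {ch: i for i, ch in enumerate(cfg.channel_labels)}
    unit_psd = np.where((freqs >= plant.coherence_band[0]) & (freqs <= plant.coherence_band[1]) & (freqs > 0), 1.0, 0.0)
    for p, (a, b, _) in enumerate(plant.coherent_pairs):
        source = _complex_spectrum(unit_psd, n, cfg.fs, rng)
        spectra[idx[a]] += weights[p][a] * source
        spectra[idx[b]] += weights[p][b] * source

    if plant.eog_amplitude_uv > 0:
        eog_psd = np.where((freqs >= 0.3) & (freqs <= 3.0), 1.0, 0.0)
        df = cfg.fs / n
        eog_psd *= plant.eog_amplitude_uv**2 / max(eog_psd.sum() * df, 1e-30)
        eog = _complex_spectrum(eog_psd, n, cfg.fs, rng)
        for ch, w in _eog_weights(cfg.channel_labels).items():
            spectra[idx[ch]] += w * eog
    return np.fft.irfft(spectra, n=n, axis=-1)


def _eog_weights(labels: tuple[str, ...]) -> dict[str, float]:
    """Frontally decaying projection of the ocular artifact source."""
    out: dict[str, float] = {}
    for ch in labels:
        if ch in PREFRONTAL_3:
            out[ch] = 1.0
        elif ch.startswith("F") and not ch.startswith("FT"):
            out[ch] = 0.4
    return out


# ---------------------------------------------------------------------------
# Recording- and dataset-level generation
# ---------------------------------------------------------------------------


def generate_subject(cfg: ProtocolConfig, plant: PlantSpec, subject_id: int) -> EEGRecording:
    """Generate one subject's continuous recording with stimulation events.

    Trials alternate between the two emotion states in a per-subject
    pseudo-random order (deterministic given ``cfg.seed`` and ``subject_id``);
    each trial is rest / stimulation / rest. Stimulation-onset events carry the
    class label and the chronological trial index.
    """
    plant.validate_against(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919 + subject_id]))

    labels_seq = np.array([HVA] * cfg.n_trials_per_class + [LVA] * cfg.n_trials_per_class)
    rng.shuffle(labels_seq)

    n_rest = int(round(cfg.rest_s * cfg.fs))
    n_stim = int(round(cfg.stim_s * cfg.fs))
    n_ch = len(cfg.channel_labels)

    chunks: list[np.ndarray] = []
    events: list[Event] = []
    cursor = 0
    for trial_index, lab in enumerate(labels_seq):
        if n_rest:
            chunks.append(_synthesize_window(cfg, plant, None, n_rest, rng))
            cursor += n_rest
        events.append(Event(sample=cursor, label=str(lab), trial_index=trial_index))
        chunks.append(_synthesize_window(cfg, plant, str(lab), n_stim, rng))
        cursor += n_stim
        if n_rest:
            chunks.append(_synthesize_window(cfg, plant, None, n_rest, rng))
            cursor += n_rest

    data = np.concatenate(chunks, axis=1).astype(np.float32) if chunks else np.zeros((n_ch, 0), np.float32)
    return EEGRecording(
        data=data, fs=cfg.fs, labels=cfg.channel_labels, events=events, subject_id=subject_id
    )


@dataclass
class SyntheticDataset:
    """All subjects' recordings plus a tidy event manifest."""

    recordings: list[EEGRecording]
    manifest: pd.DataFrame
    cfg: ProtocolConfig
    plant: PlantSpec


def generate_dataset(cfg: ProtocolConfig, plant: PlantSpec) -> SyntheticDataset:
    """Generate every subject and assemble the manifest (one row per trial)."""
    plant.validate_against(cfg)
    recordings = []
    rows = []
    for subject_id in range(cfg.n_subjects):
        rec = generate_subject(cfg, plant, subject_id)
        recordings.append(rec)
        for ev in rec.events:
            rows.append(
                {
                    "subject": subject_id,
                    "trial_index": ev.trial_index,
                    "label": ev.label,
                    "onset_sample": ev.sample,
                }
            )
    manifest = pd.DataFrame(rows, columns=["subject", "trial_index", "label", "onset_sample"])
    return SyntheticDataset(recordings=recordings, manifest=manifest, cfg=cfg, plant=plant)
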