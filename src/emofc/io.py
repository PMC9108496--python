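"""On-disk formats: the array container, a minimal EDF writer, PNG images.

The primary interchange format is the *array container*: a directory holding
``data.npy`` (channels x samples, float32 microvolts) plus a ``meta.json``
sidecar with channel labels, sampling rate, subject id and event markers.
Recordings can additionally be exported to EDF (16-bit European Data Format)
for use with standard EEG tooling; the EDF writer is implemented here
directly against the format specification, and its output is verified
against an independent EDF reader in the test suite. Event markers
accompany the EDF as a ``*.events.json`` sidecar.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGRecording, Event, ImageSample, TrialSegment

logger = logging.getLogger(__name__)

__all__ = [
    "save_recording",
    "load_recording",
    "save_segments",
    "load_segments",
    "write_edf",
    "read_edf",
    "save_images",
]


# ---------------------------------------------------------------------------
# Array container
# ---------------------------------------------------------------------------


def _events_to_json(events: list[Event]) -> list[dict]:
    return [{"sample": int(e.sample), "label": e.label, "trial_index": int(e.trial_index)} for e in events]


def _events_from_json(rows: list[dict]) -> list[Event]:
    return [Event(sample=r["sample"], label=r["label"], trial_index=r["trial_index"]) for r in rows]


def save_recording(rec: EEGRecording, out_dir: str | Path) -> Path:
    """Write a recording as ``data.npy`` + ``meta.json``; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "data.npy", rec.data.astype(np.float32))
    meta = {
        "labels": list(rec.labels),
        "fs": rec.fs,
        "subject_id": rec.subject_id,
        "events": _events_to_json(rec.events),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    return out


def load_recording(in_dir: str | Path) -> EEGRecording:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "meta.json").read_text())
    return EEGRecording(
        data=np.load(in_dir / "data.npy"),
        fs=meta["fs"],
        labels=tuple(meta["labels"]),
        events=_events_from_json(meta["events"]),
        subject_id=meta.get("subject_id"),
    )


def save_segments(segments: list[TrialSegment], out_dir: str | Path) -> Path:
    """Stack equally shaped trial segments into one container directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "segments.npy", np.stack([s.data for s in segments]).astype(np.float32))
    np.save(out / "baselines.npy", np.stack([s.baseline for s in segments]).astype(np.float32))
    meta = {
        "fs": segments[0].fs,
        "labels": list(segments[0].labels),
        "trials": [
            {"subject_id": s.subject_id, "trial_index": s.trial_index, "label": s.label}
            for s in segments
        ],
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    return out


def load_segments(in_dir: str | Path) -> list[TrialSegment]:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "meta.json").read_text())
    data = np.load(in_dir / "segments.npy")
    base = np.load(in_dir / "baselines.npy")
    return [
        TrialSegment(
            data=data[i],
            baseline=base[i],
            label=row["label"],
            subject_id=row["subject_id"],
            trial_index=row["trial_index"],
            fs=meta["fs"],
            labels=tuple(meta["labels"]),
        )
        for i, row in enumerate(meta["trials"])
    ]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------


def _fixed(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write the recording as 16-bit EDF with 1-second data records.

    The sampling rate must be an integer. Each channel is scaled to its own
    physical min/max over the full recording; a trailing partial second is
    dropped. Events are written to ``<path>.events.json`` alongside.
    """
    path = Path(path)
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_records = rec.n_samples // fs
    if n_records * fs != rec.n_samples:
        logger.warning("dropping trailing partial second in EDF export")
    ns = rec.n_channels
    data = rec.data[:, : n_records * fs].astype(np.float64)

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max <= phys_min
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.rint((data - phys_min[:, None]) / scale[:, None] + dig_min).astype("<i2")

    header = b"".join(
        [
            _fixed("0", 8),
            _fixed("X X X X", 80),
            _fixed("Startdate X X X X", 80),
            _fixed("01.01.00", 8),
            _fixed("00.00.00", 8),
            _fixed(str(256 * (ns + 1)), 8),
            _fixed("", 44),
            _fixed(str(n_records), 8),
            _fixed("1", 8),
            _fixed(str(ns), 4),
        ]
    )

    def col(values: list[str], width: int) -> bytes:
        return b"".join(_fixed(v, width) for v in values)

    def num(x: float) -> str:
        s = f"{x:.8g}"
        return s[:8]

    header += col([f"EEG {ch}" for ch in rec.labels], 16)
    header += col(["" for _ in range(ns)], 80)
    header += col(["uV"] * ns, 8)
    header += col([num(v) for v in phys_min], 8)
    header += col([num(v) for v in phys_max], 8)
    header += col([str(dig_min)] * ns, 8)
    header += col([str(dig_max)] * ns, 8)
    header += col(["" for _ in range(ns)], 80)
    header += col([str(fs)] * ns, 8)
    header += col(["" for _ in range(ns)], 32)

    with open(path, "wb") as fh:
        fh.write(header)
        # records are channel-sequential: all of channel 1's samples, then channel 2's ...
        records = digital.reshape(ns, n_records, fs).transpose(1, 0, 2)
        fh.write(records.tobytes())

    Path(str(path) + ".events.json").write_text(json.dumps(_events_to_json(rec.events), indent=1))
    return path


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF recording (via mne) plus the events sidecar if present."""
    import mne  # deferred: only EDF import needs it

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = tuple(ch.removeprefix("EEG ").strip() for ch in raw.ch_names)
    events: list[Event] = []
    sidecar = Path(str(path) + ".events.json")
    if sidecar.exists():
        events = _events_from_json(json.loads(sidecar.read_text()))
    return EEGRecording(
        data=raw.get_data() * 1e6,  # mne returns volts
        fs=float(raw.info["sfreq"]),
        labels=labels,
        events=events,
    )


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


def save_images(samples: list[ImageSample], out_dir: str | Path) -> pd.DataFrame:
    """Write each sample as an 8-bit grayscale PNG plus a manifest CSV."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        name = f"img_{i:05d}_s{s.subject_id}_t{s.trial_index}_{s.label}.png"
        Image.fromarray(s.Y.astype(np.uint8), mode="L").save(out / name)
        rows.append(
            {
                "path": name,
                "subject": s.subject_id,
                "trial": s.trial_index,
                "second": s.second,
                "label": s.label,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
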