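"""Electrode montage constants for the 32-channel 10-20 cap.

The montage lists 32 electrode labels in cap order, front to back. M1 and M2
(mastoids) are acquisition reference electrodes: they are recorded but carry
no scalp signal of interest, so every analysis stage works on the remaining
30 scalp channels.
"""

from __future__ import annotations

#: Full 32-electrode montage in row order (anterior to posterior).
MONTAGE_32: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "M1",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "M2",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)

#: Reference electrodes excluded from analysis.
REFERENCE_LABELS: tuple[str, ...] = ("M1", "M2")

#: The 30 scalp channels used in every analysis.
ANALYSIS_30: tuple[str, ...] = tuple(
    ch for ch in MONTAGE_32 if ch not in REFERENCE_LABELS
)

#: The eight frontal-region channels used for channel-subset optimization.
FRONTAL_8: tuple[str, ...] = ("Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8")

#: The three prefrontal channels where class-dependent coupling concentrates.
PREFRONTAL_3: tuple[str, ...] = ("Fp1", "Fpz", "Fp2")
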