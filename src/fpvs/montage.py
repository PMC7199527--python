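"""64-channel montage and occipital/occipito-temporal regions of interest."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MontageError(ValueError):
    pass


#: electrodes defining the three analysis ROIs
ROI_ELECTRODES = {
    "MO": ("Iz", "Oz", "POz"),
    "LOT": ("O1", "PO7", "P7", "P9"),
    "ROT": ("O2", "PO8", "P8", "P10"),
}

#: frontal channels used as the centre of the blink topography
FRONTAL = ("Fp1", "Fpz", "Fp2", "AF7", "AF8")


@dataclass(frozen=True)
class MontageSpec:
    """Channel labels with unit-sphere 3-D positions."""

    channel_labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm

    def __post_init__(self) -> None:
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise MontageError("channel labels must be unique")
        if self.positions.shape != (len(self.channel_labels), 3):
            raise MontageError("positions must be (n_channels, 3)")
        missing = [e for roi in ROI_ELECTRODES.values() for e in roi
                   if e not in self.channel_labels]
        if missing:
            raise MontageError(f"montage is missing ROI electrodes: {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise MontageError(f"unknown channel {label!r}") from None

    def indices(self, labels) -> np.ndarray:
        return np.array([self.index(l) for l in labels])

    def roi_indices(self, roi: str) -> np.ndarray:
        if roi not in ROI_ELECTRODES:
            raise MontageError(f"unknown ROI {roi!r}")
        return self.indices(ROI_ELECTRODES[roi])


def biosemi64() -> MontageSpec:
    """The standard BioSemi 64-electrode layout, positions on the unit sphere."""
    import mne

    m = mne.channels.make_standard_montage("biosemi64")
    pos = m.get_positions()["ch_pos"]
    labels = tuple(m.ch_names)
    xyz = np.array([pos[ch] for ch in labels], dtype=float)
    xyz -= xyz.mean(axis=0)  # re-centre before projecting onto the sphere
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    return MontageSpec(channel_labels=labels, positions=xyz)
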