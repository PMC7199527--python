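"""Continuous-recording container and file round-trip.

The in-memory container is a plain dataclass (channels × time in µV) so the
generator and the preprocessing stages stay free of heavy dependencies; disk
round-trips go through MNE's FIF format, which preserves channel names,
sampling rate and event annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import MontageSpec


@dataclass
class RawRecording:
    """Continuous multichannel EEG in microvolts.

    ``events`` is a list of ``(onset_seconds, label)`` pairs; for
    frequency-tagging runs the label is the condition of the sequence whose
    full-contrast plateau starts at that onset.
    """

    samples: np.ndarray  # (n_channels, n_times), µV
    fs: float
    montage: MontageSpec
    events: list[tuple[float, str]] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.shape[0] != self.montage.n_channels:
            raise ValueError("samples/montage channel mismatch")
        dur = self.samples.shape[1] / self.fs
        for onset, _ in self.events:
            if not 0 <= onset <= dur:
                raise ValueError(f"event at {onset} s outside recording")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.shape[1]) / self.fs


def _to_mne(rec: RawRecording):
    import mne

    info = mne.create_info(list(rec.montage.channel_labels), rec.fs, "eeg")
    raw = mne.io.RawArray(rec.samples * 1e-6, info, verbose="error")
    if rec.events:
        onsets = [t for t, _ in rec.events]
        raw.set_annotations(
            mne.Annotations(onset=onsets, duration=[0.0] * len(onsets),
                            description=[lab for _, lab in rec.events]))
    return raw


def write_recording(rec: RawRecording, path) -> None:
    """Write to a FIF file (lossless up to float32 quantization)."""
    path = str(path)
    if not path.endswith((".fif", ".fif.gz")):
        raise ValueError("write_recording writes FIF; path must end in .fif")
    _to_mne(rec).save(path, overwrite=True, verbose="error")


def read_recording(path, montage: MontageSpec | None = None) -> RawRecording:
    """Read a recording written by :func:`write_recording` (or any FIF)."""
    import mne

    raw = mne.io.read_raw_fif(str(path), preload=True, verbose="error")
    from .montage import biosemi64

    mont = montage if montage is not None else biosemi64()
    labels = tuple(raw.ch_names)
    if labels != mont.channel_labels:
        mont = MontageSpec(channel_labels=labels,
                           positions=mont.positions[mont.indices(labels)])
    events = [(float(on), str(desc))
              for on, desc in zip(raw.annotations.onset,
                                  raw.annotations.description)]
    return RawRecording(samples=raw.get_data() * 1e6, fs=float(raw.info["sfreq"]),
                        montage=mont, events=events)
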