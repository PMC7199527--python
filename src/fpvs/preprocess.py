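"""Sequence-locked segmentation and cleaning of continuous recordings.

Pipeline order is fixed: segment → band-pass filter → resample →
interpolate bad channels → common-average re-reference.  Each step appends
a provenance flag to the segment set so downstream stages can assert the
order was respected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .io import RawRecording
from .montage import MontageSpec

STEP_ORDER = ("segment", "bandpass", "resample", "interpolate", "rereference")


class TruncationError(ValueError):
    pass


class MetadataError(ValueError):
    pass


class FilterDesignError(ValueError):
    pass


class PipelineOrderError(RuntimeError):
    pass


@dataclass
class SegmentSet:
    """Sequence-locked segments (n_segments, n_channels, n_times) in µV.

    Times run from ``-pre`` to ``post_end`` seconds relative to the
    full-contrast (plateau) onset of each sequence; ``conditions`` holds
    one condition label per segment.
    """

    data: np.ndarray
    fs: float
    montage: MontageSpec
    conditions: tuple[str, ...]
    pre: float
    post: float = 0.0
    steps: tuple[str, ...] = ("segment",)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (n_segments, n_channels, n_times)")
        if len(self.conditions) != self.data.shape[0]:
            raise MetadataError("one condition label per segment required")

    @property
    def n_segments(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[2] / self.fs

    @property
    def times(self) -> np.ndarray:
        """Seconds relative to plateau onset."""
        return np.arange(self.data.shape[2]) / self.fs - self.pre

    def _advance(self, step: str) -> tuple[str, ...]:
        if STEP_ORDER.index(step) < max(STEP_ORDER.index(s) for s in self.steps):
            raise PipelineOrderError(
                f"step {step!r} must precede {self.steps[-1]!r}; "
                f"fixed order is {STEP_ORDER}")
        return self.steps + (step,)


def segment_sequences(rec: RawRecording, pre: float = 2.0,
                      post: float = 5.0,
                      plateau_duration: float = 60.0) -> SegmentSet:
    """Cut one segment per sequence event.

    Events mark the plateau (full-contrast) onset; each segment spans
    ``[-pre, plateau_duration + post]`` around it — the defaults give the
    67-s window (2 s before the 60-s plateau, 5 s after it).
    """
    if not rec.events:
        raise MetadataError("recording carries no sequence events")
    n_pre = int(round(pre * rec.fs))
    n_len = int(round((pre + plateau_duration + post) * rec.fs))
    segs, conds = [], []
    for onset, label in rec.events:
        if not label:
            raise MetadataError(f"event at {onset} s has no condition label")
        i0 = int(round(onset * rec.fs)) - n_pre
        if i0 < 0 or i0 + n_len > rec.samples.shape[1]:
            raise TruncationError(
                f"segment at {onset} s exceeds recording bounds")
        segs.append(rec.samples[:, i0:i0 + n_len])
        conds.append(label)
    return SegmentSet(data=np.stack(segs), fs=rec.fs, montage=rec.montage,
                      conditions=tuple(conds), pre=pre, post=post)


def bandpass(seg: SegmentSet, low: float = 0.1, high: float = 100.0,
             order: int = 4) -> SegmentSet:
    """Zero-phase Butterworth band-pass of every channel.

    ``order`` is the filter order of the underlying Butterworth design
    (applied forward and backward, so the effective attenuation doubles
    while stimulation-locked phase is preserved).
    """
    nyq = seg.fs / 2.0
    if not 0 < low < high:
        raise FilterDesignError("need 0 < low < high")
    if high >= nyq:
        raise FilterDesignError(f"high={high} Hz not below Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=seg.fs,
                        output="sos")
    out = signal.sosfiltfilt(sos, seg.data, axis=-1)
    return replace(seg, data=out, steps=seg._advance("bandpass"))


def resample(seg: SegmentSet, target_fs: float = 256.0) -> SegmentSet:
    """Polyphase downsampling (anti-aliasing FIR built in)."""
    if target_fs > seg.fs:
        raise ValueError("upsampling not supported")
    if target_fs == seg.fs:
        return replace(seg, steps=seg._advance("resample"))
    from fractions import Fraction

    frac = Fraction(target_fs / seg.fs).limit_denominator(1000)
    out = signal.resample_poly(seg.data, frac.numerator, frac.denominator,
                               axis=-1)
    return replace(seg, data=out, fs=target_fs, steps=seg._advance("resample"))


class BadChannelError(ValueError):
    pass


def interpolate_bad_channels(seg: SegmentSet, bad: list[str],
                             montage: MontageSpec | None = None,
                             max_fraction: float = 0.05) -> SegmentSet:
    """Replace each bad channel by an inverse-distance weighted mean of its
    three nearest good neighbors (3-D electrode distance).

    At most ``max_fraction`` of the channels (5% — three of 64) may be
    interpolated.
    """
    montage = montage or seg.montage
    if not bad:
        return replace(seg, steps=seg._advance("interpolate"))
    limit = int(np.floor(max_fraction * montage.n_channels))
    if len(bad) > limit:
        raise BadChannelError(
            f"{len(bad)} bad channels exceeds the {limit}-channel (5%) limit")
    bad_idx = montage.indices(bad)
    good = np.setdiff1d(np.arange(montage.n_channels), bad_idx)
    out = seg.data.copy()
    for bi in bad_idx:
        d = np.linalg.norm(montage.positions[good] - montage.positions[bi],
                           axis=1)
        order = np.argsort(d)[:3]
        if np.any(d[order] == 0):
            raise BadChannelError("duplicate electrode positions")
        w = 1.0 / d[order]
        w /= w.sum()
        out[:, bi, :] = np.einsum("j,sjt->st", w, seg.data[:, good[order], :])
    return replace(seg, data=out, steps=seg._advance("interpolate"))


class ReferenceError_(ValueError):
    pass


def rereference_average(seg: SegmentSet) -> SegmentSet:
    """Common average reference: subtract the instantaneous channel mean."""
    if seg.n_channels < 2:
        raise ReferenceError_("average reference needs >= 2 channels")
    out = seg.data - seg.data.mean(axis=1, keepdims=True)
    return replace(seg, data=out, steps=seg._advance("rereference"))


def preprocess_recording(rec: RawRecording, pre: float = 2.0, post: float = 5.0,
                         plateau_duration: float = 60.0,
                         low: float = 0.1, high: float = 100.0, order: int = 4,
                         target_fs: float = 256.0,
                         bad_channels: list[str] | None = None) -> SegmentSet:
    """The full cleaning chain in its fixed order."""
    seg = segment_sequences(rec, pre=pre, post=post,
                            plateau_duration=plateau_duration)
    seg = bandpass(seg, low=low, high=high, order=order)
    seg = resample(seg, target_fs=target_fs)
    seg = interpolate_bad_channels(seg, bad_channels or [])
    return rereference_average(seg)
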