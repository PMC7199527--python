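"""High-resolution amplitude spectra and the three local-noise statistics.

After condition averaging, segments are cropped to a whole number of
base-frequency cycles (1.5 Hz for 6/7.5 Hz tagging) so both stimulation
rates and all their harmonics fall exactly on FFT bins.  Response strength
at a bin is then expressed relative to its local noise neighborhood:

* SNR           = amplitude / mean(noise bins)          (dimensionless)
* baseline      = amplitude − mean(noise bins)          (µV, summable)
* z-score       = (amplitude − mean) / SD(noise bins)   (significance)

The default neighborhood takes 12 bins on each side of the target (24),
drops the bin directly adjacent on each side (leakage guard) and the
single largest and single smallest of the remaining 22, leaving 20 bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import SegmentSet


class CroppingError(ValueError):
    pass


class GridError(ValueError):
    pass


class NeighborhoodError(ValueError):
    pass


class UndefinedStatisticError(ZeroDivisionError):
    pass


# ---------------------------------------------------------------------------
# cropping and averaging


def whole_cycle_samples(fs: float, base_frequency: float) -> int:
    """Smallest block of whole base-frequency cycles that is also a whole
    number of samples (3 cycles = 512 samples at 256 Hz and 1.5 Hz)."""
    from fractions import Fraction

    ratio = (Fraction(base_frequency).limit_denominator(10 ** 6)
             / Fraction(fs).limit_denominator(10 ** 6))
    return ratio.denominator


def crop_integer_cycles(seg: SegmentSet, base_frequency: float,
                        max_duration: float | None = None) -> SegmentSet:
    """Crop each segment to whole base-frequency cycles after fade-in.

    The window starts at plateau onset (segment time 0) and keeps the
    largest whole number of cycle blocks — each a whole number of samples —
    that fits in ``max_duration`` seconds (default: everything up to the
    end of the segment minus the trailing post-window, i.e. the plateau).
    """
    block = whole_cycle_samples(seg.fs, base_frequency)
    i0 = int(round(seg.pre * seg.fs))
    if max_duration is None:
        # default to the plateau: everything between fade-in end and the
        # post-window (which contains the fade-out)
        max_duration = seg.duration - seg.pre - seg.post
    avail = min(seg.data.shape[2] - i0, int(round(max_duration * seg.fs)))
    n_blocks = avail // block
    if n_blocks < 1:
        raise CroppingError(
            f"no whole {base_frequency} Hz cycle block of {block} samples "
            f"fits in the {avail}-sample window")
    n_keep = n_blocks * block
    out = seg.data[:, :, i0:i0 + n_keep]
    return replace(seg, data=out, pre=0.0, post=0.0)


def average_condition(seg: SegmentSet) -> dict[str, np.ndarray]:
    """Time-domain mean per condition (phase-preserving noise reduction).

    Returns ``{condition: (n_channels, n_times)}``; averaging segments with
    identical stimulation phase leaves the steady-state response intact
    while out-of-phase background shrinks by roughly 1/sqrt(n).
    """
    out = {}
    for cond in dict.fromkeys(seg.conditions):
        idx = [i for i, c in enumerate(seg.conditions) if c == cond]
        out[cond] = seg.data[idx].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# spectra


@dataclass
class AmplitudeSpectrum:
    """One-sided amplitude spectrum per channel, scaled so a pure sinusoid
    of amplitude A at a bin frequency reads A in ``amps``."""

    freqs: np.ndarray  # (n_bins,)
    amps: np.ndarray   # (n_channels, n_bins), µV
    fs: float

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    @property
    def T(self) -> float:
        """Analyzed duration in seconds (1/Δf)."""
        return 1.0 / self.df

    @property
    def n_samples(self) -> int:
        return int(round(self.fs / self.df))

    def bin_of(self, freq: float, tol_fraction: float = 0.01) -> int:
        """Index of the bin at ``freq``; errors if it misses the grid by
        more than ``tol_fraction``·Δf (no silent snapping)."""
        b = freq / self.df
        bi = int(round(b))
        if abs(b - bi) > tol_fraction or not 0 <= bi < self.freqs.size:
            raise GridError(f"{freq} Hz is not a bin center (Δf={self.df:g})")
        return bi


def fft_amplitude(avg: np.ndarray, fs: float) -> AmplitudeSpectrum:
    """FFT amplitude spectrum of an averaged segment (channels × time)."""
    avg = np.atleast_2d(avg)
    n = avg.shape[1]
    if n == 0:
        raise ValueError("empty input")
    spec = np.fft.rfft(avg, axis=1)
    amps = np.abs(spec) * (2.0 / n)
    amps[:, 0] /= 2.0
    if n % 2 == 0:
        amps[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return AmplitudeSpectrum(freqs=freqs, amps=amps, fs=fs)


# ---------------------------------------------------------------------------
# local-noise statistics


@dataclass(frozen=True)
class NoiseNeighborhood:
    """Which bins around a target count as its local noise."""

    side_width: int = 12
    n_adjacent_excluded: int = 2   # one bin on each side of the target
    n_extreme_excluded: int = 2    # single max and single min

    def __post_init__(self) -> None:
        if self.n_adjacent_excluded % 2 or self.n_adjacent_excluded < 0:
            raise ValueError("adjacent exclusion is symmetric (even count)")
        if self.n_extreme_excluded % 2 or self.n_extreme_excluded < 0:
            raise ValueError("extreme exclusion drops max/min pairs")
        if self.n_bins < 1:
            raise ValueError("no noise bins left")

    @property
    def n_bins(self) -> int:
        return (2 * self.side_width - self.n_adjacent_excluded
                - self.n_extreme_excluded)

    def candidate_offsets(self) -> np.ndarray:
        """Offsets from the target of the post-adjacency candidate bins."""
        guard = self.n_adjacent_excluded // 2
        side = np.arange(guard + 1, self.side_width + 1)
        return np.concatenate([-side[::-1], side])


def noise_bin_values(amps_1d: np.ndarray, target_bin: int,
                     hood: NoiseNeighborhood) -> np.ndarray:
    """The retained noise-bin amplitudes around ``target_bin``.

    From 12 bins on each side, the bin adjacent to the target on each side
    is dropped, then the single largest and single smallest of the
    remaining values (ties broken toward lower frequency).
    """
    offs = hood.candidate_offsets()
    idx = target_bin + offs
    if idx.min() < 0 or idx.max() >= amps_1d.size:
        raise NeighborhoodError(
            f"target bin {target_bin} too close to the spectrum edge")
    vals = amps_1d[idx]
    keep = np.ones(vals.size, dtype=bool)
    for _ in range(hood.n_extreme_excluded // 2):
        live = np.flatnonzero(keep)
        keep[live[np.argmax(vals[live])]] = False
        live = np.flatnonzero(keep)
        keep[live[np.argmin(vals[live])]] = False
    return vals[keep]


def local_noise(spec: AmplitudeSpectrum, target_bin: int,
                hood: NoiseNeighborhood = NoiseNeighborhood()
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel (mean, SD) over the retained noise bins (sample SD)."""
    means = np.empty(spec.amps.shape[0])
    sds = np.empty(spec.amps.shape[0])
    for ch in range(spec.amps.shape[0]):
        vals = noise_bin_values(spec.amps[ch], target_bin, hood)
        means[ch] = vals.mean()
        sds[ch] = vals.std(ddof=1)
    return means, sds


@dataclass
class SpectralStatistic:
    """SNR, baseline-corrected amplitude or z-score at target bins."""

    kind: str  # 'snr' | 'baseline_corrected' | 'zscore'
    freqs: np.ndarray          # (n_targets,)
    values: np.ndarray         # (n_channels, n_targets)
    neighborhood: NoiseNeighborhood


def _targets_to_bins(spec: AmplitudeSpectrum, target_freqs) -> np.ndarray:
    return np.array([spec.bin_of(f) for f in np.atleast_1d(target_freqs)])


def snr_spectrum(spec: AmplitudeSpectrum, target_freqs,
                 hood: NoiseNeighborhood = NoiseNeighborhood()
                 ) -> SpectralStatistic:
    """Amplitude divided by the local-noise mean at each target frequency."""
    bins = _targets_to_bins(spec, target_freqs)
    vals = np.empty((spec.amps.shape[0], bins.size))
    for j, b in enumerate(bins):
        mean, _ = local_noise(spec, b, hood)
        if np.any(mean <= 0):
            raise UndefinedStatisticError(
                f"noise mean is zero at {spec.freqs[b]:g} Hz")
        vals[:, j] = spec.amps[:, b] / mean
    return SpectralStatistic("snr", spec.freqs[bins], vals, hood)


def baseline_corrected(spec: AmplitudeSpectrum, target_freqs,
                       hood: NoiseNeighborhood = NoiseNeighborhood()
                       ) -> SpectralStatistic:
    """Amplitude minus the local-noise mean, in µV (may be negative)."""
    bins = _targets_to_bins(spec, target_freqs)
    vals = np.empty((spec.amps.shape[0], bins.size))
    for j, b in enumerate(bins):
        mean, _ = local_noise(spec, b, hood)
        vals[:, j] = spec.amps[:, b] - mean
    return SpectralStatistic("baseline_corrected", spec.freqs[bins], vals, hood)


def zscore_spectrum(spec: AmplitudeSpectrum, target_freqs,
                    hood: NoiseNeighborhood = NoiseNeighborhood()
                    ) -> SpectralStatistic:
    """(amplitude − noise mean) / noise SD at each target frequency."""
    bins = _targets_to_bins(spec, target_freqs)
    vals = np.empty((spec.amps.shape[0], bins.size))
    for j, b in enumerate(bins):
        mean, sd = local_noise(spec, b, hood)
        if np.any(sd == 0):
            raise UndefinedStatisticError(
                f"noise SD is zero at {spec.freqs[b]:g} Hz")
        vals[:, j] = (spec.amps[:, b] - mean) / sd
    return SpectralStatistic("zscore", spec.freqs[bins], vals, hood)


def spectrum_table(spec: AmplitudeSpectrum, target_freqs,
                   hood: NoiseNeighborhood = NoiseNeighborhood()):
    """Long-format table (freq, channel, amplitude, snr, baseline, zscore)."""
    import pandas as pd

    snr = snr_spectrum(spec, target_freqs, hood)
    bc = baseline_corrected(spec, target_freqs, hood)
    z = zscore_spectrum(spec, target_freqs, hood)
    rows = []
    for j, f in enumerate(snr.freqs):
        for ch in range(spec.amps.shape[0]):
            rows.append(dict(freq=float(f), channel=ch,
                             amplitude=float(spec.amps[ch, spec.bin_of(f)]),
                             snr=float(snr.values[ch, j]),
                             baseline_corrected=float(bc.values[ch, j]),
                             zscore=float(z.values[ch, j])))
    return pd.DataFrame(rows)


def plot_snr(spec: AmplitudeSpectrum, channel_idx, fmin: float = 5.0,
             fmax: float = 8.0, hood: NoiseNeighborhood = NoiseNeighborhood(),
             ax=None):
    """SNR spectrum of the mean over ``channel_idx``, for figure-style QC."""
    import matplotlib.pyplot as plt

    roi_amp = spec.amps[np.atleast_1d(channel_idx)].mean(axis=0, keepdims=True)
    roi = AmplitudeSpectrum(spec.freqs, roi_amp, spec.fs)
    lo = int(np.ceil(fmin / spec.df))
    hi = int(np.floor(fmax / spec.df))
    # restrict to bins with a full neighborhood
    lo = max(lo, hood.side_width)
    hi = min(hi, spec.freqs.size - hood.side_width - 1)
    freqs = roi.freqs[lo:hi + 1]
    snr = snr_spectrum(roi, freqs, hood).values[0]
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(freqs, snr, lw=0.7)
    ax.set(xlabel="frequency (Hz)", ylabel="SNR")
    return ax
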