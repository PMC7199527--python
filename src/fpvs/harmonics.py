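"""Harmonic selection, summed responses, and individual significance.

The steady-state response is spread over harmonics of each stimulation
rate.  Harmonics are selected once, on group-level data: grand-averaged
amplitude spectra are z-scored against their local noise and consecutive
harmonics are retained while z > 2.32 (p < .01).  The two rates then get
an equal number of harmonics, and harmonics shared by both rates (30 Hz
for 6 and 7.5 Hz) are excluded.  Per subject, condition and ROI the
baseline-corrected amplitudes at the retained harmonics are summed into a
single µV response; its significance is assessed by summing mini-spectra
centered on each harmonic and z-scoring the center bin (z > 1.64,
one-tailed p < .05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import ROI_ELECTRODES, MontageSpec
from .spectral import (AmplitudeSpectrum, NeighborhoodError,
                       NoiseNeighborhood, baseline_corrected,
                       noise_bin_values, zscore_spectrum)

Z_GROUP = 2.32       # group-level harmonic selection, p < .01
Z_INDIVIDUAL = 1.64  # individual significance, one-tailed p < .05
#: extraction half-width (bins per side) of the individual mini-spectra
INDIVIDUAL_SIDE_WIDTH = 20


class QuantificationError(ValueError):
    pass


@dataclass(frozen=True)
class ROIDefinition:
    name: str
    electrodes: tuple[str, ...]


def default_rois() -> list[ROIDefinition]:
    return [ROIDefinition(name, tuple(els))
            for name, els in ROI_ELECTRODES.items()]


@dataclass
class HarmonicSet:
    """Retained harmonic frequencies of one stimulation rate."""

    rate: float
    harmonics: tuple[float, ...]
    z_threshold: float = Z_GROUP
    shared_excluded: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.harmonics, self.harmonics[1:])):
            raise ValueError("harmonics must be strictly increasing")

    @property
    def n_retained(self) -> int:
        return len(self.harmonics)


def select_harmonics_group(group_spectrum: AmplitudeSpectrum, rate: float,
                           z_threshold: float = Z_GROUP,
                           hood: NoiseNeighborhood = NoiseNeighborhood(),
                           max_harmonic: int = 16) -> HarmonicSet:
    """Walk harmonics k=1,2,… of ``rate`` on a grand-averaged ROI spectrum
    (one row) and retain consecutive harmonics with z above threshold,
    stopping at the first non-significant one."""
    if group_spectrum.amps.shape[0] != 1:
        raise ValueError("expected a single grand-averaged spectrum row")
    kept: list[float] = []
    for k in range(1, max_harmonic + 1):
        f = k * rate
        if f >= group_spectrum.freqs[-1] - hood.side_width * group_spectrum.df:
            break
        z = zscore_spectrum(group_spectrum, [f], hood).values[0, 0]
        if z > z_threshold:
            kept.append(f)
        else:
            break
    return HarmonicSet(rate=rate, harmonics=tuple(kept),
                       z_threshold=z_threshold)


def _is_shared(freq: float, rate_a: float, rate_b: float,
               tol: float = 1e-9) -> bool:
    ra = freq / rate_a
    rb = freq / rate_b
    return abs(ra - round(ra)) < tol and abs(rb - round(rb)) < tol


def equalize_and_exclude(set_a: HarmonicSet, set_b: HarmonicSet
                         ) -> tuple[HarmonicSet, HarmonicSet]:
    """Drop harmonics shared by both rates, then truncate both sets to the
    shorter length so each rate contributes equally."""
    shared_a = tuple(f for f in set_a.harmonics
                     if _is_shared(f, set_a.rate, set_b.rate))
    shared_b = tuple(f for f in set_b.harmonics
                     if _is_shared(f, set_a.rate, set_b.rate))
    ha = tuple(f for f in set_a.harmonics if f not in shared_a)
    hb = tuple(f for f in set_b.harmonics if f not in shared_b)
    if not ha or not hb:
        raise QuantificationError("a harmonic set is empty after exclusion")
    n = min(len(ha), len(hb))
    return (HarmonicSet(set_a.rate, ha[:n], set_a.z_threshold, shared_a),
            HarmonicSet(set_b.rate, hb[:n], set_b.z_threshold, shared_b))


def default_harmonic_sets() -> tuple[HarmonicSet, HarmonicSet]:
    """The 6/7.5 Hz selection: {6, 12, 18} and {7.5, 15, 22.5} Hz."""
    a = HarmonicSet(6.0, (6.0, 12.0, 18.0, 24.0, 30.0))
    b = HarmonicSet(7.5, (7.5, 15.0, 22.5, 30.0))
    return equalize_and_exclude(a, b)


# ---------------------------------------------------------------------------
# summed responses


@dataclass
class SummedResponse:
    subject: str
    condition: str
    category: str
    roi: str
    amplitude_uv: float
    harmonics: HarmonicSet


def roi_spectrum(spec: AmplitudeSpectrum, montage: MontageSpec,
                 roi: ROIDefinition) -> AmplitudeSpectrum:
    """Average the amplitude spectrum across the ROI's electrodes."""
    idx = montage.indices(roi.electrodes)
    return AmplitudeSpectrum(spec.freqs, spec.amps[idx].mean(axis=0,
                                                             keepdims=True),
                             spec.fs)


def sum_harmonics(spec: AmplitudeSpectrum, hset: HarmonicSet,
                  roi: ROIDefinition, montage: MontageSpec,
                  hood: NoiseNeighborhood = NoiseNeighborhood()) -> float:
    """ROI-averaged baseline-corrected amplitude summed across harmonics.

    Averaging across electrodes and summing across harmonics commute; both
    orders are computed and asserted equal.
    """
    idx = montage.indices(roi.electrodes)
    bc = baseline_corrected(spec, list(hset.harmonics), hood)
    per_channel_sums = bc.values[idx].sum(axis=1)     # sum then average
    roi_then_sum = bc.values[idx].mean(axis=0).sum()  # average then sum
    total = float(per_channel_sums.mean())
    assert np.isclose(total, roi_then_sum, rtol=1e-10, atol=1e-12)
    return total


# ---------------------------------------------------------------------------
# individual significance


@dataclass
class IndividualSignificance:
    subject: str
    category: str
    roi: str
    z: float
    significant: bool
    threshold: float = Z_INDIVIDUAL


def summed_segment_z(spectra: list[AmplitudeSpectrum],
                     harmonic_lists: list[tuple[float, ...]],
                     roi: ROIDefinition, montage: MontageSpec,
                     side_width: int = INDIVIDUAL_SIDE_WIDTH,
                     hood: NoiseNeighborhood = NoiseNeighborhood()) -> float:
    """The four-step individual z statistic.

    1. average each raw amplitude spectrum across the ROI electrodes;
    2. cut mini-spectra of ±``side_width`` bins centered on every target
       harmonic (one list of harmonics per spectrum, so both counterbalanced
       conditions can contribute their own target frequencies);
    3. sum the mini-spectra element-wise;
    4. z-score the center bin of the summed mini-spectrum against its
       surrounding bins, applying the usual exclusions (bins adjacent to
       the center, then the most extreme values).
    """
    segments = []
    for spec, harms in zip(spectra, harmonic_lists):
        rspec = roi_spectrum(spec, montage, roi)
        for f in harms:
            b = rspec.bin_of(f)
            if b - side_width < 0 or b + side_width >= rspec.freqs.size:
                raise NeighborhoodError(f"harmonic {f} Hz too close to edge")
            segments.append(rspec.amps[0, b - side_width:b + side_width + 1])
    if not segments:
        raise QuantificationError("no harmonics to sum")
    summed = np.sum(segments, axis=0)
    wide = NoiseNeighborhood(side_width=side_width,
                             n_adjacent_excluded=hood.n_adjacent_excluded,
                             n_extreme_excluded=hood.n_extreme_excluded)
    noise = noise_bin_values(summed, side_width, wide)
    sd = noise.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("noise SD is zero in summed segment")
    return float((summed[side_width] - noise.mean()) / sd)


def individual_significance(spectra: list[AmplitudeSpectrum],
                            harmonic_lists: list[tuple[float, ...]],
                            roi: ROIDefinition, montage: MontageSpec,
                            subject: str = "", category: str = "",
                            threshold: float = Z_INDIVIDUAL,
                            side_width: int = INDIVIDUAL_SIDE_WIDTH,
                            hood: NoiseNeighborhood = NoiseNeighborhood()
                            ) -> IndividualSignificance:
    """Significant iff the summed-segment z strictly exceeds ``threshold``."""
    z = summed_segment_z(spectra, harmonic_lists, roi, montage,
                         side_width=side_width, hood=hood)
    return IndividualSignificance(subject=subject, category=category,
                                  roi=roi.name, z=z,
                                  significant=bool(z > threshold),
                                  threshold=threshold)


# ---------------------------------------------------------------------------
# per-subject quantification table


def quantify_subject(spectra_by_condition: dict[str, AmplitudeSpectrum],
                     design, hsets: dict[float, HarmonicSet],
                     montage: MontageSpec,
                     rois: list[ROIDefinition] | None = None,
                     subject: str = "", group: str = "",
                     hood: NoiseNeighborhood = NoiseNeighborhood()
                     ) -> pd.DataFrame:
    """Summed responses and individual z per stimulus × rate × ROI.

    Returns one row per (category, rate, ROI): the summed baseline-corrected
    amplitude from the condition in which that category ran at that rate,
    plus the pooled individual z (both conditions' harmonics summed).
    """
    rois = rois or default_rois()
    rows = []
    for roi in rois:
        for cat in ("faces", "houses"):
            spec_list, harm_list = [], []
            for cond in design.conditions:
                rate = design.rate_of(cat, cond)
                spec_list.append(spectra_by_condition[cond])
                harm_list.append(hsets[rate].harmonics)
            sig = individual_significance(spec_list, harm_list, roi, montage,
                                          subject=subject, category=cat,
                                          hood=hood)
            for cond in design.conditions:
                rate = design.rate_of(cat, cond)
                amp = sum_harmonics(spectra_by_condition[cond], hsets[rate],
                                    roi, montage, hood)
                rows.append(dict(subject=subject, group=group, stimulus=cat,
                                 rate=rate, roi=roi.name, amplitude_uv=amp,
                                 z_individual=sig.z,
                                 significant=sig.significant))
    return pd.DataFrame(rows)
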