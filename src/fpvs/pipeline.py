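"""End-to-end drivers: recording → spectra → response table → statistics.

Cohorts are processed one subject at a time (a 64-channel 512-Hz run is
~75 MB); only the ROI electrodes' amplitude spectra — everything the
quantification uses — are kept per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StimulusDesign, make_design
from .harmonics import (HarmonicSet, default_rois, equalize_and_exclude,
                        quantify_subject, select_harmonics_group)
from .io import RawRecording
from .montage import ROI_ELECTRODES, MontageSpec, biosemi64
from .preprocess import preprocess_recording, segment_sequences
from .simulate import SubjectSpec, cohort_specs, simulate_subject_eeg
from .spectral import (AmplitudeSpectrum, NoiseNeighborhood,
                       average_condition, crop_integer_cycles, fft_amplitude)

ROI_CHANNELS = tuple(e for roi in ROI_ELECTRODES.values() for e in roi)


def roi_montage(montage: MontageSpec) -> MontageSpec:
    """Sub-montage holding only the 11 ROI electrodes."""
    idx = montage.indices(ROI_CHANNELS)
    return MontageSpec(channel_labels=ROI_CHANNELS,
                       positions=montage.positions[idx])


def subject_spectra(rec: RawRecording, design: StimulusDesign,
                    bad_channels: list[str] | None = None,
                    apply_preprocessing: bool = True,
                    target_fs: float = 256.0,
                    keep_waveforms: bool = False):
    """Per-condition amplitude spectra of one subject's recording.

    Runs the fixed cleaning chain (optionally skipped for generator-level
    studies where the signal is already band-limited), crops to whole base
    cycles of the plateau, averages per condition in the time domain and
    FFTs.  Returns ``{condition: AmplitudeSpectrum}`` restricted to the
    ROI electrodes (plus the averaged waveforms if requested).
    """
    if apply_preprocessing:
        seg = preprocess_recording(
            rec, plateau_duration=design.full_contrast_duration,
            target_fs=target_fs, bad_channels=bad_channels)
    else:
        seg = segment_sequences(rec,
                                plateau_duration=design.full_contrast_duration)
    seg = crop_integer_cycles(seg, design.base_frequency)
    avg = average_condition(seg)
    idx = seg.montage.indices(ROI_CHANNELS)
    spectra = {c: fft_amplitude(w[idx], seg.fs) for c, w in avg.items()}
    if keep_waveforms:
        waves = {c: w[idx] for c, w in avg.items()}
        return spectra, waves, seg.fs
    return spectra


def grand_average_spectrum(all_spectra: list[dict],
                           montage: MontageSpec) -> AmplitudeSpectrum:
    """Grand average across subjects, conditions and the ROI electrodes —
    the group-level spectrum on which harmonics are selected."""
    first = next(iter(all_spectra[0].values()))
    acc = np.zeros(first.freqs.size)
    n = 0
    for per_cond in all_spectra:
        for spec in per_cond.values():
            acc += spec.amps.mean(axis=0)
            n += 1
    return AmplitudeSpectrum(first.freqs, (acc / n)[None, :], first.fs)


def select_harmonic_sets(grand: AmplitudeSpectrum, design: StimulusDesign,
                         hood: NoiseNeighborhood = NoiseNeighborhood()
                         ) -> dict[float, HarmonicSet]:
    """Group-level selection for both rates, equalized, shared excluded."""
    sa = select_harmonics_group(grand, design.f1, hood=hood)
    sb = select_harmonics_group(grand, design.f2, hood=hood)
    sa, sb = equalize_and_exclude(sa, sb)
    return {design.f1: sa, design.f2: sb}


@dataclass
class CohortRun:
    """Everything the group statistics need from one simulated cohort."""

    response: pd.DataFrame
    subjects: pd.DataFrame
    hsets: dict
    grand: AmplitudeSpectrum
    design: StimulusDesign
    montage: MontageSpec          # ROI sub-montage matching the spectra
    spectra: list[dict] = field(repr=False, default_factory=list)
    waveforms: list[dict] = field(repr=False, default_factory=list)
    ground_truth: list = field(repr=False, default_factory=list)
    fs: float = 256.0


def run_cohort(specs: list[SubjectSpec], groups: dict[str, str] | None = None,
               design: StimulusDesign | None = None,
               montage: MontageSpec | None = None, fs: float = 512.0,
               apply_preprocessing: bool = True,
               keep_waveforms: bool = False,
               keep_ground_truth: bool = False,
               subjects: pd.DataFrame | None = None) -> CohortRun:
    """Simulate and analyze a cohort subject by subject."""
    design = design or make_design()
    montage = montage or biosemi64()
    sub_mont = roi_montage(montage)
    all_spectra, all_waves, gts = [], [], []
    for spec in specs:
        rec, gt = simulate_subject_eeg(spec, design, montage, fs)
        out = subject_spectra(rec, design,
                              apply_preprocessing=apply_preprocessing,
                              keep_waveforms=keep_waveforms)
        if keep_waveforms:
            spectra, waves, out_fs = out
            all_waves.append(waves)
        else:
            spectra = out
        all_spectra.append(spectra)
        if keep_ground_truth:
            gts.append(gt)
        del rec

    grand = grand_average_spectrum(all_spectra, sub_mont)
    hsets = select_harmonic_sets(grand, design)
    rows = []
    for spec, spectra in zip(specs, all_spectra):
        rows.append(quantify_subject(spectra, design, hsets, sub_mont,
                                     subject=spec.subject_id,
                                     group=spec.group))
    response = pd.concat(rows, ignore_index=True)
    if subjects is None:
        subjects = pd.DataFrame([dict(subject=s.subject_id, group=s.group,
                                      srs_t=s.srs_t) for s in specs])
    out_fs = all_spectra[0][design.condition_a].fs
    return CohortRun(response=response, subjects=subjects, hsets=hsets,
                     grand=grand, design=design, montage=sub_mont,
                     spectra=all_spectra, waveforms=all_waves,
                     ground_truth=gts, fs=out_fs)


def simulate_and_run(n_per_group: int, effects=None, seed: int = 0,
                     fs: float = 512.0, apply_preprocessing: bool = True,
                     keep_waveforms: bool = False,
                     keep_ground_truth: bool = False) -> CohortRun:
    """Convenience wrapper: draw a cohort and run the full pipeline."""
    design = make_design()
    specs, table = cohort_specs(n_per_group, effects, seed, design)
    run = run_cohort(specs, design=design, fs=fs,
                     apply_preprocessing=apply_preprocessing,
                     keep_waveforms=keep_waveforms,
                     keep_ground_truth=keep_ground_truth, subjects=table)
    return run


def quantify_waveforms_at_length(run: CohortRun, length: float
                                 ) -> pd.DataFrame:
    """Re-quantify a cohort from its averaged waveforms using only the
    first ``length`` seconds after fade-in (whole-cycle cropped)."""
    from .preprocess import SegmentSet
    from .spectral import whole_cycle_samples

    block = whole_cycle_samples(run.fs, run.design.base_frequency)
    n_keep = int(int(round(length * run.fs)) // block) * block
    if n_keep < block:
        raise ValueError(f"{length} s holds no whole base cycle block")
    rows = []
    for subj, waves in zip(run.subjects.itertuples(), run.waveforms):
        spectra = {c: fft_amplitude(w[:, :n_keep], run.fs)
                   for c, w in waves.items()}
        rows.append(quantify_subject(spectra, run.design, run.hsets,
                                     run.montage, subject=subj.subject,
                                     group=subj.group))
    return pd.concat(rows, ignore_index=True)


def cohort_time_course(run: CohortRun, lengths=tuple(range(5, 65, 5)),
                       pool_hemispheres: bool = False):
    """Time-course analysis of a cohort run (needs ``keep_waveforms``)."""
    from .stats import time_course

    if not run.waveforms:
        raise ValueError("run was created without keep_waveforms=True")
    return time_course(lambda L: quantify_waveforms_at_length(run, L),
                       lengths=lengths, pool_hemispheres=pool_hemispheres)
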