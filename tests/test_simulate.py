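"""Generator contracts: spectral fidelity, determinism, group structure."""

import numpy as np
import pytest

from fpvs.design import make_design
from fpvs.harmonics import default_harmonic_sets, default_rois, sum_harmonics
from fpvs.montage import MontageError
from fpvs.pipeline import roi_montage, subject_spectra
from fpvs.simulate import (AliasingError, SchedulingError, SubjectSpec,
                           channel_amplitudes, cohort_specs, null_effects,
                           study_effects, simulate_cohort,
                           simulate_subject_eeg, simulate_task_events)

ZERO = {"MO": 0.0, "LOT": 0.0, "ROT": 0.0}


def test_null_generator_is_silent(design, montage):
    spec = SubjectSpec("z", noise_scale=0.0, blink_rate=0.0,
                       face_zone_sums=dict(ZERO), house_zone_sums=dict(ZERO),
                       seed=0)
    rec, gt = simulate_subject_eeg(spec, design, montage, fs=256.0)
    assert np.all(rec.samples == 0.0)
    assert len(rec.events) == design.n_sequences


def test_blinks_only_are_frontal(design, montage):
    spec = SubjectSpec("b", noise_scale=0.0, blink_rate=0.36,
                       face_zone_sums=dict(ZERO), house_zone_sums=dict(ZERO),
                       seed=1)
    rec, _ = simulate_subject_eeg(spec, design, montage, fs=256.0)
    rms = np.sqrt((rec.samples ** 2).mean(axis=1))
    assert rms[montage.index("Fpz")] > 10 * rms[montage.index("Oz")]


def test_injected_amplitudes_exact_on_fft_bins(design, montage,
                                               noiseless_subject):
    """Noiseless injection: the FFT of the plateau reads back every injected
    harmonic amplitude within 1e-6 and ~0 elsewhere (whole-cycle window)."""
    _, _, gt, spectra = noiseless_subject
    sub = roi_montage(montage)
    for cond_i, cond in enumerate(design.conditions):
        spec = spectra[cond]
        seq = design.condition_of_sequence.index(cond)
        for cat in ("faces", "houses"):
            amps = gt.amplitudes[(seq, cat)][montage.indices(sub.channel_labels)]
            freqs = gt.harmonic_freqs[(seq, cat)]
            for k, f in enumerate(freqs):
                if f % 6.0 == 0 and f % 7.5 == 0:
                    continue  # 30 Hz: both streams superpose there
                got = spec.amps[:, spec.bin_of(f)]
                assert np.allclose(got, np.abs(amps[:, k]), atol=1e-6)
        # a non-harmonic bin stays at the numerical floor
        assert spec.amps[:, spec.bin_of(9.0)].max() < 1e-9


def test_linearity_of_injection_and_recovery(design, montage):
    """Scaling all injected amplitudes by c scales every summed
    baseline-corrected estimate by c (noiseless case)."""
    sub = roi_montage(montage)
    h6, h75 = default_harmonic_sets()
    lot = [r for r in default_rois() if r.name == "LOT"][0]
    results = []
    for c in (1.0, 2.5):
        spec = SubjectSpec(
            "lin", noise_scale=0.0, blink_rate=0.0,
            face_zone_sums={z: c * v for z, v in
                            (("MO", 1.44), ("LOT", 1.32), ("ROT", 1.26))},
            house_zone_sums={z: c * v for z, v in
                             (("MO", 1.82), ("LOT", 0.75), ("ROT", 0.91))},
            seed=5)
        rec, _ = simulate_subject_eeg(spec, design, montage, fs=256.0)
        spectra = subject_spectra(rec, design, apply_preprocessing=False)
        results.append(sum_harmonics(spectra[design.condition_a], h6, lot, sub))
    assert results[1] == pytest.approx(2.5 * results[0], rel=1e-9)


def test_td_default_face_response_larger_laterally(noiseless_subject, design,
                                                   montage):
    """TD defaults: the LOT face-rate fundamental exceeds the house one."""
    _, _, gt, spectra = noiseless_subject
    sub = roi_montage(montage)
    spec = spectra[design.condition_a]  # faces at 6 Hz
    lot = sub.roi_indices("LOT")
    faces = spec.amps[lot, spec.bin_of(6.0)].mean()
    houses = spec.amps[lot, spec.bin_of(7.5)].mean()
    assert faces > houses


def test_ground_truth_stores_prefade_plateau_values(noiseless_subject,
                                                    design, montage):
    _, _, gt, _ = noiseless_subject
    for (seq, cat), freqs in gt.harmonic_freqs.items():
        rate = design.rate_of(cat, design.condition_of_sequence[seq])
        assert np.allclose(freqs / rate, np.round(freqs / rate))


def test_aliasing_guard(design, montage):
    with pytest.raises(AliasingError):
        simulate_subject_eeg(SubjectSpec("a", seed=0), design, montage,
                             fs=50.0)


def test_unknown_zone_rejected(montage):
    with pytest.raises(MontageError):
        channel_amplitudes({"XX": 1.0}, montage)


def test_channel_amplitudes_hit_roi_targets_and_are_car_invariant(montage):
    targets = {"MO": 1.9, "LOT": 0.3, "ROT": 1.1}
    amps = channel_amplitudes(targets, montage)
    assert abs(amps.mean()) < 1e-12  # invariant under average reference
    for zone, t in targets.items():
        roi_amps = amps[montage.roi_indices(zone)]
        assert np.allclose(roi_amps, t)
        assert roi_amps.min() >= 0


def test_cohort_determinism(design, montage):
    a, ta = simulate_cohort(1, seed=3, design=design, montage=montage,
                            fs=256.0)
    b, tb = simulate_cohort(1, seed=3, design=design, montage=montage,
                            fs=256.0)
    assert ta.equals(tb)
    for (ra, _), (rb, _) in zip(a, b):
        assert np.array_equal(ra.samples, rb.samples)


def test_cohort_group_structure(design):
    """Injected LOT face−house difference ≈ 0.57 µV in TD, ≈ 0.19 in ASD."""
    specs, table = cohort_specs(150, seed=9, design=design)
    diffs = {"TD": [], "ASD": []}
    srs = {"TD": [], "ASD": []}
    for s in specs:
        diffs[s.group].append(np.mean(s.face_zone_sums["LOT"])
                              - np.mean(s.house_zone_sums["LOT"]))
        srs[s.group].append(s.srs_t)
    assert np.mean(diffs["TD"]) == pytest.approx(0.57, abs=0.08)
    assert np.mean(diffs["ASD"]) == pytest.approx(0.19, abs=0.08)
    assert np.mean(srs["ASD"]) == pytest.approx(85, abs=3)
    assert np.mean(srs["TD"]) == pytest.approx(42, abs=2)
    assert len(table) == 300


def test_null_effects_make_groups_exchangeable():
    specs, _ = cohort_specs(50, null_effects(), seed=2)
    m = {"TD": [], "ASD": []}
    for s in specs:
        m[s.group].append(np.mean(s.face_zone_sums["LOT"]))
    assert np.mean(m["TD"]) == pytest.approx(np.mean(m["ASD"]), abs=0.2)


def test_task_events_counts_and_accuracy(design):
    ev = simulate_task_events(design, 1.0, 0.46, seed=0)
    assert (ev.groupby("sequence").size() == design.n_color_changes).all()
    assert ev.responded.all()
    ev0 = simulate_task_events(design, 0.0, 0.46, seed=0)
    assert not ev0.responded.any()
    # events never overlap
    for _, g in ev.groupby("sequence"):
        assert np.diff(np.sort(g.onset.to_numpy())).min() >= 1.0


def test_task_mean_hit_rate_matches_accuracy(design):
    hits = [simulate_task_events(design, 0.971, 0.46, seed=s).responded.mean()
            for s in range(50)]
    assert np.mean(hits) == pytest.approx(0.971, abs=0.01)


def test_task_scheduling_error_when_overcrowded(design):
    with pytest.raises(SchedulingError):
        simulate_task_events(design, 1.0, 0.46, seed=0, min_separation=10.0)
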