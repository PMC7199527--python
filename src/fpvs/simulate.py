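"""Synthetic steady-state EEG cohorts with known ground truth.

The generator emulates the frequency-tagging experiment: two superimposed
stimulation streams (faces and houses) tagged at 6 and 7.5 Hz, four 64-s
sequences (60 s full contrast flanked by 2-s fades), counterbalanced
rate-to-category mapping, 64-channel recordings at 512 Hz with 1/f
background noise and frontal blink transients.

Steady-state responses are injected as sums of sinusoids at harmonics of
each stream's rate, with category-specific parametric topographies: the
face response peaks over lateral occipito-temporal cortex, the house
response over medial occipital cortex.  Injected amplitudes are specified
as ROI-level targets (the quantity the downstream analysis estimates) and
converted to per-channel amplitudes by solving a small linear system, so
the ROI average of the injected topography matches the target exactly.

Group structure mirrors the study cohort: typically-developing (TD)
subjects have laterally differentiated face responses (faces > houses over
occipito-temporal ROIs, the reverse medially), autism-spectrum (ASD)
subjects have undifferentiated responses; SRS T-scores are drawn per group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StimulusDesign, make_design
from .io import RawRecording
from .montage import FRONTAL, ROI_ELECTRODES, MontageSpec, MontageError, biosemi64

ZONES = ("MO", "LOT", "ROT")

#: group-level summed (3-harmonic) baseline-corrected amplitude targets, µV
GROUP_CELL_MEANS = {
    "TD": {"faces": {"LOT": 1.32, "ROT": 1.26, "MO": 1.44},
           "houses": {"LOT": 0.75, "ROT": 0.91, "MO": 1.82}},
    "ASD": {"faces": {"LOT": 0.95, "ROT": 0.95, "MO": 1.30},
            "houses": {"LOT": 0.76, "ROT": 0.77, "MO": 1.49}},
}

#: SRS T-score distributions (mean, SD) per group
SRS_PARAMS = {"ASD": (85.0, 12.0), "TD": (42.0, 6.0)}

#: behavioral defaults per group: (accuracy mean, accuracy SD, RT mean, RT SD)
BEHAVIOR_PARAMS = {"ASD": (0.97, 0.06, 0.47, 0.07), "TD": (0.971, 0.039, 0.46, 0.04)}

#: harmonic roll-off A_k = A_1 * DECAY**(k-1)
HARMONIC_DECAY = 0.5
#: highest injected harmonic frequency (Hz); K = floor(limit / rate)
HARMONIC_LIMIT_HZ = 30.0
#: number of harmonics the quantification sums
N_SUMMED_HARMONICS = 3
#: fraction of a unit fundamental carried by the summed harmonics (1+1/2+1/4)
SUMMED_FRACTION = sum(HARMONIC_DECAY ** k for k in range(N_SUMMED_HARMONICS))

#: background-noise RMS, µV (broadband 1/f + white floor).  Default gives
#: per-bin noise amplitudes of ~0.009 µV at 6 Hz after condition
#: averaging, keeping the inherent noise-floor subtraction bias of
#: baseline-corrected amplitudes (≈ −Σ_k µ_k per summed response, ~0.02 µV
#: over three harmonics) within a few percent even for weak ~0.3 µV cells,
#: so the generator's ROI-level targets are what the pipeline measures.
#: The bias itself is a property of the statistic; see the methods note.
DEFAULT_NOISE_SCALE = 1.0
DEFAULT_BLINK_RATE = 0.36  # events per second
#: between-condition lognormal SD of per-cell summed amplitudes, µV
#: (the residual variability implied by the reported group statistics)
AMP_SD = 0.5
#: per-subject multiplicative gain CV (overall response strength)
SUBJECT_GAIN_CV = 0.25

LEAD_SECONDS = 3.0
GAP_SECONDS = 5.0
TAIL_SECONDS = 6.0


class AliasingError(ValueError):
    pass


class SchedulingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# topography helpers


def zone_weights(montage: MontageSpec, sigma: float = 0.3) -> np.ndarray:
    """(n_channels, 3) spatial profiles, one per ROI zone.

    Each profile is exactly 1 on the zone's own electrodes, exactly 0 on
    the other zones' electrodes, and a Gaussian tail (chord distance from
    the zone centroid, width ``sigma``) elsewhere.  The flat top keeps
    injected ROI-electrode amplitudes non-negative for any non-negative
    zone targets; the zeros prevent cross-talk between the measured ROIs.
    """
    W = np.empty((montage.n_channels, len(ZONES)))
    all_roi = {i for z in ZONES for i in montage.roi_indices(z)}
    for j, zone in enumerate(ZONES):
        idx = montage.roi_indices(zone)
        centroid = montage.positions[idx].mean(axis=0)
        d = np.linalg.norm(montage.positions - centroid, axis=1)
        w = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
        w[list(all_roi - set(idx.tolist()))] = 0.0
        w[idx] = 1.0
        W[:, j] = w
    return W


def roi_average_matrix(montage: MontageSpec) -> np.ndarray:
    """(3, n_channels) matrix averaging channels within each ROI zone."""
    R = np.zeros((len(ZONES), montage.n_channels))
    for j, zone in enumerate(ZONES):
        idx = montage.roi_indices(zone)
        R[j, idx] = 1.0 / len(idx)
    return R


def channel_amplitudes(zone_targets: dict[str, float],
                       montage: MontageSpec) -> np.ndarray:
    """Per-channel signed amplitudes whose ROI averages equal ``zone_targets``.

    The injected field is demeaned across channels (scalp fields are
    zero-mean dipolar patterns, and this makes the injection invariant
    under common-average re-referencing).  Because demeaning shifts every
    channel by the global mean m̄, the zone targets are raised by m̄ first
    — a closed form, since m̄ = Σ t'_z·mean(b_z) is linear in the raised
    targets t'.  The result has amplitude exactly ``zone_targets[z]`` on
    zone z's electrodes and small negative far-field values elsewhere
    (phase-inverted sinusoids).
    """
    unknown = set(zone_targets) - set(ZONES)
    if unknown:
        raise MontageError(f"unknown ROI zone(s) {sorted(unknown)}")
    t = np.array([zone_targets.get(z, 0.0) for z in ZONES])
    if not np.any(t):
        return np.zeros(montage.n_channels)
    B = zone_weights(montage)
    mu = B.mean(axis=0)
    mbar = (t @ mu) / (1.0 - mu.sum())
    return B @ (t + mbar) - mbar


def n_harmonics(rate: float, limit: float = HARMONIC_LIMIT_HZ) -> int:
    """Number of injected harmonics: all k with k*rate <= limit."""
    return int(math.floor(limit / rate + 1e-9))


# ---------------------------------------------------------------------------
# subject specification and ground truth


@dataclass
class SubjectSpec:
    """Everything needed to realize one synthetic subject.

    ``face_zone_sums``/``house_zone_sums`` give the target summed
    (3-harmonic) baseline-corrected amplitude per ROI zone, either one
    value per zone (same in both counterbalanced conditions) or one value
    per condition (arrays of length ``n_conditions``).
    """

    subject_id: str
    group: str = "TD"
    srs_t: float = 42.0
    face_zone_sums: dict = field(
        default_factory=lambda: dict(GROUP_CELL_MEANS["TD"]["faces"]))
    house_zone_sums: dict = field(
        default_factory=lambda: dict(GROUP_CELL_MEANS["TD"]["houses"]))
    noise_scale: float = DEFAULT_NOISE_SCALE
    blink_rate: float = DEFAULT_BLINK_RATE
    accuracy: float = 0.971
    mean_rt: float = 0.46
    seed: int = 0

    def zone_sum(self, category: str, condition_index: int) -> dict[str, float]:
        src = self.face_zone_sums if category == "faces" else self.house_zone_sums
        out = {}
        for zone, v in src.items():
            v = np.atleast_1d(np.asarray(v, dtype=float))
            out[zone] = float(v[condition_index % len(v)])
            if out[zone] < 0:
                raise ValueError("injected amplitudes must be non-negative")
        return out


@dataclass
class GroundTruth:
    """Injected parameters of one realized subject.

    ``amplitudes[(seq_index, category)]`` is the (n_channels, K) array of
    per-harmonic sinusoid amplitudes at full contrast (pre-fade plateau
    values); ``phases[(category, k)]`` the subject-stable phase;
    ``harmonic_freqs[(seq_index, category)]`` the injected frequencies.
    """

    subject_id: str
    amplitudes: dict = field(default_factory=dict)
    phases: dict = field(default_factory=dict)
    harmonic_freqs: dict = field(default_factory=dict)
    accuracy: float = float("nan")
    mean_rt: float = float("nan")

    def injected_roi_sum(self, montage: MontageSpec, category: str,
                         condition: str, design: StimulusDesign,
                         roi: str, n_harm: int = N_SUMMED_HARMONICS) -> float:
        """ROI-averaged injected amplitude summed over the first harmonics,
        averaged over the sequences of ``condition`` (the quantity the
        pipeline's summed baseline-corrected response estimates)."""
        idx = montage.roi_indices(roi)
        vals = []
        for s, cond in enumerate(design.condition_of_sequence):
            if cond != condition:
                continue
            amp = self.amplitudes[(s, category)]
            vals.append(amp[idx, :n_harm].mean(axis=0).sum())
        return float(np.mean(vals))


# ---------------------------------------------------------------------------
# noise and artifacts


def pink_noise(n_channels: int, n_times: int, fs: float, rng,
               alpha: float = 1.0, white_floor: float = 0.1) -> np.ndarray:
    """Channel-wise independent 1/f^alpha noise with a white floor, unit RMS."""
    freqs = np.fft.rfftfreq(n_times, 1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = np.sqrt(1.0 / freqs[nz] ** alpha + white_floor)
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * shape
    x = np.fft.irfft(spec, n=n_times, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def blink_template(fs: float, duration: float = 0.4) -> np.ndarray:
    """Biphasic blink transient: dominant positive lobe, small rebound."""
    n = int(round(duration * fs))
    t = np.arange(n) / n
    lobe = np.sin(np.pi * t) ** 2
    rebound = -0.25 * np.sin(2 * np.pi * t) * (t > 0.5)
    return lobe + rebound


def blink_weights(montage: MontageSpec, sigma: float = 0.5) -> np.ndarray:
    present = [ch for ch in FRONTAL if ch in montage.channel_labels]
    centroid = montage.positions[montage.indices(present)].mean(axis=0)
    d = np.linalg.norm(montage.positions - centroid, axis=1)
    return np.exp(-(d ** 2) / (2.0 * sigma ** 2))


# ---------------------------------------------------------------------------
# single-subject simulation


def contrast_envelope(n: int, fs: float, design: StimulusDesign) -> np.ndarray:
    """Linear fade-in, plateau at 1, linear fade-out, over one sequence."""
    t = np.arange(n) / fs
    fade = design.fade_duration
    total = design.sequence_duration
    env = np.ones(n)
    if fade > 0:
        env = np.minimum(t / fade, 1.0)
        env = np.minimum(env, np.clip((total - t) / fade, 0.0, 1.0))
    return env


def simulate_subject_eeg(spec: SubjectSpec, design: StimulusDesign | None = None,
                         montage: MontageSpec | None = None,
                         fs: float = 512.0) -> tuple[RawRecording, GroundTruth]:
    """Realize one subject's continuous recording plus its ground truth.

    The recording holds ``design.n_sequences`` sequences separated by
    noise-only rest; each sequence is the superposition, per category, of
    harmonics k=1..K of that category's rate, scaled by the contrast
    envelope, on top of 1/f noise and blink transients.  Event markers at
    each full-contrast (plateau) onset carry the condition label.
    """
    design = design or make_design()
    montage = montage or biosemi64()
    rng = np.random.default_rng(spec.seed)

    rates = {design.rate_of(cat, cond)
             for cat in ("faces", "houses") for cond in design.conditions}
    max_freq = max(n_harmonics(r) * r for r in rates)
    if fs < 2.0 * max_freq:
        raise AliasingError(
            f"fs={fs} Hz below Nyquist for highest harmonic {max_freq} Hz")

    seq_len = design.sequence_duration
    total = (LEAD_SECONDS + design.n_sequences * seq_len
             + (design.n_sequences - 1) * GAP_SECONDS + TAIL_SECONDS)
    n_t = int(round(total * fs))
    n_ch = montage.n_channels

    if spec.noise_scale > 0:
        data = spec.noise_scale * pink_noise(n_ch, n_t, fs, rng)
    else:
        data = np.zeros((n_ch, n_t))

    if spec.blink_rate > 0:
        tmpl = blink_template(fs)
        w = blink_weights(montage)
        n_blinks = rng.poisson(spec.blink_rate * total)
        onsets = rng.uniform(0, total - 0.5, size=n_blinks)
        amps = rng.normal(100.0, 20.0, size=n_blinks)
        for onset, amp in zip(onsets, amps):
            i0 = int(round(onset * fs))
            data[:, i0:i0 + tmpl.size] += amp * np.outer(w, tmpl[: n_t - i0])

    gt = GroundTruth(subject_id=spec.subject_id,
                     accuracy=spec.accuracy, mean_rt=spec.mean_rt)
    events: list[tuple[float, str]] = []
    n_seq_samp = int(round(seq_len * fs))
    env = contrast_envelope(n_seq_samp, fs, design)
    t_seq = np.arange(n_seq_samp) / fs

    # subject-stable phases per (category, harmonic)
    for cat in ("faces", "houses"):
        for k in range(1, max(n_harmonics(r) for r in rates) + 1):
            gt.phases[(cat, k)] = float(rng.uniform(0, 2 * np.pi))

    cond_index = {c: i for i, c in enumerate(design.conditions)}
    for s, cond in enumerate(design.condition_of_sequence):
        onset = LEAD_SECONDS + s * (seq_len + GAP_SECONDS)
        i0 = int(round(onset * fs))
        events.append((onset + design.fade_duration, cond))
        for cat in ("faces", "houses"):
            rate = design.rate_of(cat, cond)
            K = n_harmonics(rate)
            targets = spec.zone_sum(cat, cond_index[cond])
            fund = channel_amplitudes(
                {z: v / SUMMED_FRACTION for z, v in targets.items()}, montage)
            amps = fund[:, None] * HARMONIC_DECAY ** np.arange(K)[None, :]
            gt.amplitudes[(s, cat)] = amps
            gt.harmonic_freqs[(s, cat)] = rate * np.arange(1, K + 1)
            if not np.any(amps):
                continue
            block = np.zeros((n_ch, n_seq_samp))
            for k in range(1, K + 1):
                ph = gt.phases[(cat, k)]
                block += np.outer(amps[:, k - 1],
                                  np.sin(2 * np.pi * k * rate * t_seq + ph))
            data[:, i0:i0 + n_seq_samp] += block * env

    rec = RawRecording(samples=data, fs=fs, montage=montage, events=events,
                       subject_id=spec.subject_id)
    return rec, gt


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class EffectConfig:
    """Named effect sizes and noise levels for a simulated cohort."""

    cell_means: dict = field(
        default_factory=lambda: {g: {c: dict(v) for c, v in d.items()}
                                 for g, d in GROUP_CELL_MEANS.items()})
    amp_sd: float = AMP_SD
    subject_gain_cv: float = SUBJECT_GAIN_CV
    noise_scale: float = DEFAULT_NOISE_SCALE
    blink_rate: float = DEFAULT_BLINK_RATE
    srs: dict = field(default_factory=lambda: dict(SRS_PARAMS))
    behavior: dict = field(default_factory=lambda: dict(BEHAVIOR_PARAMS))


def study_effects() -> EffectConfig:
    """The study's effect structure: TD differentiated, ASD flat."""
    return EffectConfig()


def null_effects() -> EffectConfig:
    """No group/stimulus/ROI structure: every cell mean equals the grand mean."""
    grand = float(np.mean([GROUP_CELL_MEANS[g][c][z]
                           for g in GROUP_CELL_MEANS
                           for c in ("faces", "houses") for z in ZONES]))
    flat = {g: {c: {z: grand for z in ZONES} for c in ("faces", "houses")}
            for g in ("TD", "ASD")}
    return EffectConfig(cell_means=flat)


def _lognormal(rng, mean: float, sd: float, size=None):
    """Lognormal draws with the given arithmetic mean and SD."""
    if mean <= 0:
        return np.zeros(size) if size else 0.0
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return rng.lognormal(math.log(mean) - s2 / 2.0, math.sqrt(s2), size=size)


def cohort_specs(n_per_group: int, effects: EffectConfig | None = None,
                 seed: int = 0, design: StimulusDesign | None = None
                 ) -> tuple[list[SubjectSpec], pd.DataFrame]:
    """Draw per-subject parameters for a two-group cohort.

    Per subject: a multiplicative overall gain (lognormal, CV
    ``subject_gain_cv``), then per category × ROI zone × condition an
    independent lognormal draw of the summed-amplitude target around
    (gain × group cell mean) with SD ``amp_sd``; SRS T-scores from the
    group-specific Gaussian truncated to [30, 120].  Fully reproducible
    from ``seed``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    effects = effects or study_effects()
    design = design or make_design()
    rng = np.random.default_rng(seed)
    n_cond = len(design.conditions)

    specs, rows = [], []
    for group in ("TD", "ASD"):
        for i in range(n_per_group):
            sid = f"{group.lower()}{i + 1:02d}"
            gain = float(_lognormal(rng, 1.0, effects.subject_gain_cv))
            zone_sums = {}
            for cat in ("faces", "houses"):
                zone_sums[cat] = {}
                for zone in ZONES:
                    mean = effects.cell_means[group][cat][zone] * gain
                    draws = _lognormal(rng, mean, effects.amp_sd, size=n_cond)
                    zone_sums[cat][zone] = np.asarray(draws)
            mu, sd = effects.srs[group]
            srs = float(np.clip(rng.normal(mu, sd), 30.0, 120.0))
            am, asd_, rm, rsd = effects.behavior[group]
            # Beta draw keeps the stated mean exactly despite the [0,1] bound
            nu = am * (1.0 - am) / asd_ ** 2 - 1.0
            acc = float(rng.beta(am * nu, (1.0 - am) * nu))
            rt = float(max(rng.normal(rm, rsd), 0.15))
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            specs.append(SubjectSpec(
                subject_id=sid, group=group, srs_t=srs,
                face_zone_sums=zone_sums["faces"],
                house_zone_sums=zone_sums["houses"],
                noise_scale=effects.noise_scale, blink_rate=effects.blink_rate,
                accuracy=acc, mean_rt=rt, seed=sub_seed))
            rows.append(dict(subject=sid, group=group, srs_t=srs,
                             accuracy=acc, mean_rt=rt, seed=sub_seed))
    return specs, pd.DataFrame(rows)


def simulate_cohort(n_per_group: int, effects: EffectConfig | None = None,
                    seed: int = 0, design: StimulusDesign | None = None,
                    montage: MontageSpec | None = None, fs: float = 512.0
                    ) -> tuple[list[tuple[RawRecording, GroundTruth]], pd.DataFrame]:
    """Materialize a full cohort of recordings (memory: ~75 MB per subject;
    for large cohorts iterate over :func:`cohort_specs` instead)."""
    design = design or make_design()
    montage = montage or biosemi64()
    specs, table = cohort_specs(n_per_group, effects, seed, design)
    out = [simulate_subject_eeg(s, design, montage, fs) for s in specs]
    return out, table


#: additive SD (µV) of the summed baseline-corrected amplitude contributed
#: by the residual spectral noise after ROI averaging and condition
#: averaging (~sqrt(3 harmonics) x the per-bin ROI noise SD at the default
#: background level)
MEASUREMENT_SD = 0.01


def simulate_response_table(n_per_group: int,
                            effects: EffectConfig | None = None,
                            seed: int = 0,
                            measurement_sd: float = MEASUREMENT_SD,
                            design: StimulusDesign | None = None
                            ) -> pd.DataFrame:
    """Draw a ResponseTable directly at the summed-amplitude level.

    Uses the same subject draws as :func:`cohort_specs` (gain × lognormal
    cell draws per condition) plus additive measurement noise, skipping the
    EEG realization — the statistical structure the mixed model sees is
    identical, at a fraction of the cost.  Used for Monte-Carlo calibration
    of the group statistics (type-I error, power).
    """
    design = design or make_design()
    specs, _ = cohort_specs(n_per_group, effects, seed, design)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 910]))
    cond_index = {c: i for i, c in enumerate(design.conditions)}
    rows = []
    for spec in specs:
        for cat in ("faces", "houses"):
            for cond in design.conditions:
                rate = design.rate_of(cat, cond)
                targets = spec.zone_sum(cat, cond_index[cond])
                for zone, amp in targets.items():
                    obs = amp + rng.normal(0.0, measurement_sd)
                    rows.append(dict(subject=spec.subject_id,
                                     group=spec.group, stimulus=cat,
                                     rate=rate, roi=zone,
                                     amplitude_uv=float(obs)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# behavioral task


def simulate_task_events(design: StimulusDesign, accuracy: float,
                         mean_rt: float, seed: int = 0,
                         min_separation: float = 1.0) -> pd.DataFrame:
    """Color-change detection events for one run.

    ``n_color_changes`` events per sequence at uniformly random,
    non-overlapping onsets; each is detected with probability ``accuracy``
    and, if detected, answered after a Gamma-distributed reaction time with
    the requested mean.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if mean_rt <= 0:
        raise ValueError("mean_rt must be positive")
    rng = np.random.default_rng(seed)
    n = design.n_color_changes
    usable = design.sequence_duration - design.color_change_duration
    slack = usable - n * min_separation
    if slack <= 0:
        raise SchedulingError(
            f"cannot place {n} events of >= {min_separation}s separation "
            f"in {usable:.1f}s")
    rows = []
    shape = 10.0  # Gamma shape: positively skewed, CV ~0.32
    for s in range(design.n_sequences):
        u = np.sort(rng.uniform(0, slack, size=n))
        onsets = u + np.arange(n) * min_separation
        hits = rng.random(n) < accuracy
        rts = rng.gamma(shape, mean_rt / shape, size=n)
        for onset, hit, rt in zip(onsets, hits, rts):
            rows.append(dict(sequence=s, onset=float(onset),
                             responded=bool(hit),
                             rt=float(rt) if hit else np.nan))
    return pd.DataFrame(rows)


def behavior_table(specs: list[SubjectSpec], design: StimulusDesign | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Observed per-subject accuracy and mean RT from simulated task events."""
    design = design or make_design()
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specs:
        ev = simulate_task_events(design, spec.accuracy, spec.mean_rt,
                                  seed=int(rng.integers(0, 2 ** 31 - 1)))
        rows.append(dict(subject=spec.subject_id, group=spec.group,
                         accuracy=float(ev["responded"].mean()),
                         mean_rt=float(ev["rt"].mean())))
    return pd.DataFrame(rows)
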