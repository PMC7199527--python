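# Methods

This note records the models, parameter choices and numerical decisions
behind `fpvs`, and what the synthetic-data tests do and do not establish
about real recordings.

## Signal model of the generator

Each subject's recording is

    x_c(t) = Σ_cat Σ_k A_c,k(cat) · e(t) · sin(2π k f_cat t + φ_k,cat) + n_c(t) + b_c(t)

per channel c, with `e(t)` the contrast envelope (linear 2-s fade-in,
60-s plateau at 1, fade-out; the 0–50% contrast modulation
affects the stimulus, so ground truth stores plateau amplitudes),
`n_c` background noise and `b_c` blink transients.  Sequences are
separated by 5 s of rest plus a 3-s lead-in, so the −2/+5-s segmentation
window never crosses sequences.

**Phases** φ are drawn once per subject × category × harmonic, uniform on
[0, 2π): the analysis averages within subject only, so phase never enters
the group statistics, but it must be stable within a subject for
time-domain condition averaging to preserve the response.

**Harmonic series.** Injected harmonics run to 30 Hz (5 for the 6 Hz
stream, 4 for 7.5 Hz) with amplitudes A_k = A_1·2^−(k−1).  This roll-off
makes group-level harmonic selection terminate exactly at the highest
injected harmonic, reproducing the expected selection pattern (shared
30 Hz excluded, three harmonics retained per rate).  The quantified sum
over the first three harmonics is then 1.75·A_1, which is how ROI-level
amplitude targets are converted to fundamentals.

**Topography.** Each ROI zone (MO, LOT, ROT) has a spatial profile equal
to 1 on its own electrodes, 0 on the other zones' electrodes, and a
Gaussian tail (width σ = 0.3 on the unit sphere) elsewhere.  The injected
field is demeaned across channels — scalp potentials are zero-mean-like
dipolar patterns, and this makes the injection exactly invariant under
common-average re-referencing — after raising the zone targets by the
(closed-form) global mean.  Consequently the ROI average of the injected
field equals the requested target exactly, channel amplitudes on ROI
electrodes are non-negative for any non-negative targets, and far-field
channels carry small phase-inverted components.  These are parametric
weights, not leadfields: no volume conduction is modelled, and
between-ROI correlation structure of real EEG is absent.

**Noise** is channel-independent 1/f^α (α = 1) with a white floor
(relative power 0.1), normalized to 1 µV RMS per channel by default.
**Blinks** are 400-ms biphasic transients with a frontal Gaussian
topography, ~100 µV at Fp, Poisson events at 0.36/s; no blink correction
is applied downstream, mirroring the analysis the pipeline implements.

## Cohort structure and calibration

Group-level defaults are the reported study pattern: per-cell summed
amplitude means (µV)

|            | LOT faces/houses | ROT | MO |
|------------|-----------------|-----|----|
| TD         | 1.32 / 0.75 | 1.26 / 0.91 | 1.44 / 1.82 |
| ASD        | 0.95 / 0.76 | 0.95 / 0.77 | 1.30 / 1.49 |

Per subject, a multiplicative gain (lognormal, CV 0.25) scales all cells;
each subject × category × zone × condition amplitude is then an
independent lognormal draw around gain × cell mean with SD 0.5 µV.  The
0.5 µV figure is derived from the reported group statistics themselves:
the within-cell residual σ implied by the published contrast t-values is
0.57·√21/4.73 ≈ 0.55, 0.35·√21/2.75 ≈ 0.58 and 0.38·√21/3.54 ≈ 0.49 µV —
roughly amplitude-independent, so a constant SD is used.  SRS T-scores
are Gaussian (ASD 85 ± 12, TD 42 ± 6) truncated to [30, 120]; behavioral
accuracy is Beta-distributed with the stated group means (97.1/97.0%) and
SDs, reaction times Gaussian (0.46/0.47 s).

**Background level and estimator bias.** The baseline-corrected amplitude
A − μ is *not* unbiased for the injected amplitude: at high SNR the
signal bin reads ≈A (noise adds only quadratically), yet the local noise
mean μ is subtracted per harmonic, so summed responses are depressed by
≈Σ_k μ_k; near the floor a Rician lift partly compensates.  The default
background (1 µV RMS → per-bin floor ≈0.009 µV at 6 Hz after condition
averaging) keeps this bias within a few percent even for weak ~0.3 µV
cells, so injected targets are what the pipeline measures.  At realistic
raw-EEG noise levels (10–30 µV RMS) the same pipeline underestimates
absolute summed amplitudes by ≈ the summed noise floor (~0.2 µV at
12 µV RMS in our measurements) while leaving *differences* between
conditions nearly untouched; passing recovery tests therefore certify
the implementation, not absolute-amplitude accuracy on noisy data.

What the generator does not emulate: volume-conducted spatial noise
correlations, non-stationary artifacts (movement, alpha bursts),
rate-dependent response amplitudes, or realistic inter-electrode
covariance; significance rates on real child EEG will be lower than the
near-ceiling rates seen here.

## Numerical and procedural choices

- **Filtering** is zero-phase (forward–backward `sosfiltfilt`) so
  stimulation-locked phase is undistorted; the stated order (4) is the
  order of the underlying Butterworth design.
- **Resampling** uses polyphase FIR (`resample_poly`); 512→256 Hz is an
  exact 2:1 ratio and in-band amplitudes survive within 0.5%.
- **Bad channels** are a per-subject configuration list (≤5% of
  channels); interpolation is an inverse-distance weighted mean of the
  three nearest good electrodes ("linear interpolation from the three
  nearest" is otherwise under-specified).
- **Pipeline order** segment → filter → resample → interpolate →
  re-reference is enforced via provenance flags; re-referencing is
  idempotent but does not commute exactly with interpolation.
- **Cropping** keeps the largest whole number of base-cycle blocks that
  are whole numbers of samples (3 cycles = 512 samples at 256 Hz),
  starting at fade-in end, bounded by the plateau.  Over a full 60-s
  plateau this gives Δf = 1/60 ≈ 0.0167 Hz.  (A commonly quoted 59.38-s
  window is not a whole number of 1.5 Hz cycles; the rule, not the
  count, is implemented.)
- **FFT scaling** is one-sided 2/N (DC and Nyquist unscaled), so a pure
  sinusoid of amplitude A µV reads A at its bin; verified against an
  explicit-sum DFT oracle to <1e−9 relative.
- **Noise neighborhood**: 12 bins per side, drop the single adjacent bin
  on each side (leakage guard), then the single largest and single
  smallest of the remaining 22 (ties broken toward lower frequency),
  leaving 20 bins; SD is the sample SD (ddof = 1).  Target frequencies
  must hit bin centers within Δf/100 — no silent snapping.
- **z statistic calibration**: on pure Rayleigh noise the z > 1.64
  exceedance is ~10%, not 5% — amplitude bins are right-skewed and the
  extreme-value exclusion shrinks the noise SD.  The threshold convention
  is kept as defined; the mild anticonservativeness is measured by a
  dedicated Monte-Carlo test.
- **Individual significance** extracts ±20 bins around each target
  harmonic of *both* counterbalanced conditions (six mini-spectra per
  stimulus type), sums them element-wise, and z-scores the center against
  the surrounding bins with the usual exclusions; "exceeds" is strict at
  both thresholds (2.32 group, 1.64 individual).
- **Rate pooling**: responses are quantified per stimulus × rate
  (condition); the two rate replicates enter the mixed model as
  within-cell replicates rather than being averaged first, which is what
  reproduces ~450 denominator df for 42 subjects.
- **Mixed model**: REML random-intercept fit (statsmodels MixedLM);
  F statistics are Wald tests of sum-coded term blocks against the REML
  fixed-effect covariance.  Denominator df defaults to the pooled
  residual `n_obs − rank(X) − (n_subjects − 1)` (451 for the full
  design), which coincides with Satterthwaite/Kenward–Roger on this
  balanced design; a plain-residual alternative is selectable.  A
  published denominator of 441 for this design is not reproducible by any
  standard method we know of; the model records its method and df.
- **Post-hoc contrasts** are faces−houses per group × ROI, with SE from
  the residual variance only (random intercepts cancel within subject)
  and p-values from the studentized-range distribution over the family of
  all 12 cell means — the adjustment that reproduces emmeans-style Tukey
  values for this design.
- **Time course** keeps LOT/ROT as a hemisphere factor by default (this
  matches the ~287 denominator df of the published time-course tests;
  full pooling, which gives ~123, is available via `pool_hemispheres`).
  Lengths that are not whole cycle blocks are truncated down (5 s → 4 s
  at 256 Hz).
- **Behavioral t-tests** default to Welch (df reported); pooled-variance
  is selectable.  Spearman correlations are reported per group and pooled,
  per ROI, for faces, houses and their difference, with an explicit
  "no multiple-testing correction" marker.  Note that pooling groups
  induces correlation between SRS and the face−house difference whenever
  the groups differ on both — a structural confound visible in synthetic
  cohorts.

## Statistical calibration at desk scale

The Monte-Carlo calibration uses a table-level twin of the cohort
generator (same gain × lognormal cell draws plus 0.01 µV measurement
noise) so that 600 mixed-model fits run in under a minute.  Under the
null configuration the three-way interaction rejects at ~5% (α = .05).
Under the study-pattern defaults its detection rate is ~60%: with the
published cell means and the residual σ implied by the published
t-values, the interaction's noncentrality is λ = 42·Σ(αβγ)²/σ² ≈ 5–7,
i.e. 50–67% power — consistent with the marginal published
F(2,441) = 3.40.  A detection rate above 80% would require either larger
effects or less subject-level variability than the study itself reports;
the package keeps the faithful calibration and reports the measured rate.

## Problem sizes

Default analyses use the study-sized cohort (21 + 21 subjects, four 64-s
sequences, 64 channels at 512 Hz, ~1 s/subject through the full chain).
Parameter-recovery runs use 200 subjects at the generator's native
256 Hz without the filtering stage (the response is already band-limited;
filter fidelity is certified separately), and calibration uses 500 null
plus 100 study-pattern table-level cohorts.
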