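# Methods

`backnirs` implements an event-related analysis for continuous-wave fNIRS
recordings of mechanosensory stimulation of the lower back, together with a
forward simulator that generates recordings with the statistical structure
the analysis assumes.  This note documents the model, the defaults, the
numerical choices, and what the simulation-based validation does and does
not establish.

## Measurement model

A two-wavelength (760/850 nm) probe of 8 sources and 8 detectors forms 18
channels over two regions of interest: the bilateral supplementary motor
area (SMA, channels 1–6) and the midline primary somatosensory cortex (S1,
channels 7–18).  Channels 2 and 10 are ~11 mm short-separation channels,
sensitive almost exclusively to extracerebral tissue; all other separations
lie in 25–45 mm.  Per-channel separations are nominal configuration values:
nothing downstream depends on them except the pathlength term of the
Beer–Lambert conversion, and a serialized probe layout can override them.

Optical-density changes relate to chromophore concentration changes through
the modified Beer–Lambert law,

    ΔOD(λ) = [ε_O2Hb(λ)·Δ[O2Hb] + ε_HHb(λ)·Δ[HHb]] · d · DPF(λ),

solved per channel and sample as a 2×2 linear system.  Extinction
coefficients are the Gratzer/Prahl whole-blood compilation (shipped as
package data with a provenance header); the differential pathlength factor
is the published closed-form general equation in subject age and
wavelength (also package data).  One DPF per wavelength, shared across
channels.  Raw intensity input is accepted and converted as
−log10(I/I_ref) with I_ref the mean over the 5-min rest baseline.

## Signal chain

1. **MBLL inversion** to Δ[O2Hb]/Δ[HHb] in µmol/L.
2. **Savitzky–Golay band-pass**: third-degree SG smoothing with a 4 s
   window minus a third-degree SG trend with an 80 s window.  Windows are
   `round(seconds × 7.81)` forced odd (31 and 625 samples); edges use the
   terminal in-window polynomial fit.  Measured response: ≥80% attenuation
   at 0.01 Hz, ≥70% transmission in 0.08–0.2 Hz.  Note that an 80 s cubic
   trend tracks only components below roughly 0.02 Hz, so a 0.05 Hz
   oscillation passes essentially unattenuated — slow Mayer-type activity
   is handled by the short-separation regression, not the detrender.
3. **Segmentation** into 3.9 s pre-ISI + 5 s stimulus + 3.9 s post-ISI
   (30 + 39 + 30 = 99 samples), onsets mapped to the nearest sample,
   15 trials per condition for the study protocol.
4. **Per-segment detrend and baseline**: an OLS drift line is fitted on
   the response-free pre-ISI samples and extrapolated over the segment,
   then the pre-ISI median is subtracted (exactly zero afterwards).
   Fitting the line over the *whole* segment is available via
   `detrend_scope="segment"` but is not the default: a line fitted through
   a rising hemodynamic response absorbs a large part of the response
   itself (it recovers only ~55% of an onset-locked step and inverts the
   sign of the mid-stimulus summary of a 6 s-peaking response), which
   would make the pipeline unable to detect the very effects it exists to
   measure.
5. **Short-separation regression (SSR)**: each long channel minus the
   least-squares-scaled signal of its ROI's short channel
   (α = ⟨long, short⟩/⟨short, short⟩), separately per chromophore;
   channels 1, 3–6 use channel 2, channels 7–9, 11–18 use channel 10.
   The default scope estimates one α per channel-chromophore on the
   continuous band-passed recording and subtracts before segmentation,
   matching the original formulation of the method on whole recordings.
   A per-segment variant (`ssr_scope="segment"`) exists and satisfies the
   usual algebraic properties (orthogonality of the residual,
   idempotence), but it is not the default: after band-passing, a 12.8 s
   segment holds only ~6–15 effective degrees of freedom, so a per-segment
   α co-adapts to in-window noise and systematically removes part of the
   evoked response (in simulation the recovered amplitude even changes
   sign).  With a task-locked scalp wave the per-segment α tends to
   (A+S)/S and annihilates the cerebral response outright.

## Summary statistics and inference

The per-trial summary is the median over the middle 2.5 s of the stimulus
window (samples covering [onset + 1.25 s, onset + 3.75 s], 20 samples).
The per-subject **block average** is the per-sample median over the 15
trials; its middle-window median is the response scalar (µmol/L).  The
**grand average** is the per-sample median across subjects, with a
standard error of the median from a seeded 1000-resample bootstrap over
subjects (the Gaussian approximation 1.2533·SD/√n is available).

A subject–channel–condition cell is a **responder** when the Wilcoxon
signed-rank test of its 15 trial medians against zero has two-sided
p < 0.05 (uncorrected; configurable).  Group statistics run in two tracks:
*All* (every subject contributes everywhere) and *Responders* (a subject
contributes to a cell only if flagged there).  Per long channel and
chromophore: a Friedman test across the three conditions, a Wilcoxon
signed-rank test of each condition against zero, and paired Wilcoxon
signed-rank tests for the three condition pairs.  Wilcoxon p-values are
exact for n ≤ 25 without ties and tie-corrected normal otherwise; zeros
are dropped.  Each family — one test type, condition or pair, and
chromophore — is corrected across the 16 long channels with the
Benjamini–Hochberg step-up procedure at q < 0.05.  Short channels never
enter group statistics.  Cells with fewer than five contributing subjects
are reported missing and excluded from their family.

The habituation screen regresses the 15 chronological trial medians on
trial index per subject/channel/condition (OLS, two-sided t test on the
slope, uncorrected): significantly positive slopes are read as
sensitization, negative as habituation.  Heart-rate analysis extracts
HRmean/HRmax per 5 s stimulus, 15 s pre-ISI and 15 s post-ISI window
(stimulus and post-ISI tile each event's 20 s; a post-ISI is also the next
event's pre-ISI), aggregates per-event maxima by their mean, and compares
post-ISI against stimulus HRmax per condition with paired Wilcoxon tests
(one FDR family of three) plus a Friedman test across conditions on the
differences.

## Forward simulator

Per subject, in chromophore space (µmol/L):

* **Cerebral response** on long channels of the responsive ROIs: amplitude
  × a peak-normalized double-gamma (peak 6 s, undershoot ratio 1/12),
  summed over events.  Default O2Hb amplitudes: PAPain 0.46, PA30 0.36,
  Brush 0; HHb at −25% of O2Hb.  The qualitative structure — both
  pressure conditions active in SMA and S1, painful pressure slightly
  stronger, brushing silent — is the design constraint; the absolute
  magnitudes are order-of-magnitude choices typical of event-related
  fNIRS, fixed once.
* **Superficial (scalp) component**, perfectly shared by every channel of
  an ROI including its short channel: a task-locked transient (single
  gamma peaking at 4 s — skin blood flow responds faster than the
  neurovascular response) with O2Hb amplitudes PAPain 0.30 / PA30 0.15 /
  Brush 0 (pain-dominated), plus ongoing band-limited (0.04–0.20 Hz)
  skin-blood-flow fluctuations of 0.5 µmol/L RMS.  The background is
  essential, not decorative: it is what the short channel actually
  measures, and without a dominant non-task superficial signal any SSR
  scaling is driven by the task-locked covariance and removes cerebral
  signal.  HHb superficial signals are 10% of O2Hb.
* Projection to OD via the forward Beer–Lambert relation, then OD-space
  nuisances: cardiac (1.1 Hz), respiratory (0.25 Hz) and residual
  Mayer-wave (0.1 Hz) oscillations with phase diffusion, scaled per
  channel by separation/30 mm (they are blood-volume oscillations, so
  their OD expression grows with pathlength — without this scaling an
  equal-OD oscillation would invert to a 1/d concentration pattern and
  SSR would amplify rather than remove it); linear drift and a random
  walk; white noise of 0.002 OD at 30 mm growing one decade per 20 mm of
  separation (detected intensity falls roughly exponentially with
  distance, so short channels are the quietest — this is also what makes
  the short channel a low-noise regressor, as in real probes).
* The **ground truth** object retains the cerebral and superficial
  compartments separately; their sum projected forward equals the OD
  output before the OD-space nuisances, which enables parameter-recovery
  tests.
* **Heart rate** (1 Hz): per-subject baseline ~62 bpm, a
  condition-independent gamma-shaped transient of 4 bpm peaking 7 s after
  stimulus onset (2 s into the post-ISI), slow wander and 1 bpm noise.

A **population layer** adds between-subject structure for cohort
simulations: amplitude A(subject, condition, channel) = base·s + u + w with
a lognormal global responsiveness s (σ = 0.25), a condition-level subject
deviation u (SD 0.10·|base|, shared across channels), and a channel-level
deviation w (SD 0.60·|base| + 0.35 µmol/L for O2Hb, +0.25 for HHb).  The
large channel floor encodes the well-known heterogeneity of scalp-probe
recordings, in which a sizeable minority of channels shows no or an
inverted response; it is what keeps the painful-vs-nonpainful paired
contrast statistically invisible at n = 20 while both pressure conditions
remain robust against zero — the structure the analysis is designed to
resolve.  Conditions without a cerebral response receive only a small
idiosyncratic floor (0.06/0.05 µmol/L), yielding single-subject responder
rates of roughly 55–62% for the pressure conditions and ~7–10% for
brushing under the default noise.  Ages are uniform on 22–61 years.

## Validation experiments and their limits

All validation is self-referential — recovery of injected parameters and
calibration under the simulator's own null — because no subject data are
available.  `backnirs.validation` provides:

* **Null calibration**: on noise-only recordings the responder test
  rejects ~5% of subject–channel cells (checked over ≥500 cells within
  ±2 points), and every FDR family's mean discovery proportion over 200
  all-null cohorts stays at or below 5%.
* **Parameter recovery**: over 100 seeded 30-subject cohorts with the
  default (identical) amplitudes, the grand-median response scalars
  recover the injected ordering PAPain > PA30 > Brush in ≥95% of cohorts,
  and the recovered pressure amplitudes agree with the deterministic
  noiseless-pipeline value within 15%.  The noiseless pipeline output is
  the correct oracle for amplitude magnitude: the mid-stimulus median of
  a response peaking at 6 s is ~0.2× its peak by construction, so the
  scalar estimates the response level in that window, not the peak
  concentration, and only noise robustness is at issue.  Thirty-subject
  cohorts give the grand median enough resolution for the small
  pain-vs-nonpain contrast; at n = 20 the per-cohort ordering probability
  is ~0.97.
* **Pattern reproduction**: on 20-subject population cohorts the group
  analysis is required to show ≥3 FDR-significant channels against zero
  for each pressure condition, ≤1 for brushing, ≥2 significant channels
  across the two pressure-vs-brush post hoc families, and ≤1 in
  painful-vs-nonpainful.  Null-leaning families are allowed one stray
  discovery because BH-FDR at q = 0.05 explicitly tolerates that rate;
  demanding literal zeros would test conservativeness the procedure does
  not promise.

What passing these does **not** show: the simulator's noise is stationary
and Gaussian (no motion artifacts, no hair/coupling dropouts, no
non-stationary systemic physiology), the scalp component is perfectly
correlated within an ROI, and evoked shapes are identical across channels
and subjects up to scale.  Real recordings violate all of these, so the
validation establishes correctness and calibration of the *procedure*, not
expected performance on arbitrary data.

## Numerical and degenerate-input choices

* Sample-index conversions round to the nearest sample
  (`round(seconds × fs)`); SG windows are forced odd by adding one.
* A zero-power short-channel segment yields α = 0 (no correction) with a
  logged warning; all-zero Wilcoxon input yields p = 1; a constant trial
  series yields slope 0, p = 1, classification "none"; a Friedman matrix
  of identical rows yields χ² = 0, p = 1.
* The MBLL system raises on a singular (spectrally collinear) extinction
  matrix; the DPF equation raises outside 690–950 nm or ages outside
  0–100 years.
* Determinism: every stochastic component (simulation, SEMed bootstrap,
  protocol randomization) is driven by an explicit integer seed; reports
  embed the package version, seed and configuration hash, and re-running
  an analysis is byte-identical.

## Known limitations

* The simulator's HHb population variability makes group-level HHb effects
  somewhat easier to detect than in the study, where HHb survived no
  correction; HHb acceptance is therefore limited to calibration, not
  pattern matching.
* With recording-scope SSR, the task-locked scalp covariance biases α
  slightly above one and differentially attenuates conditions with larger
  scalp transients (a few percent here); this is a property of the
  published method on task-locked superficial contamination, not of this
  implementation.
* Baseline contamination by the preceding trial's response tail biases
  response scalars by about +0.01 µmol/L under the default protocol
  (15 s ISI); this affects all conditions alike and is inherent to the
  short-ISI event design.
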