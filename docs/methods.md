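# Methods

## The measurement model

A point source over a free field loses amplitude to geometric (spherical)
spreading at 20·log10(d/d_ref) dB; real near-ground transmission adds
frequency- and substrate-dependent loss or gain on top. The package's central
quantity is that residual, the **excess attenuation**

    EA(f, d) = [SPL(f, 0.5 m) − SPL(f, d)] − 20·log10(d / 0.5)   [dB],

computed for d ∈ {1, 2, 4, 8} m against the 0.5-m reference. Positive EA
means the medium attenuates more than geometry predicts; negative EA
(typical over water below ~2 kHz) means boundary channeling. The doubling
distances make the spherical term a clean 6.02/12.04/18.06/24.08-dB
staircase, which the simulator and the unit tests exploit as a closed-form
oracle.

Two algebraic conventions matter and are fixed package-wide:

- **Averaging.** Mean EA cells are computed on the linear pressure scale:
  dB → 10^(x/20), arithmetic mean, → 20·log10(·). The ÷20 (amplitude)
  rather than ÷10 (power) divisor is the convention consistent with
  averaging pressures (N/m²); it is the only one that reproduces every
  desk-recomputable cell of the shipped summary tables at 2-dp rounding
  (the verification stage demonstrates that the power convention fails
  them). The linear mean dominates the arithmetic dB mean (Jensen), so
  "Total" cells sit above naive dB averages.
- **Extrema and dispersion.** Min/max columns are plain extrema of the dB
  values. SD is reported on the dB scale; this is a documented convention,
  not a reproduction claim, since the provenance of the printed SD columns
  is not recoverable from the published cells.

Table output rounds half away from zero to two decimals. The shipped table
fixtures normalize the source's decimal-comma SD cells to decimal dots.

## The simulator (synthetic data)

The original field recordings are archived in a museum collection and not
programmatically available, so the package generates its own transects with
known ground truth. A `PropagationScenario` holds, per (locality,
substrate):

- an **EA-rate profile**: dB per distance doubling as a function of
  frequency, applied in the frequency domain as
  −[20·log10(d/0.5) + ea(f)·log2(d/0.5)] dB (zero-phase FFT multiply, no
  dispersion or two-ray comb structure — the default medium is descriptive,
  not physically derived);
- a fixed **loudspeaker coloration** within ±8 dB (the tested hardware
  spec), shared by all distances of a locality — since the 0.5-m reference
  passes through the same filter, it cancels exactly in EA, which criterion
  tests verify to < 0.2 dB;
- a receiver-side **ambient noise floor** (added after attenuation: field
  background noise is position-local, not source-borne);
- discrete **recorder gain steps** (+10 dB at 4 m, +20 dB at 8 m by
  default; the field protocol's step sizes are unpublished, so these are
  config-exposed choices);
- an amplitude convention: digital full scale ≡ 110 dB SPL, placing the
  75-dB-peak broadcast level and the 94-dB calibration tone below clipping.

Each simulated recording is [94-dB cal tone | propagated program | cal tone
| 60 s background noise]; calibration tones are injected at the microphone
(bypassing propagation) and everything is scaled by the distance's gain
step, so per-recording calibration removes the gain exactly.

Study-fixture profiles mimic the qualitative field pattern: water transects
with negative EA rates below ~2 kHz rising sharply at 2–3 kHz; soil
transects with uniformly higher, more variable rates. Rates are bounded so
total EA at 8 m spans roughly −16…+26 dB, matching the observed field
ranges, and the ambient floor is drawn at 22–26 dB SPL (a calm pre-dusk
rural site) so that even the most attenuated 8-m tones clear the SNR
validity screen — emulating the field protocol, which raised sound-level-
meter sensitivity at distance precisely to keep far signals measurable.
Atmospheric absorption is omitted (negligible below 5 kHz at ≤8 m).

What the simulator does **not** emulate: ground/water impedance physics,
wind gusts, reverberation, microphone directivity, or the fine pulse
structure of real calls. Passing recovery tests therefore demonstrates the
correctness of the analysis chain, not the realism of any particular EA
profile.

## Stimulus synthesis

Tones: sine with 5-ms raised-cosine ramps (ramps avoid spectral splatter;
the source protocol is silent on ramps). Synthetic calls: a decaying
harmonic stack (amplitude 1/k) whose strongest partial sits at the species'
dominant frequency (≈2678 Hz native / ≈1405 Hz invasive, durations 430 /
641 ms), amplitude-modulated with a raised-cosine envelope (45 / 30 Hz) and
seeded random phases for between-rendition variation. Each of the 7 + 6
individuals contributes 6 renditions; per-individual dominant-frequency
offsets stay within each species' reported spread. Every segment is 100%
peak-normalized before assembly; call segments are high-passed at 300 Hz
(4th-order Butterworth, zero-phase) by default. The published "filtered
between 0 and 300 Hz" statement is ambiguous — a 0–300-Hz stop-band
conflicts with the invasive species' 0.2–0.4-kHz fundamental — so both
behaviors are exposed (`highpass_calls`/`highpass_tones`) and neither is
asserted as the original intent. White noise is Gaussian, band-limited to
0.1–10 kHz (bandwidth unstated in the protocol), peak-normalized.
Inter-segment silence defaults to 0.5 s.

## SPL measurement

Calibration offset = 94 − 20·log10(digital RMS of the cal segment); two
segments are averaged in dB and their difference reported as drift (warning
above 1 dB). Segment RMS excludes the 5-ms edge ramps (the original
interactive measurement tool's window is unpublished). SNR compares the
segment's band-limited RMS (±1/3 octave around a tone's frequency; 0.2–5 kHz
for calls and noise) against the same band of the recording's background-
noise segment, both via FFT-band power (Parseval). Records below 6 dB SNR
or clipped (≥0.1% from full scale in >1% of samples) are flagged invalid
and excluded from EA — never zero-filled. Background-noise statistics tile
the 60-s noise segment into 15-s windows and report the maximum per-window
RMS and peak SPL. Calibration is per-recording (whether the original
analysis re-referenced per distance or per transect is unstated; the
per-recording choice makes gain steps cancel exactly).

## Frequency categories

Tones pool into five closed kHz bands keyed to the two species' call
spectra: F1 0.2–0.5 (invasive fundamental), F2 0.6–1.0, F3 1.1–2.0
(invasive dominant), F4 2.1–3.0 (native dominant), F5 3.5–5.0. The 29-tone
series fills them 4/5/10/6/4; frequencies in the gaps (e.g. 3.2 kHz) are
explicitly uncategorized and the caller decides.

## Inference

Both analyses are split-plot designs: subjects are the 29 tones (between
factor: frequency category — the only reading consistent with the published
between df of 4, 24 = 29 − 5 subjects) or the 13 individuals (between:
species); within factors are distance (4) × substrate (2) × locality (7),
complete crossing required (incomplete subjects are dropped with a logged
warning; missing design cells are a hard error). Sums of squares use
orthonormal within-cell contrasts (see `rmstats` module docstring);
with a single between factor the weighted (Type I ≡ II) decomposition is
exact and reproduces the published df patterns (4,24; 3,72; 1,24; 6,144;
and 1,11; 3,33; 6,66 for calls). Per within-stratum: Mauchly's W with
Box's second-order chi-square series (the ezANOVA approximation, validated
against pingouin on single-factor designs), Greenhouse–Geisser and
Huynh–Feldt epsilons from the pooled contrast covariance (HF truncated at
1; GG available behind a flag but never the default), Shapiro–Wilk on
stratum residuals. Huynh–Feldt-corrected p-values are reported when
Mauchly's p < 0.05 (a flag forces always-corrected output). Two-level
factors are trivially spherical (W = 1 by convention). Bonferroni pairwise
comparisons multiply raw paired-t p-values by the number of level pairs,
capped at 1.

EA values may be transformed before inference; the published log transform
is under-specified for negative dB values, so three monotone candidates are
exposed (`shifted_log` log(v − min + 1), `identity`, `linear_log`), the
choice recorded in the output, none asserted as the original.

Monte-Carlo calibration: under iid normal null data on the tone design, the
reported per-effect rejection rate at α = 0.05 stays within the 95%
binomial band for 1000 replicates (the contrast strata are orthogonal, so
the uncorrected tests are exact F under sphericity).

## Problem sizes and determinism

Oracle and calibration checks run on the tones-only program (~35 s of
audio per distance); the full 70-recording study fixture is generated
lazily, one transect at a time, to bound memory. All stochastic stages
derive from explicit integer seeds (`numpy` `SeedSequence` spawning), and
fixed-seed runs are byte-identical down to written WAVs.

## Known limitations

- Scenario EA profiles are descriptive; no impedance or meteorology model.
- The published F statistics of the two ANOVA tables are not reproduction
  targets: they require the undeposited field recordings. The package
  reproduces their design structure (effects, df pattern, correction
  policy) and the desk-recomputable summary cells only.
- SD columns of the summary tables follow a declared convention (dB scale)
  rather than a verified reproduction.
- The chi-square approximation behind Mauchly's p degrades when a stratum's
  contrast dimension approaches the error df (e.g. 18-dimensional
  distance × locality contrasts on few subjects); singular pooled
  covariances are reported as W = 0 with an undefined p rather than
  extrapolated.
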