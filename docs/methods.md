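# Methods

This note documents the model implemented in `bsim`, its assumptions, the
synthetic data that drives it, and the numerical choices that a user would
need to know to interpret (or distrust) its output.

## The model

### Scenes

A listening condition is a calibrated binaural scene: speech from the front,
a stationary masker either from the front (`S0N0`) or from ±90° on the side
of the listener's worse ear (`S0N90`), and a monaural variant (`S0mN90m`) in
which only the better ear receives signal.  All waveforms share one digital
calibration (RMS 1.0 ≡ 100 dB SPL).  The masker is presented at 65 dB SPL;
the SNR is defined between the free-field (pre-spatialization) broadband
levels of speech and noise, so per-ear SNRs in the lateral conditions emerge
from the binaural cues.

Spatialization is parametric rather than measured: a pure interaural time
difference (700 µs at ±90°) plus a head-shadow attenuation that is 0 dB
below 500 Hz and rises linearly in log-frequency to 10 dB at 4 kHz and
above.  These are values typical of a human head, not a calibrated HRTF
set; consequences are discussed under *Limitations*.

The speech token is speech-shaped noise (flat 100–500 Hz, −9 dB/oct above)
carrying a 2–8 Hz band-limited envelope modulation (depth 0.6), i.e. it has
the long-term spectrum and the syllabic modulation of running speech but no
linguistic content.  The masker is fresh Gaussian noise spectrally matched
to the token via a Welch estimate, hence stationary.  Defaults: 44.1 kHz,
ten 2-s tokens per threshold estimate.

### Periphery and hearing loss

Each ear is decomposed by a bank of 30 fourth-order gammatone filters with
centre frequencies equally spaced on the ERB-number scale from 146 Hz to
8.3 kHz.  The filters are all-pole gammatones realized as four cascaded
biquads (pole radius from b = 1.019·ERB(f_c)), normalized to unit gain at
the centre frequency.  This realization is numerically linear to machine
precision, which the shadow-filtering contract below requires; the summed
band power for band-limited white noise sits within ±1.5 dB of the input
power (no perfect-reconstruction claim).

Hearing loss enters as threshold-simulating noise (TSN): per ear, Gaussian
noise whose band spectrum level is

    HL(f) + T_ref(f) − 10·log10(ERB(f)) + offset,

with HL interpolated linearly in log-frequency between the audiometric
points and T_ref a free-field-like monaural threshold reference (declared
package constants).  With `offset = 0` a pure tone at threshold produces
roughly 0 dB SNR within its band.  The left and right TSNs come from
independent random streams, so they are interaurally uncorrelated and the
binaural stage cannot cancel them; they are treated as part of the masker
for all downstream SNR computations.

### Blind EC front-end

Below 1.5 kHz each band is processed by an independent equalization–
cancellation stage.  Equalization estimates the interaural level
difference (RMS ratio in dB, right minus left) and the interaural delay
(peak of the normalized circular cross-correlation within ±2 ms, refined to
sub-sample precision by parabolic interpolation; delay and gain are
estimated sequentially, with the estimate validated against an exhaustive
residual-power search in the tests).  Cancellation then aligns the right
ear to the left and either subtracts (*minimize*: removes the interaurally
coherent masker, useful at negative SNRs) or adds (*maximize*: reinforces
the coherent target, useful at positive SNRs); outputs are scaled by 1/2 so
that the diotic maximize pathway is level-neutral.

The strategy is chosen blindly per band by the speech-to-reverberation
modulation energy ratio (SRMR) of the two candidate outputs: the envelope
(magnitude of the analytic signal, low-passed at 128 Hz) is passed through
eight log-spaced modulation filters between 4 and 128 Hz, and the score is
the power in the four lowest over the four highest filters.  Ties go to
minimize.  At and above 1.5 kHz no binaural interaction is modelled; the
better ear is selected per band, again by SRMR (ties go left).  A scene
with one silent ear bypasses the EC stage entirely and propagates the
active ear.

Human binaural imprecision is modelled by Gaussian jitter on the
equalization parameters (SD 65 µs delay, 1.5 dB gain — the classical
binaural-inaccuracy values; fixed SDs, no level/delay dependence), drawn
independently per band and Monte-Carlo realization.  Selection operates on
the jitter-free outputs; jitter perturbs the parameters of each stored
draw.

### Shadow-filtered SII back-end

Every front-end disposition is a linear operator, so the parameters
estimated on the mixture can be re-applied to the clean speech and the
noise(+TSN) separately; the two outputs sum to the processed mixture
exactly ("ideal shadow filtering"; enforced in the tests at 1e-9 relative
error).  The back-end computes per-band SNRs from the shadow-filtered
powers, clamps them to ±15 dB, maps them linearly to band audibilities
(SNR+15)/30, weights them with the critical-band importance function
interpolated (in ERB number) to the 30 gammatone centres and renormalized
to sum 1, and sums to an index in [0, 1].  Hearing loss is deliberately
absent from this stage (the TSN already carries it), and the
level-distortion and masking-spread terms of the full standard procedure
are omitted.

### SRT solving and individualization

For one listener and condition the SII is computed on the SNR grid −20…+20
dB in 1-dB steps (noise fixed, speech varied), averaged over sentences ×
Monte-Carlo draws (10 × 10 at full scale), made monotone by a cumulative
maximum, and the SRT is the first upward crossing of the reference value
0.2, linearly interpolated.  A crossing outside the grid returns the grid
bound with an `out_of_range` flag.

Two individualization schemes use a listener's measured S0N0 SRT:

* **ISC_SII** — the reference becomes the S0N0 curve's value at the
  measured SRT; S0N0 is thereby fitted (flagged), the lateral conditions
  are predicted with the individual reference.
* **ISC_Noise** — the external masker is raised by
  max(0, measured − predicted) dB in every condition (upward-only); the
  reference stays 0.2 and SRTs are reported relative to the nominal 65 dB
  SPL noise.

**Benefits under individualization.**  The masking-release benefits are
SRT differences (SRM = S0N0−S0N90, BRM = S0mN90m−S0N90, BEL = S0N0−S0mN90m,
so SRM = BEL + BRM identically).  A condition-independent suprathreshold
component cancels in these differences.  Re-solving each condition at an
individual reference would *not* preserve them exactly when the
psychometric curves of different conditions are not parallel, so the
package always reports predicted benefits from the common-reference
predictions; the ISC schemes recalibrate absolute SRTs only.  This mirrors
how individualized accuracy tables conventionally leave the benefit
columns untouched.

### Engine implementation

The solver does not re-filter waveforms at every grid point.  All
dispositions being linear, the shadow-filtered band powers for any (delay,
gain, strategy) are exact functions of cached per-band spectra and
cross-spectra, evaluated at fractional lags in the frequency domain; the
cross-correlation used by the equalizer is assembled per grid SNR from the
four source-pair correlation windows.  The SRMR selector runs on
frequency-shifted, band-limited complex baseband versions of the analytic
band signals (the shift leaves envelope magnitudes untouched; decimation to
4 kHz discards only far-out filter skirts).  The time-domain path
(`bsim.ec.ec_process` → `bsim.sii.shadow_filter`) is the reference
implementation; the test suite checks the two against each other.

## Synthetic cohorts

Audiogram templates encode the standard audiogram-shape taxonomy: NH,
flat-to-sloping losses of increasing severity (N1–N4) and steep
high-frequency losses (S1–S3).  The template values are package constants
respecting the taxonomy's ordering (strictly increasing better-ear PTA
N1→N4; ≥30 dB rise from 250 Hz to 6 kHz for S groups); they are stand-ins,
not published group means.  Listeners get per-frequency Gaussian jitter
(SD 3 dB), an optional interaural asymmetry (one ear +20–60 dB in a
configurable fraction), and a ground-truth suprathreshold offset drawn
around a group mean (0 dB NH rising to 4 dB for the severest groups,
SD 3 dB).

"Measured" SRTs are simulated as model prediction + offset + N(0, 1 dB),
with the same offset in every condition.  What passing tests on these data
do **not** show: the generator contains no linguistic material, no adaptive
staircase, no cognitive covariates, and its measurement noise is Gaussian
and condition-independent — so recovery results demonstrate internal
consistency of the individualization machinery, not clinical validity.

## Numerical choices

* Fractional delays are circular FFT phase ramps (Nyquist bin scaled by
  cos πd); the analytic power path uses the identical operator, so fast and
  reference paths agree to machine precision.
* Quartiles for Tukey fences use linear interpolation; the outlier rule is
  1.5 × IQR.
* The KS normality screen estimates mean/SD from the sample (the p-values
  therefore carry the usual caveat of estimated parameters).
* Correlation comparisons use Fisher's Z on r = +√R², treating samples as
  independent.
* Group-pair comparisons are two one-sided Welch t-tests at α = 0.05
  without multiplicity correction (exposed as parameters).
* Degenerate inputs: silent bands equalize to (0, 0) with a flag; zero
  noise power clamps the band SNR to +15 dB; out-of-grid crossings return
  the bound with a flag; ties in blind selection go to minimize / left.

## Problem sizes used in tests and the acceptance script

Tests and the acceptance script run the solver at 22.05 kHz with 1–2 s
tokens, 1–2 sentences and 2–3 Monte-Carlo draws (the large recovery study
uses 5 master seeds × 40 listeners at 1 × 2), sizes chosen so the checked
identities — calibration fit, benefit invariance, shadow-filter linearity,
directional orderings — are unaffected while a full run stays desk-scale.
Library defaults remain at the full values (44.1 kHz, 10 × 2-s sentences,
10 draws).

## Known limitations

* The parametric spatializer yields a perfectly interaurally coherent
  masker, so jitter-limited EC cancellation plus the ILD profile produces
  more spatial release than measured-HRTF scenes typically do; for
  normal-hearing profiles the S0N90 threshold can reach the −20 dB grid
  bound (returned clamped and flagged).
* The TSN calibration constant and the audiogram templates are declared
  constants, not fitted to any clinical dataset.
* SRMR-based selection is a blind heuristic and occasionally picks the
  SNR-inferior pathway in near-tie bands; this is part of the modelled
  behavior, not corrected.
* Benefits are reported at the common reference by design (see above);
  users who want re-solved benefits under an individual reference can
  compute them from the per-method tables directly.
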