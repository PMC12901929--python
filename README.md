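# bsim — binaural speech intelligibility modelling

`bsim` predicts speech recognition thresholds (SRTs) in noise for listeners
with normal or impaired hearing, and decomposes the benefit of spatially
separating speech and noise into its better-ear and binaural parts.  It is
aimed at computational audiology: model developers who need a testable
reference implementation of a blind binaural front-end with an
intelligibility-index back-end, and researchers who want to simulate how
individualized calibration changes cohort-level prediction accuracy.

## The model

The front-end is *blind*: it receives only the mixed speech-plus-noise
signals at the two ears.  Hearing loss is injected as interaurally
uncorrelated threshold-simulating noise (TSN) whose band levels follow the
listener's audiogram.  A 30-channel ERB-spaced gammatone filterbank feeds an
independent equalization–cancellation (EC) stage in every band below
1.5 kHz: the ears are equalized in level and phase, then either subtracted
(noise cancellation, useful at negative SNRs) or added (target
reinforcement, useful at positive SNRs), with the strategy chosen per band
by the speech-to-reverberation modulation energy ratio (SRMR) — the ratio
of envelope power in the four lowest to the four highest of eight
modulation filters.  Above 1.5 kHz the better ear is selected per band by
the same criterion.  Human binaural imprecision is modelled by Gaussian
jitter on the EC delay (σ = 65 µs) and gain (σ = 1.5 dB) over Monte-Carlo
realizations.

Because every front-end operation is linear, its dispositions can be
re-applied to clean speech and noise separately ("shadow filtering"),
enabling a non-blind back-end: per-band SNRs are clamped to ±15 dB, mapped
to band audibilities (SNR+15)/30, weighted by the critical-band importance
function, and summed to the speech intelligibility index (SII) ∈ [0, 1].
Sweeping the SNR from −20 to +20 dB (noise fixed at 65 dB SPL) and solving

    SII(SRT) = 0.2

yields the predicted SRT.  Per listener the three conditions S0N0 (speech
and noise frontal), S0N90 (noise at the worse ear's side) and S0mN90m
(same, better ear only) give the masking-release decomposition

    SRM = SRT(S0N0)    − SRT(S0N90)      spatial release from masking
    BRM = SRT(S0mN90m) − SRT(S0N90)      binaural release from masking
    BEL = SRT(S0N0)    − SRT(S0mN90m)    better-ear listening,  SRM = BEL + BRM

Two individualization schemes use a measured S0N0 SRT: **ISC_SII** replaces
the 0.2 reference by the curve value at the measured SRT (fitting S0N0,
predicting the rest), and **ISC_Noise** raises the external masker by
max(0, measured − predicted) dB (upward-only).  Cohort analysis covers
R²/bias/RMSE accuracy metrics, Fisher-Z comparison of correlations, Tukey
1.5×IQR outlier screening with a KS normality check, and a group-pair
"pattern projection" of one-sided Welch tests on the benefits.

A synthetic data layer generates everything needed to run without external
audio or clinical data: speech-shaped modulated tokens, spectrally matched
stationary maskers, parametric ITD/ILD spatialization, and listener cohorts
drawn from audiogram-shape templates (normal, flat N1–N4, steep S1–S3) with
ground-truth suprathreshold offsets.  See `docs/methods.md` for assumptions
and limitations.

## Worked example

```python
from bsim import BinauralSRTModel, SolverConfig, SRTEngine, ECConfig, synthesize_cohort

solver = SolverConfig(sample_rate=22050.0, token_duration=1.0, n_sentences=2, n_monte_carlo=3)
engine = SRTEngine(solver=solver, ec=ECConfig(n_monte_carlo=3))
cohort = synthesize_cohort(6, group_mix={"NH": 0.3, "N2": 0.4, "S2": 0.3}, seed=1)
model = BinauralSRTModel(cohort, engine=engine, seed=1)
model.simulate_measurements(measurement_noise_sd_db=1.0)

results = model.fit("isc_sii")
print(results.summary())
```

prints

```
Binaural SRT prediction results
==============================================
method:            isc_sii
listeners:         6
conditions:        S0N0, S0N90, S0mN90m

accuracy (measured vs predicted)
----------------------------------------------
         S0N0  S0N90  S0mN90m    SRM    BRM    BEL
R2        1.0  0.816    0.750  0.604  0.365  0.161
bias_db   0.0  0.550   -0.202 -0.528 -0.746  0.219
rmse_db   0.0  0.898    0.880  0.852  1.252  0.886
note: S0N0 is fitted (calibration), not predicted

predicted SRT (dB SNR) by condition
----------------------------------------------
            mean    sd  n
condition
S0N0       -7.42  1.36  6
S0N90     -17.83  1.81  6
S0mN90m   -11.23  1.85  6
```

Reading this: the S0N0 column is the ISC_SII calibration (R² = 1, zero
error by construction); S0N90 and S0mN90m are genuine predictions whose
errors combine the simulated measurement noise with the model's imperfect
tracking of each listener's suprathreshold offset.  The condition means
show ~10 dB spatial release for these mild-to-moderate losses, split into
~6 dB binaural and ~4 dB better-ear benefit
(`results.benefits("predicted")` gives the per-listener table).

The same pipeline is scriptable from the shell:

```sh
bsim simulate-cohort --n 20 --seed 1 --out-dir results
bsim predict --audiograms results/audiograms.csv --measured results/measured_srts.tsv \
     --method isc_sii --seed 1 --out results/predictions.tsv
bsim evaluate --results results/predictions.tsv --measured results/measured_srts.tsv
```

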