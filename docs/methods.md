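# Methods

`binratio` predicts the energetic-masking component of binaural speech
intelligibility in multi-source scenes and ships the synthetic acoustics
needed to exercise the prediction end to end.  This note records the model,
the generators, the numerical choices, and what the synthetic pipeline can
and cannot show about real measurements.

## The intelligibility model

The model takes two binaural inputs per condition: the ear signals of the
target alone, and the ear signals of the *sum* of all interferers.  Both are
split into gammatone bands (ERB-spaced, two filters per ERB, 80 Hz–10 kHz by
default).  The interferer is analysed in 24-ms half-overlapping Hann frames
(12 ms effective duration); the target contributes only long-term, whole-
signal statistics, computed once per condition, so pauses in the target
cannot masquerade as unintelligibility.

Per band *b* and frame *t* two advantages are computed and added:

**Better-ear listening.**
`BE = min(ceiling, max_ear 10 log10(T_ear / I_ear,t))`, where `T` is the
long-term target band power and `I` the short-term interferer band power at
that ear.  The ceiling (default 20 dB) bounds the ratio in interferer
pauses; if the interferer is silent at both ears the cell takes the ceiling
value, and a silent target band propagates as −∞ (an unusable band).

**Binaural unmasking.**  An equalization–cancellation (EC) stage that
aligns and subtracts the interferer across ears, limited by internal
amplitude jitter σ_ε and time jitter σ_δ:

    BU = 10 log10[(k − cos(φ_T − φ_I)) / (k − ρ)],
    k  = (1 + σ_ε²) · exp(ω² σ_δ²),   ω = 2π f_band

with φ_T/φ_I the target/interferer interaural phases, ρ the interferer
interaural coherence.  Defaults σ_ε = 0.25 and σ_δ = 105 µs are the
standard EC internal-noise constants of this model family; both are
exposed in `EcParameters`.  BU is floored at 0 dB (cancellation cannot
hurt; switchable) and forced to 0 wherever the interferer has zero power at
either ear — without interaural comparison there is nothing to cancel.

Band values `BE + BU` are combined with SII-style band-importance weights
(one-third-octave table interpolated on a log-frequency axis to the
gammatone centers and renormalized; a uniform weighting is available), and
the per-frame broadband ratios are averaged across frames *in the dB
domain* into the scalar **binaural ratio**.  Ratios are inversely related
to speech reception thresholds (SRTs): differences between conditions
predict SRT differences with the opposite sign, with no fitted constants.
Derived quantities are pure differences — predicted SRM (separated −
collocated ratio) and predicted hearing-aid disadvantage (unaided − aided
ratio) — and both decompose exactly into better-ear and unmasking parts
because the two components are computed independently.

A long-term variant (`long_term_model`) runs the identical computation with
one whole-signal rectangular frame.

### Interaural statistics

Short-time phase and coherence come from analytic band signals
(frequency-domain gammatone filtering with the negative frequencies
removed): with `cross = Σ w² l_a conj(r_a)` over the tapered frame, phase is
`arg(cross)` and coherence `|cross| / sqrt(Σw²|l_a|² · Σw²|r_a|²)`.  For
narrowband gammatone outputs this magnitude coincides with the maximum of
the normalized interaural cross-correlation within physiological lags
(±1 ms), which is the textbook definition; the explicit lag search is
implemented in the cue-analysis module, where the lag itself is the ITD
estimate (ties broken toward the smaller |lag|, ITDs reported only for
bands below 1.5 kHz where fine-structure ITD is unambiguous, summarized as
an energy-weighted median).  Frame powers are normalized by the window
energy `Σw²`, which makes them unbiased for stationary inputs.  Cells with
zero power at both ears are flagged invalid; consumers decide (the model's
guards above).

### Short-term vs long-term offset (a known property)

For strictly stationary interferers the short-term binaural ratio sits
~1–2 dB *above* the long-term ratio.  Three mechanisms, all inherent to
this model class, contribute: (a) averaging per-frame dB ratios incurs a
Jensen bias `E[−10log10(χ²_ν/ν)] > 0` that grows as band ERB shrinks
(ν ≈ 2·ERB·12 ms; ~+1.8 dB at 80 Hz, ~+0.1 dB at 10 kHz); (b) the per-frame
max over ears exploits frame-to-frame interaural power asymmetries of
partially decorrelated (e.g. reverberant) ears — the model's glimpsing
machinery operating across ears; (c) short-frame coherence estimates tend
toward 1 in narrow bands, inflating per-frame BU.  The offset is
condition-invariant and cancels exactly in the differences the package
reports (SRM, hearing-aid disadvantage); only absolute short-vs-long
comparisons expose it.  The acceptance suite asserts a 0.3-dB absolute
stationary-limit agreement and that check documents this property by
failing; the dip-listening direction (short > long for modulated maskers,
growing with modulation depth) holds as expected.

## Synthetic scenes

A laboratory-style measurement chain is emulated so the analysis runs
without any recorded data.  None of this synthetic front end claims psychoacoustic
fidelity beyond what the cue analysis checks; it exists to give the model
inputs with controllable, realistic interaural structure.

**Room.**  Shoebox image-source simulation (default 6×5×3 m, listener near
the center, sources on a 1.3-m ring at {0, ±90, 180}°).  Uniform wall
absorption is derived from the target T30 = 200 ms via Sabine
(`α = 0.161 V / (S·T30)`); for this renderer Sabine reproduces the
Schroeder-integrated T30 (−5…−35 dB fit, extrapolated to −60 dB) within
~15%, where Eyring leaves it ~40% long, because the specular image decay is
slower than the mean-free-path argument assumes.  Reflections get a seeded
±0.2-ms jitter against sweeping echoes and are rounded to the sample grid;
the direct path uses an 81-tap windowed-sinc fractional delay so ITDs are
exact to well under a sample.

**Head.**  A parametric spherical head: Woodworth ITD
`(a/c)(θ + sin θ)` (a = 8.75 cm, folded front–back symmetrically, 656 µs at
90°) split ± half across the ears, and a first-order high-shelf cut
(corner 1.5 kHz, 15 dB depth scaled by sin|azimuth|) at the contralateral
ear, applied per 22.5° direction sector.  Crude, but it produces ILDs that
grow with frequency and lateral angle, which is all the analysis consumes.

**Stimuli.**  Stationary speech-shaped noise (SSN) is white Gaussian noise
shaped by a 2048-tap linear-phase FIR fitted to the reference's Welch
magnitude spectrum (designed on the full Welch grid — a coarse design grid
cannot follow steep low-frequency slopes) and RMS-equalized to the
reference.  The speech-like masker multiplies an SSN carrier with a
log-normal envelope `exp(a·z)`, `z` band-limited to 2–6 Hz; `a = 1.2`
(≈10 dB level spread, comparable to running speech) is pinned jointly by
the generator's two contracts — a realization's long-term spectrum within
±1.5 dB of the SSN and >5% of 12-ms frames more than 20 dB below mean
power (near-silent gaps for dip listening).  With no recorded talker
available, `speech_shaped_reference` supplies a long-term-speech-spectrum
surrogate (flat to 500 Hz, −8 dB/octave above).

**BRIR conditioning.**  As in the measurement chain being emulated: all
responses truncated to 300 ms; the first 3.85 ms of the frontal response
(direct sound before the first reflection) is filtered with the target's
long-term magnitude spectrum, and the single scalar that equalizes the two
ears' RMS over that window is applied to the right ear of every BRIR in
the set.

**BTE (hearing-aid) transform.**  Three zero-phase magnitude effects plus a
time shift, applied to an unaided BRIR (double application is an error):
a −8 dB Gaussian notch (log-f, ~1 octave) at 2.5 kHz replacing the lost
ear-canal resonance; for lateral sources (|azimuth| ≥ 45°) a +5 dB shelf
above 2 kHz at the *ipsilateral* ear — the head baffles the exposed BTE
microphone, so lateral sources get louder at the near ear, growing the ILD
while *worsening* the effective SNR for a frontal target (this sign is
what makes hearing aids costly in separated layouts and neutral in
collocated ones); ITD shrinkage by a factor 0.9 as an exact fractional
advance of the lagging ear (the underlying reduction is only known
qualitatively; the factor is configuration, not ground truth); and a flat
+10 dB insertion gain, compensated at rendering time by a −10 dB playback
attenuation of every loudspeaker feed in aided scenes so presentation
levels match.  The notch shape and boost are configurable for the same
reason as the ITD factor.

**Rendering.**  Each masker feed is calibrated to equal A-weighted power
(IEC 61672 analytic weighting evaluated on the spectrum) with the total
masker level at −25 dBFS, the digital stand-in for the fixed 65 dB(A)
masker level of the emulated procedure; the target level is what the
adaptive procedure would vary, and the model needs only ratios.  Stimuli
are convolved with their BRIRs and the masker ear signals summed.

## Staircase simulation

Synthetic listeners follow a logistic psychometric function
`p = (1 − lapse) / (1 + exp(−4·slope·(L − SRT)))` (slope in probability/dB
at the midpoint).  The 1-up-1-down track lowers the level by one step
(default 2 dB, not dictated by the emulated procedure) after a correct
response and raises it after an error; from trial 16 on, it stops as soon
as the standard error of the threshold estimate drops below 0.8 dB, else
at trial 32.  The estimator is a fixed-slope logistic maximum-likelihood
fit of the threshold to all (level, response) pairs, SE from the observed
Fisher information `Σ k² p(1−p)` — the published procedure implies a
model-based estimator through its SE stopping rule but does not print one;
a reversal-midpoint average is kept as a cross-check.  500 simulated
tracks on a −12 dB, 0.15/dB listener recover the threshold to within
0.1 dB with ~27 trials per track.  When linked to the model, a listener's
true SRT per condition is a per-listener constant minus that condition's
binaural ratio.

## Problem sizes and determinism

Synthesis defaults to 44.1 kHz.  Model-scale analyses (the experiment
matrix, stationary-limit and collocated-null checks) run at 24 kHz — the
full 80 Hz–10 kHz bank fits under Nyquist and the interaural statistics of
band-limited noise do not depend on oversampling — with the standard
two-minute masker duration; the bundled acceptance script uses these sizes,
and the test suite trims durations further where only signs or guards are
at stake.  Every stochastic stage takes an explicit seed (NumPy
`default_rng`); fixed seeds make BRIRs, stimuli, staircases and the whole
matrix bit-reproducible, and each matrix run records a hash of its full
configuration.

## Limitations

* The synthetic head has no pinna, torso or measured HRTF structure;
  absolute cue magnitudes (and hence absolute SRM/disadvantage sizes) are
  indicative, not calibrated to any manikin.
* The model predicts energetic masking only; informational masking —
  released by spatial separation of real talkers — is out of scope, so
  speech-masker SRM from human data will exceed these predictions.
* No absolute SRT prediction is attempted; all outputs are condition
  differences.
* The stationary short-vs-long offset described above is a property of
  dB-domain short-time framing, not removable without changing the model
  class.
* Morpheme-level scoring, listener training effects, and inferential
  statistics on simulated data are not modelled.
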