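# binratio

Binaural speech-intelligibility modelling on synthetic room scenes.

When listeners wear simple linear hearing aids, speech-in-noise thresholds
can get *worse*, and mostly so when target and maskers are spatially
separated.  `binratio` implements the short-term binaural
intelligibility model that explains this as an energetic-masking effect —
better-ear glimpsing plus equalization–cancellation binaural unmasking —
together with everything needed to study it without any recorded data:
an image-source room simulator with a spherical-head receiver, speech-shaped
and speech-like masker generators, a behind-the-ear (BTE) microphone
transform, interaural cue analysis, and an adaptive-staircase simulation of
the behavioural procedure.

It is aimed at hearing scientists and audio engineers who want a
self-contained, reproducible sandbox for binaural intelligibility
predictions: every stage is importable, seeded, and tested.

## The model in brief

For gammatone band *b* (ERB-spaced, 2 filters/ERB, 80 Hz–10 kHz) and 24-ms
Hann frame *t* of the summed interferers (target statistics are long-term,
computed once):

    BE(b,t) = min( ceiling, max_ear 10 log10 T_ear(b) / I_ear(b,t) )
    BU(b,t) = 10 log10 [ (k − cos(φ_T − φ_I)) / (k − ρ) ],
              k = (1 + σ_ε²) · exp(ω² σ_δ²)

with φ_T, φ_I the target/interferer interaural phases, ρ the interferer
interaural coherence, σ_ε = 0.25 and σ_δ = 105 µs the EC internal-noise
constants, and a 20-dB ceiling guarding interferer pauses.  Band values
BE + BU are SII-importance-weighted and frame-averaged into the broadband
**binaural ratio** (dB).  Ratios are inversely related to speech reception
thresholds: condition differences predict SRT differences with no fitting —
spatial release from masking (SRM) as separated − collocated ratio, and
hearing-aid disadvantage as unaided − aided ratio.

## Worked example

```bash
python examples/04_predict_intelligibility.py
```

builds a reverberant scene (T30 = 200 ms, frontal speech-shaped target,
three stationary maskers) in both layouts and prints:

```
separated  : binaural ratio  -1.27 dB (better-ear  -2.05, unmasking +0.78)
collocated : binaural ratio  -3.68 dB (better-ear  -3.69, unmasking +0.01)
predicted SRM: +2.41 dB
```

Reading: the separated layout improves the effective target-to-interferer
ratio by 2.4 dB — most of it from better-ear listening, ~0.8 dB from
binaural unmasking — so the model predicts SRTs about 2.4 dB lower than in
the collocated layout.  Collocated unmasking is nil because target and
maskers share one set of interaural cues.

The other examples cover the filterbank (`01`), the room simulator (`02`),
the BTE cue changes (`03`), staircase SRT simulation (`05`) and the full
eight-condition experiment matrix (`06`).  A thin CLI mirrors the pipeline
stages (`binratio synth-scene | condition-brirs | cues | predict |
simulate-srt | run-matrix`).

## Layout

| Path | Contents |
| --- | --- |
| `src/binratio/signal.py` | signal containers, WAV I/O |
| `src/binratio/gammatone.py` | ERB scale, gammatone bank (Slaney biquad cascade) |
| `src/binratio/framing.py`, `stats.py` | short-time framing, interaural statistics |
| `src/binratio/noise.py` | SSN and speech-like masker generators |
| `src/binratio/rooms.py` | image-source BRIR simulation, Woodworth ITD, T30 |
| `src/binratio/bte.py` | behind-the-ear microphone transform |
| `src/binratio/scene.py` | BRIR conditioning, scene rendering, bundles |
| `src/binratio/model.py` | the intelligibility model |
| `src/binratio/cues.py` | ILD/ITD/coherence profiles |
| `src/binratio/staircase.py` | 1-up-1-down SRT simulation |
| `src/binratio/pipeline.py`, `cli.py` | experiment matrix, CLI |

`docs/methods.md` documents the model assumptions, generator calibrations,
numerical choices and known limitations.
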