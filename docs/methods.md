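# Methods

## Signal-processing chain

An input token passes through, in order:

1. **Active-speech-level normalization** (ITU-T P.56 method B). The
   rectified signal is double-exponentially smoothed (time constant
   30 ms); for a descending series of binary-divided thresholds, samples
   whose envelope exceeds the threshold — plus a 200 ms hangover — are
   counted as active, and the reported level is the one at which the
   active-level-to-threshold margin crosses 15.9 dB (linear interpolation
   between neighbouring thresholds). Tokens are normalized to an active
   level of −26 dB re full scale, the conventional normalization point, so
   that token-to-token level differences carry no information before the
   deliberate rove is applied. For a stationary signal the active level
   equals the RMS level to within ~0.1 dB.
2. **Resampling to 16 kHz** by polyphase filtering. The anti-alias filter
   uses a Kaiser window with β = 10: the ripple of a lighter window
   (β = 5) leaves a ≈ −56 dB error floor on band-limited content, which
   would dominate the round-trip error budget.
3. **Equal-ERB FIR filterbank**, 50–7000 Hz. Band edges divide the ERB
   number scale E(f) = 21.4·log10(0.00437 f + 1) evenly; with four bands
   the interior edges fall at 400.35, 1190.90 and 2974.76 Hz, and the
   8-band grid nests the 4-band one exactly (8 = 2×4). Filters are
   513-tap (order 512) Hamming windowed-sinc band-passes with the band
   edges at their −6 dB points; the order/2 group delay is removed so band
   signals stay aligned with the input. Note that under the standard ERB
   formula the 4-band grid dedicates two channels to 1.2–7 kHz (edges at
   1191 and 2975 Hz), i.e. "above 2 kHz" only approximately.
4. **Envelope extraction**: Hilbert magnitude, then a zero-phase 6th-order
   Butterworth low-pass at 23 Hz. The zero-phase filter is realized
   spectrally as the exact forward-backward magnitude
   |H(f)|² = 1/(1 + (f/23)¹²) applied to a reflect-padded segment
   (padding ≈ 3 filter time constants). This has the same magnitude as a
   padded forward-backward time-domain pass but exactly zero phase, so
   filtering a reversed signal is exactly the reverse of filtering the
   signal — a property padded `filtfilt` implementations only approximate
   at their edges. A flag (`order_is_total`) selects the alternative
   reading in which the *net* magnitude order is six. Envelopes stay at
   16 kHz and are clamped at zero, since they act as amplitude gains.
5. **Carrier synthesis**: envelopes modulate fixed sine carriers (170 Hz;
   138/170/210/259.5 Hz; 94.5/116.5/141.5/170/202.5/239/280.5/327.5 Hz)
   with per-tone gains (reference tone 0 dB) equalizing perceived tactile
   intensity across frequency. All carriers start at phase zero: "fixed
   phase" constrains phases to be identical across stimuli, not to any
   particular value. With one analysis band, the broadband envelope drives
   every tone, so the tone complex is spectrally uninformative — the
   control condition.
6. **Level**: the mix is scaled to 141.5 dB re 1 µm/s² RMS (11.885 m/s²,
   1.2 G) and then roved by a uniform draw on the dB axis (±3 dB),
   applied independently per trial interval.

## Trial assembly

Within a pair, both members are faded with a 20-ms raised-cosine
(half-Hann) ramp whose zero point is the effective end of the shorter
token — the last sample at or above 1% of the absolute peak — so duration
is not a cue. Pairs containing a diphthong or /g d l r v w j/ are exempt
(those phonemes cannot be produced in isolation unchanged). Duration
matching is applied to the audio before vocoding; the 3AFC trial places
the odd phoneme (uniformly chosen member, uniformly chosen interval)
against two independently roved instances of one token of the other
member, with a 250 ms inter-stimulus interval. Whether the two "same"
intervals of the original experiment reused one token or drew two is not
determinable; the default here is one token, independently roved.

## Synthetic corpus

The corpus emulates the statistical structure the discrimination task
depends on, not natural speech:

- **Talkers**: per-token F0 draws from N(145.4, 12.4²) Hz (male) and
  N(208.2, 14.7²) Hz (female), ±3% per-token jitter, ±10% duration
  jitter; four tokens per phoneme. Female formants are male values ×1.15.
- **Vowels/sonorants**: additive harmonic source (−6 dB/oct rolloff)
  shaped by two Lorentzian formant resonances (≈80/100 Hz bandwidth,
  narrow enough that a 1/3-octave-smoothed spectrum still peaks at the
  formants); diphthongs glide linearly between formant targets.
- **Fricatives**: Gaussian-band noise centred on the place-cue frequency,
  high-passed above ≈350 Hz (frication carries little low-frequency
  energy); voiced fricatives add a voice bar (first two harmonics of F0)
  at comparable level, giving ≥10 dB more sub-400 Hz energy than their
  voiceless cognates.
- **Plosives**: 25 ms decaying burst at the place-cue frequency after
  10 ms of silence, followed by aspiration (voiceless) or a brief schwa
  tail (voiced plosives cannot stand alone).

The 53 experiment pairs are reproduced with their contrast-type labels
(ASCII names stand in for IPA). Within-pair acoustic similarity of the
real corpus is unknowable; contrast magnitudes here are free parameters
with the defaults above, so simulated accuracies are not comparable to
human scores in magnitude.

## Simulated listener

Each interval is reduced to: per-carrier narrow-band (±10 Hz) log
energies with the mean removed — making the level rove exactly
uninformative — concatenated with a unit-norm 12-bin temporal envelope
shape. Gaussian internal noise (SD 0.3, in log₁₀-energy units) is added
per feature; the response is the interval whose noisy features are
farthest (summed Euclidean distance) from the other two, ties broken at
random. The noise default is set so that spectral cues of order 10 dB
(the voice bar) survive while sub-dB envelope differences do not; it is a
demonstration of information transfer through the vocoder, not a model of
tactile perception. Consequences that do hold: with one analysis band the
normalized channel profile is constant, so voicing pairs sit near chance;
with matched bands/tones the voice-bar channels separate them; identical
tokens differing only in rove are at chance.

## Statistics

Scores are percent correct per participant × condition (× talker ×
subgroup). Paired t-tests can be reconstructed from printed summaries as
t = mean/(sd/√n), df = n−1. The Holm step-down correction accepts a
family size `m` larger than the number of supplied p-values, as the
study's secondary battery corrects for 51 tests while individual analyses
report fewer; undefined p-values (zero-variance differences) propagate as
NaN without shrinking the family. Repeated-measures ANOVA (1–3 within
factors, balanced complete data, replicates averaged per cell) tests each
effect against its effect×subject interaction; no sphericity correction is
applied by default since Mauchly's test is provided (orthonormal-contrast
W with the standard chi-square approximation, df = k(k−1)/2 − 1).
Exploratory Spearman correlations are reported uncorrected.

## F0 tracking and spectra

The NCF pitch tracker uses 30-ms Hamming frames with a 5-ms hop and a
60–400 Hz search range (bracketing the talkers' 107–285 Hz with margin).
The pitch lag maximizes the raw windowed NCF — the taper penalizes long
lags, which usefully discourages octave-down errors — while the harmonic
ratio divides that maximum by the window's own NCF, since the taper would
otherwise push low-F0 (~107 Hz) frames below the 0.75 voicing threshold.
Sub-sample lags come from parabolic interpolation. F0 summaries use
voiced frames only.

The LTAS is a Hann-windowed mean PSD (FFT 4096, hop 2048) over all
frames of all tokens, Gaussian-smoothed on the log2-frequency axis with
a 1/3-octave FWHM (σ = (1/3)/2.355 octaves; the FWHM-vs-σ convention is a
recorded choice). The tactile spectrogram is the raw envelope matrix, one
row per carrier, in dB re the maximum envelope amplitude, unwindowed.

## Problem sizes and defaults

The full simulated design is 53 pairs × 2 talkers × 2 repeats × 5
conditions = 1060 trials per participant, 26 participants. The bundled
direction checks and the acceptance script run a scaled-down design — the
three voicing pairs, four conditions, 6 participants × 4 repeats (144
trials per condition) and a 300-trial rove-only control — which is ample
for sign-only conclusions; magnitudes are not asserted anywhere. Vocoded
stimuli and listener features are cached per (talker, pair, tokens,
condition) since the rove re-applies per interval and the features are
rove-invariant.

## Known limitations

- Tokens are stylized; spectral tilt, coarticulation and prosody of real
  speech are absent, so passing tests demonstrate the pipeline's
  information transfer, not human-level effects.
- Human behavioural percentages are not reproducible from simulation and
  are never asserted; only printed-summary t reconstructions, physical
  and spectral constants, distributional properties, and effect
  *directions* are.
- The masker level (60 dBA) is hardware-bound; pink noise is generated at
  a relative digital level only.
- P.56 constants (30 ms smoothing, 0.2 s hangover, 15.9 dB margin) follow
  the standard's method B; threshold spacing is binary and interpolation
  linear in dB, adequate to ~0.1 dB for speech-like material.
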