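"""Synthetic phoneme corpus and simulated listener.

The corpus the study recorded (two southern-English talkers, 44 phonemes,
four tokens each) is not publicly released, so this module synthesizes a
stand-in with the acoustic structure the discrimination task depends on:

* two talkers with fundamental frequencies drawn per token around 145.4 Hz
  (male) and 208.2 Hz (female);
* voicing carried by a low-frequency voice bar below 400 Hz;
* place of articulation carried by the spectral peak of frication or burst
  noise at mid-to-high frequencies;
* manner carried by temporal envelope shape (burst vs. sustained);
* vowels carried by F1/F2 formant pairs, diphthongs by formant glides.

Tokens are deliberately stylized: additive harmonic sources shaped by
formant resonances and band-shaped noise, not natural speech.  The 53
phoneme pairs of the experiment are reproduced with their contrast-type
labels (ASCII phoneme names stand in for IPA).

The simulated listener turns a 3AFC trial into a response using a small,
level-normalized feature vector (per-carrier envelope energies plus a
coarse temporal envelope shape) with additive Gaussian internal noise:
enough to demonstrate information transfer through the vocoder, with no
claim to model human tactile perception.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio_io import AudioSignal, Unit
from .stimulus import EXEMPT_CONSONANTS, TrialRecord

__all__ = [
    "TokenSpec",
    "PairSpec",
    "Corpus",
    "TALKER_F0_HZ",
    "PAIRS",
    "PHONEME_TABLE",
    "pair_is_exempt",
    "synthesize_token",
    "generate_corpus",
    "stimulus_features",
    "simulated_listener",
]

# per-talker F0 distributions (mean, SD) the corpus emulates
TALKER_F0_HZ = {"male": (145.4, 12.4), "female": (208.2, 14.7)}
F0_JITTER_FRAC = 0.03  # per-token F0 jitter of the four repeats
DURATION_JITTER_FRAC = 0.10
DEFAULT_INTERNAL_NOISE_SD = 0.3

# Phoneme inventory (ASCII names for IPA): class, voicing and the acoustic
# cue parameters.  Formants are male values; female tokens scale them by
# 1.15.  Noise peaks/bandwidths are in Hz.
PHONEME_TABLE: dict[str, dict] = {
    # --- voiceless plosives (burst noise peak encodes place) ---
    "p": dict(klass="plosive", voiced=False, noise_peak=800.0, noise_bw=1200.0),
    "t": dict(klass="plosive", voiced=False, noise_peak=3800.0, noise_bw=1800.0),
    "k": dict(klass="plosive", voiced=False, noise_peak=1800.0, noise_bw=1200.0),
    # --- voiced plosives ---
    "b": dict(klass="plosive", voiced=True, noise_peak=800.0, noise_bw=1200.0),
    "d": dict(klass="plosive", voiced=True, noise_peak=3800.0, noise_bw=1800.0),
    "g": dict(klass="plosive", voiced=True, noise_peak=1800.0, noise_bw=1200.0),
    # --- voiceless fricatives (frication peak encodes place) ---
    "f": dict(klass="fricative", voiced=False, noise_peak=1400.0, noise_bw=2600.0),
    "th": dict(klass="fricative", voiced=False, noise_peak=2100.0, noise_bw=2600.0),
    "s": dict(klass="fricative", voiced=False, noise_peak=6000.0, noise_bw=1400.0),
    "sh": dict(klass="fricative", voiced=False, noise_peak=3200.0, noise_bw=1200.0),
    # --- voiced fricatives ---
    "v": dict(klass="fricative", voiced=True, noise_peak=1400.0, noise_bw=2600.0),
    "dh": dict(klass="fricative", voiced=True, noise_peak=2100.0, noise_bw=2600.0),
    "z": dict(klass="fricative", voiced=True, noise_peak=6000.0, noise_bw=1400.0),
    "zh": dict(klass="fricative", voiced=True, noise_peak=3200.0, noise_bw=1200.0),
    # --- affricate ---
    "ch": dict(klass="affricate", voiced=False, noise_peak=3200.0, noise_bw=1200.0),
    # --- sonorants (formant pair encodes place) ---
    "l": dict(klass="sonorant", voiced=True, formants=(400.0, 1300.0)),
    "r": dict(klass="sonorant", voiced=True, formants=(480.0, 1100.0)),
    "j": dict(klass="sonorant", voiced=True, formants=(300.0, 2200.0)),
    "w": dict(klass="sonorant", voiced=True, formants=(350.0, 800.0)),
    "m": dict(klass="sonorant", voiced=True, formants=(250.0, 900.0)),
    "n": dict(klass="sonorant", voiced=True, formants=(250.0, 1400.0)),
    # --- monophthongs ---
    "i": dict(klass="vowel", voiced=True, formants=(400.0, 1900.0)),  # ih
    "aa": dict(klass="vowel", voiced=True, formants=(700.0, 1100.0)),
    "ii": dict(klass="vowel", voiced=True, formants=(300.0, 2300.0)),
    "ae": dict(klass="vowel", voiced=True, formants=(750.0, 1750.0)),
    "oo": dict(klass="vowel", voiced=True, formants=(450.0, 750.0)),
    "u": dict(klass="vowel", voiced=True, formants=(400.0, 1000.0)),  # uh as in put
    "uu": dict(klass="vowel", voiced=True, formants=(320.0, 900.0)),
    "uh": dict(klass="vowel", voiced=True, formants=(650.0, 1200.0)),  # strut
    "e": dict(klass="vowel", voiced=True, formants=(550.0, 1850.0)),
    "o": dict(klass="vowel", voiced=True, formants=(600.0, 950.0)),  # lot
    # --- diphthongs (formant glide start -> end) ---
    "oi": dict(klass="vowel", voiced=True, formants=(450.0, 750.0), formants_end=(400.0, 1900.0)),
    "ei": dict(klass="vowel", voiced=True, formants=(550.0, 1800.0), formants_end=(350.0, 2100.0)),
    "au": dict(klass="vowel", voiced=True, formants=(750.0, 1300.0), formants_end=(400.0, 1000.0)),
    "ia": dict(klass="vowel", voiced=True, formants=(400.0, 1900.0), formants_end=(520.0, 1500.0)),
    "ou": dict(klass="vowel", voiced=True, formants=(500.0, 1300.0), formants_end=(380.0, 950.0)),
    "ua": dict(klass="vowel", voiced=True, formants=(400.0, 1000.0), formants_end=(560.0, 1400.0)),
    "ea": dict(klass="vowel", voiced=True, formants=(600.0, 1750.0), formants_end=(550.0, 1400.0)),
}

_DIPHTHONGS = {p for p, d in PHONEME_TABLE.items() if "formants_end" in d}

_BASE_DURATION_S = {
    "vowel": 0.30,
    "fricative": 0.25,
    "plosive": 0.14,
    "affricate": 0.20,
    "sonorant": 0.25,
}
_DIPHTHONG_DURATION_S = 0.38

# The experiment's 53 phoneme pairs, labelled by contrast type.
PAIRS: list[tuple[str, str, str]] = [
    # consonants: place in voiceless plosives
    ("t", "p", "place_voiceless_plosive"),
    ("t", "k", "place_voiceless_plosive"),
    ("k", "p", "place_voiceless_plosive"),
    # place in voiceless fricatives
    ("f", "th", "place_voiceless_fricative"),
    ("f", "s", "place_voiceless_fricative"),
    ("sh", "s", "place_voiceless_fricative"),
    # place in voiced plosives
    ("d", "b", "place_voiced_plosive"),
    ("g", "d", "place_voiced_plosive"),
    ("g", "b", "place_voiced_plosive"),
    # place in voiced fricatives
    ("v", "dh", "place_voiced_fricative"),
    ("v", "z", "place_voiced_fricative"),
    ("dh", "z", "place_voiced_fricative"),
    # place in sonorants
    ("l", "r", "place_sonorant"),
    ("j", "l", "place_sonorant"),
    ("m", "n", "place_sonorant"),
    # voicing
    ("z", "s", "voicing"),
    ("zh", "sh", "voicing"),
    ("th", "dh", "voicing"),
    # manner
    ("t", "s", "manner"),
    ("b", "w", "manner"),
    ("ch", "sh", "manner"),
    # manner & place
    ("dh", "b", "manner_place"),
    ("k", "s", "manner_place"),
    ("g", "r", "manner_place"),
    # place & voicing
    ("v", "s", "place_voicing"),
    ("th", "z", "place_voicing"),
    ("m", "v", "place_voicing"),
    # vowels: monophthongs
    ("i", "aa", "monophthong"),
    ("ii", "ae", "monophthong"),
    ("oo", "i", "monophthong"),
    ("oo", "aa", "monophthong"),
    ("u", "aa", "monophthong"),
    ("uu", "uh", "monophthong"),
    ("ae", "e", "monophthong"),
    ("u", "i", "monophthong"),
    ("ae", "o", "monophthong"),
    ("ii", "uu", "monophthong"),
    ("uh", "ae", "monophthong"),
    ("uu", "u", "monophthong"),
    # diphthongs
    ("oi", "ei", "diphthong"),
    ("oi", "au", "diphthong"),
    ("au", "ei", "diphthong"),
    ("ia", "ou", "diphthong"),
    ("ua", "ei", "diphthong"),
    ("ea", "ua", "diphthong"),
    # monophthong vs diphthong
    ("u", "ei", "monophthong_diphthong"),
    ("ii", "ei", "monophthong_diphthong"),
    ("ia", "o", "monophthong_diphthong"),
    ("uu", "ia", "monophthong_diphthong"),
    ("ou", "uu", "monophthong_diphthong"),
    ("au", "aa", "monophthong_diphthong"),
    ("aa", "ei", "monophthong_diphthong"),
    ("oo", "ei", "monophthong_diphthong"),
]


def pair_is_exempt(a: str, b: str) -> bool:
    """Duration-matching exemption: diphthongs and /g d l r v w j/."""
    return bool(
        {a, b} & _DIPHTHONGS or {a, b} & EXEMPT_CONSONANTS
    )


@dataclass(frozen=True)
class TokenSpec:
    """Everything needed to synthesize one token of one phoneme."""

    phoneme: str
    klass: str  # vowel | fricative | plosive | sonorant | affricate
    voiced: bool
    duration_s: float
    talker_id: str
    f0_hz: float | None = None
    formants_hz: tuple | None = None
    formants_end_hz: tuple | None = None
    noise_peak_hz: float | None = None
    noise_bw_hz: float | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.voiced:
            if self.f0_hz is None or not (80.0 <= self.f0_hz <= 300.0):
                raise ValueError("voiced tokens need f0 in [80, 300] Hz")
        if self.formants_hz is not None:
            f1, f2 = self.formants_hz
            if not f1 < f2:
                raise ValueError("formants must be ordered F1 < F2")

    @property
    def is_diphthong(self) -> bool:
        return self.formants_end_hz is not None


@dataclass(frozen=True)
class PairSpec:
    token_a: str
    token_b: str
    contrast_type: str

    @property
    def pair_id(self) -> str:
        return f"{self.token_a}-{self.token_b}"

    @property
    def exempt(self) -> bool:
        return pair_is_exempt(self.token_a, self.token_b)


def _formant_gain(freqs: np.ndarray, formants: np.ndarray) -> np.ndarray:
    """Two-resonance spectral envelope with a small floor.

    ``formants`` has shape (..., 2) broadcastable against ``freqs``.
    Lorentzian-magnitude resonances of ~80/100 Hz bandwidth; narrow enough
    that 1/3-octave smoothing of the spectrum still peaks at the formants.
    """
    f1 = formants[..., 0]
    f2 = formants[..., 1]
    g1 = 1.0 / np.sqrt(1.0 + np.square((freqs - f1) / 40.0))
    g2 = 0.9 / np.sqrt(1.0 + np.square((freqs - f2) / 50.0))
    return g1 + g2 + 0.01


def _token_envelope(n: int, rate: float, attack_s: float, release_s: float) -> np.ndarray:
    """Raised-cosine attack/release around a sustained plateau."""
    env = np.ones(n)
    na = min(int(attack_s * rate), n // 2)
    nr = min(int(release_s * rate), n - na)
    if na > 0:
        env[:na] = 0.5 * (1 - np.cos(np.pi * np.arange(na) / na))
    if nr > 0:
        env[n - nr :] = 0.5 * (1 + np.cos(np.pi * np.arange(nr) / nr))
    return env


def _harmonic_complex(
    f0: float,
    n: int,
    rate: float,
    formant_traj: np.ndarray,  # (n, 2)
    rng: np.random.Generator,
    fmax: float = 7500.0,
) -> np.ndarray:
    """Additive glottal-like source with per-sample formant shaping."""
    n_harm = max(int(fmax / f0), 2)
    h = np.arange(1, n_harm + 1)
    t = np.arange(n) / rate
    rolloff = 1.0 / h  # -6 dB/octave source spectrum
    phases = rng.uniform(0, 2 * np.pi, n_harm)
    # per-sample gain of each harmonic from the (possibly gliding) formants
    gains = _formant_gain(
        h[None, :] * f0, formant_traj[:, None, :]
    )  # (n, n_harm)
    waves = np.sin(2 * np.pi * f0 * np.outer(t, h) + phases)
    return np.sum(waves * gains * rolloff, axis=1)


def _shaped_noise(
    n: int,
    rate: float,
    peak_hz: float,
    bw_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian-band noise centred on the place cue, high-passed above ~350 Hz.

    Frication and burst noise carry almost no energy below a few hundred
    hertz, which keeps the voice bar the only low-frequency voicing cue.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.exp(-0.5 * np.square((f - peak_hz) / (bw_hz / 2.0)))
    with np.errstate(divide="ignore"):
        highpass = 1.0 / (1.0 + np.power(350.0 / np.maximum(f, 1e-6), 4))
    x = np.fft.irfft(spec * shape * highpass, n=n)
    return x


def _voice_bar(f0: float, n: int, rate: float) -> np.ndarray:
    """Low-frequency periodic voicing component (first two harmonics)."""
    t = np.arange(n) / rate
    bar = np.sin(2 * np.pi * f0 * t) + 0.5 * np.sin(2 * np.pi * 2 * f0 * t)
    return bar


def synthesize_token(
    spec: TokenSpec, rate_hz: float = 16000.0, rng: np.random.Generator | None = None
) -> AudioSignal:
    """Render one phoneme token as digital audio at unit-free level.

    Vowels/sonorants: harmonic source shaped by (gliding) formants.
    Voiceless fricatives: band-shaped noise.  Voiced fricatives add a
    <400 Hz voice bar at comparable level.  Plosives: a short burst, then
    aspiration (voiceless) or a brief schwa tail (voiced).  Affricate:
    burst gated straight into frication.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n = int(round(spec.duration_s * rate_hz))
    if n < 8:
        raise ValueError("token too short to synthesize")

    if spec.klass in ("vowel", "sonorant"):
        start = np.asarray(spec.formants_hz, float)
        end = np.asarray(
            spec.formants_end_hz if spec.is_diphthong else spec.formants_hz, float
        )
        frac = np.linspace(0.0, 1.0, n)[:, None]
        traj = start[None, :] * (1 - frac) + end[None, :] * frac
        x = _harmonic_complex(spec.f0_hz, n, rate_hz, traj, rng)
        x *= _token_envelope(n, rate_hz, 0.02, 0.04)
    elif spec.klass == "fricative":
        x = _shaped_noise(n, rate_hz, spec.noise_peak_hz, spec.noise_bw_hz, rng)
        x *= _token_envelope(n, rate_hz, 0.05, 0.05)
        x /= max(np.sqrt(np.mean(np.square(x))), 1e-12)
        if spec.voiced:
            x += 0.8 * _voice_bar(spec.f0_hz, n, rate_hz) * _token_envelope(
                n, rate_hz, 0.03, 0.05
            )
    elif spec.klass in ("plosive", "affricate"):
        burst_n = int(0.025 * rate_hz)
        lead_n = int(0.01 * rate_hz)
        x = np.zeros(n)
        burst = _shaped_noise(
            burst_n, rate_hz, spec.noise_peak_hz, spec.noise_bw_hz, rng
        )
        burst *= np.exp(-np.arange(burst_n) / (0.006 * rate_hz))
        stop = min(lead_n + burst_n, n)
        x[lead_n:stop] = burst[: stop - lead_n]
        x /= max(np.max(np.abs(x)), 1e-12)
        tail_n = n - stop
        if spec.klass == "affricate" and tail_n > 8:
            fric = _shaped_noise(
                tail_n, rate_hz, spec.noise_peak_hz, spec.noise_bw_hz, rng
            )
            fric *= _token_envelope(tail_n, rate_hz, 0.01, 0.04)
            x[stop:] = 0.5 * fric / max(np.sqrt(np.mean(np.square(fric))), 1e-12)
        elif spec.voiced and tail_n > 8:
            # brief schwa tail, as voiced plosives cannot stand alone
            frac = np.linspace(0.0, 1.0, tail_n)[:, None]
            schwa = np.asarray([500.0, 1500.0])
            traj = np.broadcast_to(schwa, (tail_n, 2)) * (1.0 - 0.1 * frac)
            tail = _harmonic_complex(spec.f0_hz, tail_n, rate_hz, traj, rng)
            tail *= _token_envelope(tail_n, rate_hz, 0.01, 0.04)
            x[stop:] = 0.6 * tail / max(np.max(np.abs(tail)), 1e-12)
        elif tail_n > 8:
            asp = _shaped_noise(tail_n, rate_hz, 1500.0, 2000.0, rng)
            asp *= np.exp(-np.arange(tail_n) / (0.02 * rate_hz))
            x[stop:] = 0.15 * asp / max(np.max(np.abs(asp)), 1e-12)
    else:
        raise ValueError(f"unknown phoneme class {spec.klass!r}")

    rms = np.sqrt(np.mean(np.square(x)))
    if rms == 0:
        raise ValueError("synthesized token is silent")
    return AudioSignal(0.05 * x / rms, rate_hz, Unit.DIGITAL)


@dataclass
class Corpus:
    """tokens[(talker, phoneme)] -> list of four AudioSignals (+ specs)."""

    tokens: dict
    specs: dict
    pairs: list[PairSpec]
    seed: int

    @property
    def talkers(self) -> list[str]:
        return sorted({t for t, _ in self.tokens})

    def manifest(self) -> pd.DataFrame:
        rows = []
        for (talker, phoneme), specs in sorted(self.specs.items()):
            for i, s in enumerate(specs):
                rows.append(
                    dict(
                        talker=talker,
                        phoneme=phoneme,
                        token=i,
                        klass=s.klass,
                        voiced=s.voiced,
                        f0_hz=s.f0_hz,
                        duration_s=s.duration_s,
                    )
                )
        return pd.DataFrame(rows)


def _token_spec(
    phoneme: str, talker: str, rng: np.random.Generator
) -> TokenSpec:
    info = PHONEME_TABLE[phoneme]
    klass = info["klass"]
    voiced = info["voiced"]
    base_dur = (
        _DIPHTHONG_DURATION_S if phoneme in _DIPHTHONGS else _BASE_DURATION_S[klass]
    )
    duration = base_dur * (1 + rng.uniform(-DURATION_JITTER_FRAC, DURATION_JITTER_FRAC))
    f0 = None
    if voiced:
        mean, sd = TALKER_F0_HZ[talker]
        f0 = float(np.clip(rng.normal(mean, sd), 85.0, 295.0))
        f0 *= 1 + rng.uniform(-F0_JITTER_FRAC, F0_JITTER_FRAC)
        f0 = float(np.clip(f0, 85.0, 295.0))
    scale = 1.15 if talker == "female" else 1.0
    formants = info.get("formants")
    formants_end = info.get("formants_end")
    return TokenSpec(
        phoneme=phoneme,
        klass=klass,
        voiced=voiced,
        duration_s=duration,
        talker_id=talker,
        f0_hz=f0,
        formants_hz=tuple(scale * f for f in formants) if formants else None,
        formants_end_hz=(
            tuple(scale * f for f in formants_end) if formants_end else None
        ),
        noise_peak_hz=info.get("noise_peak"),
        noise_bw_hz=info.get("noise_bw"),
    )


def generate_corpus(
    seed: int = 0,
    n_tokens: int = 4,
    rate_hz: float = 16000.0,
    phonemes: list[str] | None = None,
) -> Corpus:
    """Deterministically synthesize the full two-talker corpus.

    ``phonemes`` restricts the inventory (pairs whose members are missing
    are dropped), which keeps scaled-down simulations cheap.
    """
    rng = np.random.default_rng(seed)
    inventory = phonemes if phonemes is not None else sorted(PHONEME_TABLE)
    tokens: dict = {}
    specs: dict = {}
    for talker in ("male", "female"):
        for phoneme in inventory:
            toks, tok_specs = [], []
            for _ in range(n_tokens):
                s = _token_spec(phoneme, talker, rng)
                toks.append(synthesize_token(s, rate_hz, rng))
                tok_specs.append(s)
            tokens[(talker, phoneme)] = toks
            specs[(talker, phoneme)] = tok_specs
    have = set(inventory)
    pairs = [
        PairSpec(a, b, contrast)
        for a, b, contrast in PAIRS
        if a in have and b in have
    ]
    return Corpus(tokens=tokens, specs=specs, pairs=pairs, seed=seed)


# ---------------------------------------------------------------------------
# simulated listener
# ---------------------------------------------------------------------------

_N_SHAPE_BINS = 12
_CHANNEL_HALF_BW_HZ = 10.0


def stimulus_features(stim) -> np.ndarray:
    """Level-normalized feature vector of one tactile stimulus.

    Per-carrier narrow-band log energies with their mean removed (so the
    level rove is uninformative) concatenated with a unit-norm coarse
    temporal envelope shape.
    """
    x = stim.signal.samples
    rate = stim.signal.rate_hz
    carriers = stim.metadata["carrier_freqs_hz"]
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate)
    energies = np.array(
        [
            np.sum(np.square(spec[(freqs >= f - _CHANNEL_HALF_BW_HZ) & (freqs <= f + _CHANNEL_HALF_BW_HZ)]))
            for f in carriers
        ]
    )
    loge = np.log10(energies + 1e-12 * max(energies.sum(), 1e-300))
    profile = loge - loge.mean()
    edges = np.linspace(0, x.size, _N_SHAPE_BINS + 1).astype(int)
    shape = np.array([np.mean(np.abs(x[a:b])) if b > a else 0.0 for a, b in zip(edges, edges[1:])])
    norm = np.linalg.norm(shape)
    if norm > 0:
        shape = shape / norm
    return np.concatenate([profile, shape])


def _respond_from_features(
    feats: list[np.ndarray],
    internal_noise_sd: float,
    rng: np.random.Generator,
) -> int:
    """Pick the interval whose (noisy) features are farthest from the others."""
    size = max(f.size for f in feats)
    noisy = [
        np.pad(f, (0, size - f.size)) + rng.normal(0.0, internal_noise_sd, size)
        for f in feats
    ]
    scores = np.array(
        [
            sum(np.linalg.norm(noisy[i] - noisy[j]) for j in range(3) if j != i)
            for i in range(3)
        ]
    )
    best = np.flatnonzero(scores == scores.max())
    return int(rng.choice(best))


def simulated_listener(
    trial: TrialRecord,
    internal_noise_sd: float = DEFAULT_INTERNAL_NOISE_SD,
    rng: np.random.Generator | None = None,
) -> int:
    """Respond to a 3AFC trial; ties are broken uniformly at random."""
    rng = rng if rng is not None else np.random.default_rng()
    if any(s is None for s in trial.interval_stimuli):
        raise ValueError("trial has a missing interval")
    feats = [stimulus_features(s) for s in trial.interval_stimuli]
    return _respond_from_features(feats, internal_noise_sd, rng)
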