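"""Stimulus preparation and 3AFC trial assembly.

Within a phoneme pair the two members are faded out with a 20-ms
raised-cosine ramp whose zero point sits at the effective end of the
shorter token (the last sample above 1% of the absolute peak), so duration
cannot be used as a discrimination cue.  Pairs containing a diphthong or
one of /g d l r v w j/ are exempt: those phonemes cannot be produced in
isolation without altering them.

Trials are three-interval, three-alternative forced choice with a 250 ms
inter-stimulus interval: one interval holds the odd phoneme, the other two
hold the same token of the other phoneme, each interval independently
level-roved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioSignal, Unit
from .levels import LevelSpec, rove_level
from .synthesis import Condition, TactileStimulus

__all__ = [
    "EXEMPT_CONSONANTS",
    "TrialRecord",
    "effective_end",
    "match_durations",
    "make_pink_noise",
    "assemble_trial",
]

EXEMPT_CONSONANTS = frozenset({"g", "d", "l", "r", "v", "w", "j"})
ISI_MS = 250.0
RAMP_MS = 20.0
EFFECTIVE_END_FRACTION = 0.01


def effective_end(x, threshold_frac: float = EFFECTIVE_END_FRACTION) -> int:
    """Index of the last sample with |x| >= threshold_frac * max|x|."""
    if isinstance(x, AudioSignal):
        x = x.samples
    x = np.asarray(x, dtype=np.float64)
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak == 0:
        raise ValueError("silent signal has no effective end")
    above = np.nonzero(np.abs(x) >= threshold_frac * peak)[0]
    return int(above[-1])


def _raised_cosine_fade(n: int, rate_hz: float, end: int, ramp_ms: float) -> np.ndarray:
    """Unit gain up to the ramp, half-Hann fade reaching zero at ``end``."""
    ramp_len = int(np.ceil(ramp_ms / 1000.0 * rate_hz))
    gains = np.ones(n)
    start = max(end - ramp_len + 1, 0)
    j = np.arange(end - start + 1)
    denom = max(end - start, 1)
    gains[start : end + 1] = 0.5 * (1.0 + np.cos(np.pi * j / denom))
    gains[end + 1 :] = 0.0
    return gains


def match_durations(
    a: AudioSignal,
    b: AudioSignal,
    ramp_ms: float = RAMP_MS,
    exempt: bool = False,
) -> tuple[AudioSignal, AudioSignal]:
    """Fade both members of a pair out at the shorter one's effective end.

    Exempt pairs are returned unchanged.
    """
    if exempt:
        return a, b
    if a.rate_hz != b.rate_hz:
        raise ValueError("pair members must share a sample rate")
    end = min(effective_end(a), effective_end(b))

    def _fade(sig: AudioSignal) -> AudioSignal:
        gains = _raised_cosine_fade(sig.n_samples, sig.rate_hz, end, ramp_ms)
        return AudioSignal(sig.samples * gains, sig.rate_hz, sig.unit)

    return _fade(a), _fade(b)


def make_pink_noise(
    duration_s: float, rate_hz: float, rng: np.random.Generator
) -> AudioSignal:
    """Unit-RMS pink (1/f power) noise, synthesized in the frequency domain."""
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    n = int(round(duration_s * rate_hz))
    if n == 0:
        return AudioSignal(np.zeros(0), rate_hz, Unit.DIGITAL)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    x /= np.sqrt(np.mean(np.square(x)))
    return AudioSignal(x, rate_hz, Unit.DIGITAL)


@dataclass
class TrialRecord:
    """One 3AFC odd-one-out trial."""

    pair_id: str
    talker_id: str
    condition: Condition | None
    interval_stimuli: list  # 3 TactileStimulus
    odd_interval: int  # 0..2
    odd_is_b: bool  # whether the odd phoneme is pair member b
    rove_offsets_db: tuple
    isi_ms: float = ISI_MS
    response: int | None = None
    correct: bool | None = None

    def __post_init__(self) -> None:
        if len(self.interval_stimuli) != 3:
            raise ValueError("a 3AFC trial needs exactly 3 intervals")
        if self.odd_interval not in (0, 1, 2):
            raise ValueError("odd_interval must be 0, 1 or 2")

    def respond(self, response: int) -> bool:
        self.response = int(response)
        self.correct = self.response == self.odd_interval
        return self.correct


def _roved_copy(
    stim: TactileStimulus, spec: LevelSpec, rng: np.random.Generator
) -> tuple[TactileStimulus, float]:
    roved, offset = rove_level(stim.signal, spec, rng)
    return (
        TactileStimulus(
            signal=roved,
            condition=stim.condition,
            applied_rove_db=offset,
            metadata={**stim.metadata, "applied_rove_db": offset},
        ),
        offset,
    )


def assemble_trial(
    stim_a: TactileStimulus,
    stim_b: TactileStimulus,
    rng: np.random.Generator,
    level_spec: LevelSpec | None = None,
    pair_id: str = "",
    talker_id: str = "",
) -> TrialRecord:
    """Assemble a 3AFC trial from the pair's two nominal-level stimuli.

    Which member is the odd one and its interval position are both uniform;
    the two same-phoneme intervals reuse one token but are roved
    independently.
    """
    level_spec = level_spec or LevelSpec()
    odd_is_b = bool(rng.integers(2))
    odd_pos = int(rng.integers(3))
    odd, same = (stim_b, stim_a) if odd_is_b else (stim_a, stim_b)
    intervals: list[TactileStimulus | None] = [None, None, None]
    offsets = [0.0, 0.0, 0.0]
    for pos in range(3):
        src = odd if pos == odd_pos else same
        intervals[pos], offsets[pos] = _roved_copy(src, level_spec, rng)
    return TrialRecord(
        pair_id=pair_id,
        talker_id=talker_id,
        condition=stim_a.condition,
        interval_stimuli=intervals,
        odd_interval=odd_pos,
        odd_is_b=odd_is_b,
        rove_offsets_db=tuple(offsets),
    )
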