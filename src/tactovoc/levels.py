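"""Signal levels: active-speech-level normalization, acceleration scaling, roving.

Speech tokens are first equalized by their *active* speech level (ITU-T
P.56 method B), which measures level only over speech-active samples found
by exponential envelope tracking and threshold counting with a hangover.
Tactile output is then scaled to a nominal RMS acceleration of 141.5 dB re
1 µm/s² (≈11.89 m/s², 1.2 G) and roved by ±3 dB (uniform in dB) so absolute
intensity carries no information in the discrimination task.

Digital levels here are dB re full scale 1.0 (RMS); acceleration levels are
dB re 1e-6 m/s².
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .audio_io import AudioSignal, Unit

__all__ = [
    "LevelSpec",
    "AslResult",
    "active_speech_level",
    "normalize_asl",
    "accel_db_to_ms2",
    "ms2_to_g",
    "scale_to_rms_level",
    "rove_level",
]

ACCEL_REF_MS2 = 1e-6
STANDARD_GRAVITY_MS2 = 9.80665
NOMINAL_LEVEL_DB = 141.5
ROVE_HALF_RANGE_DB = 3.0
ASL_TARGET_DBFS = -26.0  # conventional active-level normalization target

# ITU-T P.56 method B constants
P56_SMOOTHING_S = 0.03  # envelope exponential-smoothing time constant
P56_HANGOVER_S = 0.2  # activity hangover
P56_MARGIN_DB = 15.9  # active-level-to-threshold margin
_N_THRESHOLDS = 31  # binary-divided thresholds below the peak


@dataclass(frozen=True)
class LevelSpec:
    """Nominal tactile level and rove range."""

    nominal_db: float = NOMINAL_LEVEL_DB
    rove_db: float = ROVE_HALF_RANGE_DB
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rove_db < 0:
            raise ValueError("rove_db must be non-negative")


@dataclass(frozen=True)
class AslResult:
    asl_db: float  # active speech level, dB re full scale (RMS)
    activity_factor: float  # fraction of samples counted active, in (0, 1]
    rms_db: float  # long-term RMS level of the whole signal


def _db(x: float) -> float:
    return 10.0 * np.log10(x)


def active_speech_level(x, rate_hz: float) -> AslResult:
    """ITU-T P.56 method B active speech level.

    The rectified signal is double-exponentially smoothed (time constant
    30 ms); for each of a series of binary-divided thresholds the samples
    whose envelope exceeds the threshold (plus a 200 ms hangover) are
    counted, giving a candidate active level.  The reported level is the
    one at which the margin between active level and threshold crosses
    15.9 dB, linearly interpolated between neighbouring thresholds.
    """
    if isinstance(x, AudioSignal):
        x, rate_hz = x.samples, x.rate_hz
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty signal")
    a = np.abs(x)
    peak = a.max()
    if peak == 0:
        raise ValueError("all-zero signal has no speech activity")

    g = np.exp(-1.0 / (rate_hz * P56_SMOOTHING_S))
    p = lfilter([1.0 - g], [1.0, -g], a)
    q = lfilter([1.0 - g], [1.0, -g], p)

    n = x.size
    sq = float(np.sum(np.square(x)))
    long_term_db = _db(sq / n)
    hang = int(round(P56_HANGOVER_S * rate_hz))
    idx = np.arange(n)

    thresholds = peak * np.power(2.0, -np.arange(1, _N_THRESHOLDS + 1, dtype=float))
    prev = None  # (delta, active_db, activity)
    for c in thresholds:
        active = q >= c
        last = np.maximum.accumulate(np.where(active, idx, -1))
        counted = int(np.count_nonzero((last >= 0) & (idx - last <= hang)))
        if counted == 0:
            continue
        active_db = _db(sq / counted)
        delta = active_db - 20.0 * np.log10(c)
        cur = (delta, active_db, counted / n)
        if delta >= P56_MARGIN_DB:
            if prev is None or delta == P56_MARGIN_DB:
                return AslResult(active_db, counted / n, long_term_db)
            # interpolate in dB between the bracketing thresholds
            frac = (P56_MARGIN_DB - prev[0]) / (delta - prev[0])
            asl = prev[1] + frac * (active_db - prev[1])
            act = prev[2] + frac * (cur[2] - prev[2])
            return AslResult(asl, act, long_term_db)
        prev = cur
    # margin never reached (nearly stationary, low-crest signal): report the
    # level over everything counted at the lowest threshold
    if prev is None:
        raise ValueError("no speech activity detected")
    return AslResult(prev[1], prev[2], long_term_db)


def normalize_asl(sig: AudioSignal, target_db_fs: float = ASL_TARGET_DBFS) -> AudioSignal:
    """Scale so the active speech level equals ``target_db_fs`` (dB re FS)."""
    asl = active_speech_level(sig.samples, sig.rate_hz)
    gain = 10.0 ** ((target_db_fs - asl.asl_db) / 20.0)
    return sig.scaled(gain)


def accel_db_to_ms2(db: float) -> float:
    """Acceleration level in dB re 1e-6 m/s² to m/s² RMS."""
    return ACCEL_REF_MS2 * 10.0 ** (db / 20.0)


def ms2_to_g(a: float) -> float:
    """m/s² to G (standard gravity, 9.80665 m/s²)."""
    return a / STANDARD_GRAVITY_MS2


def scale_to_rms_level(sig: AudioSignal, level_db: float = NOMINAL_LEVEL_DB) -> AudioSignal:
    """Scale to an RMS acceleration of ``level_db`` dB re 1e-6 m/s²."""
    rms = sig.rms()
    if rms == 0:
        raise ValueError("cannot scale an all-zero signal")
    target = accel_db_to_ms2(level_db)
    return AudioSignal(
        samples=sig.samples * (target / rms),
        rate_hz=sig.rate_hz,
        unit=Unit.ACCELERATION_MS2,
    )


def rove_level(
    sig: AudioSignal, spec: LevelSpec, rng: np.random.Generator
) -> tuple[AudioSignal, float]:
    """Apply a uniform dB-axis level rove; returns (signal, offset_db)."""
    if spec.rove_db == 0:
        return sig, 0.0
    offset = float(rng.uniform(-spec.rove_db, spec.rove_db))
    return sig.scaled(10.0 ** (offset / 20.0)), offset
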