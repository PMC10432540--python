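"""Mono audio I/O and resampling with explicit physical units.

Signals are carried as :class:`AudioSignal`, a thin immutable wrapper around a
float64 sample array.  Digital audio is dimensionless in [-1, 1]; tactile
waveforms carry acceleration in m/s².  All processing downstream of file
reading happens at a fixed 16 kHz rate, the rate available on compact
real-time audio hardware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

PROCESSING_RATE_HZ = 16_000.0

__all__ = [
    "Unit",
    "AudioSignal",
    "PROCESSING_RATE_HZ",
    "read_wav",
    "write_wav",
    "resample",
]


class Unit(str, Enum):
    """Physical unit of the sample values."""

    DIGITAL = "digital"
    ACCELERATION_MS2 = "acceleration_ms2"


@dataclass(frozen=True)
class AudioSignal:
    """A mono sampled signal.

    Parameters
    ----------
    samples
        1-D float array.  Dimensionless for ``Unit.DIGITAL`` (nominally in
        [-1, 1]); m/s² for ``Unit.ACCELERATION_MS2``.
    rate_hz
        Sampling frequency in Hz, strictly positive.
    unit
        Physical unit of the samples.
    """

    samples: np.ndarray
    rate_hz: float
    unit: Unit = Unit.DIGITAL

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D (mono); got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if not (self.rate_hz > 0 and math.isfinite(self.rate_hz)):
            raise ValueError(f"rate_hz must be positive and finite; got {self.rate_hz}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def rms(self) -> float:
        if self.samples.size == 0:
            return 0.0
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def scaled(self, gain: float) -> "AudioSignal":
        """Return a copy with all samples multiplied by ``gain``."""
        return replace(self, samples=self.samples * float(gain))


_INT_FULL_SCALE = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
}


def read_wav(path: str | Path) -> AudioSignal:
    """Read a mono RIFF/WAV file.

    Integer PCM (8/16/24/32-bit) is scaled to [-1, 1]; float data is passed
    through unchanged.  Multi-channel files are rejected rather than silently
    mixed down, which would alter signal levels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        raise ValueError(
            f"{path.name}: expected mono audio, got {data.shape[1]} channels"
        )
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned with midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _INT_FULL_SCALE:
        samples = data.astype(np.float64) / _INT_FULL_SCALE[data.dtype]
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path.name}: unsupported WAV encoding {data.dtype}")
    return AudioSignal(samples=samples, rate_hz=float(rate), unit=Unit.DIGITAL)


def write_wav(path: str | Path, sig: AudioSignal) -> None:
    """Write ``sig`` as a 32-bit float WAV (lossless for our pipeline)."""
    wavfile.write(str(path), int(round(sig.rate_hz)), sig.samples.astype(np.float32))


def resample(sig: AudioSignal, target_hz: float) -> AudioSignal:
    """Resample to ``target_hz`` with polyphase anti-aliased filtering.

    The output length is ``ceil(n * target / rate)`` (the ``resample_poly``
    convention).  A same-rate input is returned unchanged.
    """
    if not target_hz > 0:
        raise ValueError(f"target_hz must be positive; got {target_hz}")
    if target_hz == sig.rate_hz:
        return sig
    if sig.n_samples == 0:
        return replace(sig, rate_hz=float(target_hz))
    ratio = Fraction(target_hz / sig.rate_hz).limit_denominator(1 << 20)
    # Kaiser beta = 10 keeps passband ripple (and hence round-trip error on
    # band-limited content) below -100 dB; the scipy default beta of 5 leaves
    # ~-56 dB ripple, audible as a broadband error floor
    out = resample_poly(
        sig.samples, ratio.numerator, ratio.denominator, window=("kaiser", 10.0)
    )
    return AudioSignal(samples=out, rate_hz=float(target_hz), unit=sig.unit)
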