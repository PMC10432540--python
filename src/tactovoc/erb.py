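"""ERB-number frequency scale and the equal-ERB FIR filterbank.

The vocoder splits the 50–7000 Hz speech range into 1, 4 or 8 bands whose
edges are equally spaced on the auditory equivalent-rectangular-bandwidth
(ERB) number scale of Glasberg & Moore,

    E(f) = 21.4 * log10(0.00437 * f + 1)    [E in Cams, f in Hz]

so that each band spans an equal share of the auditory filter count.  Under
this scale the lowest of four bands ends near 400 Hz — the region carrying
the voicing bar — and the lowest two of eight bands sit below it.

Bands are extracted with linear-phase windowed-sinc FIR band-pass filters of
order 512 (513 taps, Hamming window, band edges at the -6 dB points).  The
group delay of order/2 samples is removed so band signals stay time-aligned
with the input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import firwin, oaconvolve

from .audio_io import AudioSignal, PROCESSING_RATE_HZ

__all__ = [
    "hz_to_erb_number",
    "erb_number_to_hz",
    "FrequencyBand",
    "FilterBankSpec",
    "compute_band_edges",
    "design_bandpass_fir",
    "apply_filterbank",
]


def hz_to_erb_number(f):
    """Convert frequency in Hz to ERB number (Cams).  Monotone, E(0) = 0."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = 21.4 * np.log10(0.00437 * f + 1.0)
    return float(out) if out.ndim == 0 else out


def erb_number_to_hz(erb):
    """Inverse of :func:`hz_to_erb_number`."""
    erb = np.asarray(erb, dtype=np.float64)
    if np.any(erb < 0):
        raise ValueError("ERB number must be non-negative")
    out = (np.power(10.0, erb / 21.4) - 1.0) / 0.00437
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FrequencyBand:
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(f"invalid band [{self.low_hz}, {self.high_hz}] Hz")


@dataclass(frozen=True)
class FilterBankSpec:
    """Equal-ERB band edges plus the FIR design parameters."""

    n_bands: int
    edges_hz: tuple
    fir_order: int = 512
    rate_hz: float = PROCESSING_RATE_HZ

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges_hz)
        if len(edges) != self.n_bands + 1:
            raise ValueError("need n_bands + 1 edges")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("edges must be strictly increasing")
        if edges[-1] > self.rate_hz / 2:
            raise ValueError("top edge exceeds Nyquist")
        if self.fir_order % 2 != 0:
            raise ValueError("FIR order must be even (linear phase, integer delay)")
        object.__setattr__(self, "edges_hz", edges)

    @property
    def bands(self) -> list[FrequencyBand]:
        return [
            FrequencyBand(lo, hi) for lo, hi in zip(self.edges_hz, self.edges_hz[1:])
        ]

    def to_dict(self) -> dict:
        return {
            "n_bands": self.n_bands,
            "edges_hz": list(self.edges_hz),
            "fir_order": self.fir_order,
            "rate_hz": self.rate_hz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterBankSpec":
        return cls(
            n_bands=int(d["n_bands"]),
            edges_hz=tuple(d["edges_hz"]),
            fir_order=int(d.get("fir_order", 512)),
            rate_hz=float(d.get("rate_hz", PROCESSING_RATE_HZ)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FilterBankSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def compute_band_edges(
    n_bands: int,
    low_hz: float = 50.0,
    high_hz: float = 7000.0,
    fir_order: int = 512,
    rate_hz: float = PROCESSING_RATE_HZ,
) -> FilterBankSpec:
    """Divide [low_hz, high_hz] into ``n_bands`` equal-ERB bands."""
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if not low_hz < high_hz:
        raise ValueError("low_hz must be below high_hz")
    erb_edges = np.linspace(hz_to_erb_number(low_hz), hz_to_erb_number(high_hz), n_bands + 1)
    edges = erb_number_to_hz(erb_edges)
    edges[0], edges[-1] = low_hz, high_hz  # pin endpoints against round-trip error
    return FilterBankSpec(
        n_bands=n_bands, edges_hz=tuple(edges), fir_order=fir_order, rate_hz=rate_hz
    )


def design_bandpass_fir(
    band: FrequencyBand, order: int = 512, rate_hz: float = PROCESSING_RATE_HZ
) -> np.ndarray:
    """Windowed-sinc (Hamming) linear-phase band-pass; ``order + 1`` taps.

    Band edges are the -6 dB points of the design, the windowed-sinc
    convention.
    """
    if order % 2 != 0:
        raise ValueError("order must be even")
    if band.high_hz >= rate_hz / 2:
        raise ValueError(
            f"band edge {band.high_hz} Hz is at or above Nyquist ({rate_hz / 2} Hz)"
        )
    return firwin(
        order + 1,
        [band.low_hz, band.high_hz],
        pass_zero=False,
        window="hamming",
        fs=rate_hz,
    )


@lru_cache(maxsize=64)
def _taps_cached(low: float, high: float, order: int, rate: float) -> np.ndarray:
    return design_bandpass_fir(FrequencyBand(low, high), order, rate)


def apply_filterbank(sig: AudioSignal, spec: FilterBankSpec) -> list[np.ndarray]:
    """Split ``sig`` into band signals, each the length of the input.

    Filtering is FFT overlap-add; the order/2-sample group delay of the
    linear-phase filters is removed (zero padding at the tail) so band
    outputs are time-aligned with the input.
    """
    if sig.rate_hz != spec.rate_hz:
        raise ValueError(
            f"signal rate {sig.rate_hz} != filterbank rate {spec.rate_hz}"
        )
    n = sig.n_samples
    delay = spec.fir_order // 2
    out = []
    for band in spec.bands:
        taps = _taps_cached(band.low_hz, band.high_hz, spec.fir_order, spec.rate_hz)
        if n == 0:
            out.append(np.zeros(0))
            continue
        full = oaconvolve(sig.samples, taps, mode="full")
        out.append(full[delay : delay + n])
    return out
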