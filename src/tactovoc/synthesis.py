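"""Vibro-tactile carrier synthesis and the full vocode chain.

Band envelopes amplitude-modulate fixed sine carriers in the 94.5–327.5 Hz
range where compact haptic actuators are efficient and the skin is most
sensitive.  Per-tone gains equalize perceived intensity across carrier
frequency (referenced to the 170 Hz tone at 0 dB, the actuator sweet spot).
The study's five conditions pair a 1-, 4- or 8-band analysis with 1, 4 or 8
tones; with a single band the broadband envelope drives every tone, so the
tone complex carries no spectral information.

Chain: active-level normalization -> resample to 16 kHz -> equal-ERB FIR
filterbank -> Hilbert + 23 Hz zero-phase envelopes -> modulate carriers
(per-tone gains) -> scale to 141.5 dB re 1 µm/s² RMS -> ±3 dB rove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioSignal, PROCESSING_RATE_HZ, Unit, resample
from .envelopes import EnvelopeSet, extract_envelopes
from .erb import FilterBankSpec, apply_filterbank, compute_band_edges
from .levels import (
    LevelSpec,
    accel_db_to_ms2,
    normalize_asl,
    rove_level,
    scale_to_rms_level,
)

__all__ = [
    "CarrierSet",
    "Condition",
    "CONDITIONS",
    "TactileStimulus",
    "carrier_table",
    "envelope_to_band_mapping",
    "modulate_and_mix",
    "vocode",
]

# Published carrier tables: frequencies in Hz and matching per-tone gains in
# dB (reference tone at 0 dB).
_CARRIER_FREQS_HZ = {
    1: (170.0,),
    4: (138.0, 170.0, 210.0, 259.5),
    8: (94.5, 116.5, 141.5, 170.0, 202.5, 239.0, 280.5, 327.5),
}
_CARRIER_GAINS_DB = {
    1: (0.0,),
    4: (9.6, 5.8, 0.4, 0.0),
    8: (13.8, 12.1, 9.9, 6.4, 1.6, 0.0, 1.7, 4.0),
}


@dataclass(frozen=True)
class CarrierSet:
    """Fixed-phase tone complex: frequencies, per-tone gains, start phase."""

    freqs_hz: tuple
    gains_db: tuple
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if len(self.freqs_hz) != len(self.gains_db):
            raise ValueError("freqs and gains must have equal length")
        if any(b <= a for a, b in zip(self.freqs_hz, self.freqs_hz[1:])):
            raise ValueError("carrier frequencies must be strictly increasing")
        if not any(g == 0.0 for g in self.gains_db):
            raise ValueError("one gain must be 0 dB (the reference tone)")

    @property
    def n_tones(self) -> int:
        return len(self.freqs_hz)


def carrier_table(n_tones: int) -> CarrierSet:
    """The published carrier set for 1, 4 or 8 tones."""
    try:
        return CarrierSet(_CARRIER_FREQS_HZ[n_tones], _CARRIER_GAINS_DB[n_tones])
    except KeyError:
        raise ValueError(f"no carrier table for {n_tones} tones (use 1, 4 or 8)")


@dataclass(frozen=True)
class Condition:
    """A study condition: number of analysis bands and of carrier tones."""

    name: str
    n_bands: int
    n_tones: int

    def __post_init__(self) -> None:
        if self.n_bands not in (1, self.n_tones):
            raise ValueError(
                f"{self.name}: n_bands must be 1 or equal to n_tones"
            )


CONDITIONS: dict[str, Condition] = {
    c.name: c
    for c in (
        Condition("1FB1T", 1, 1),
        Condition("1FB4T", 1, 4),
        Condition("4FB4T", 4, 4),
        Condition("1FB8T", 1, 8),
        Condition("8FB8T", 8, 8),
    )
}


def envelope_to_band_mapping(n_bands: int, n_tones: int) -> tuple:
    """tone index -> band index.

    Matched counts map band k to tone k (ascending frequency to ascending
    frequency); a single band drives every tone.
    """
    if n_bands == n_tones:
        return tuple(range(n_tones))
    if n_bands == 1:
        return (0,) * n_tones
    raise ValueError(f"({n_bands} bands, {n_tones} tones) is not a study condition")


def modulate_and_mix(
    envs: EnvelopeSet, carriers: CarrierSet, mapping: tuple | None = None
) -> np.ndarray:
    """sum_k 10^(gain_k/20) * env_map(k)(t) * sin(2*pi*f_k*t + phase)."""
    if mapping is None:
        mapping = envelope_to_band_mapping(envs.n_bands, carriers.n_tones)
    if len(mapping) != carriers.n_tones:
        raise ValueError("mapping length must equal the number of tones")
    if max(mapping, default=-1) >= envs.n_bands:
        raise ValueError("mapping refers to a missing band")
    t = np.arange(envs.n_samples) / envs.rate_hz
    out = np.zeros(envs.n_samples)
    for k, (f, gain_db) in enumerate(zip(carriers.freqs_hz, carriers.gains_db)):
        amp = 10.0 ** (gain_db / 20.0)
        out += amp * envs.envelopes[mapping[k]] * np.sin(
            2.0 * np.pi * f * t + carriers.phase_rad
        )
    return out


@dataclass(frozen=True)
class TactileStimulus:
    """A vocoded stimulus in physical units plus its provenance."""

    signal: AudioSignal
    condition: Condition
    applied_rove_db: float
    metadata: dict = field(default_factory=dict)

    @property
    def rms_ms2(self) -> float:
        return self.signal.rms()


def vocode(
    audio: AudioSignal,
    condition: Condition | str,
    level_spec: LevelSpec | None = None,
    rng: np.random.Generator | None = None,
    apply_rove: bool = True,
    band_range_hz: tuple[float, float] = (50.0, 7000.0),
    fir_order: int = 512,
) -> TactileStimulus:
    """Convert audio to an amplitude-modulated vibro-tactile tone complex.

    Raises on silent input or an unknown condition.  With ``apply_rove``
    the level rove draws from ``rng`` (required unless rove_db == 0);
    without it the stimulus is left at the nominal level with offset 0,
    which is the form cached by the trial simulator.
    """
    if isinstance(condition, str):
        try:
            condition = CONDITIONS[condition]
        except KeyError:
            raise ValueError(
                f"unknown condition {condition!r}; expected one of {sorted(CONDITIONS)}"
            )
    level_spec = level_spec or LevelSpec()
    if audio.n_samples == 0 or audio.rms() == 0:
        raise ValueError("cannot vocode a silent signal")

    normalized = normalize_asl(audio)
    work = resample(normalized, PROCESSING_RATE_HZ)
    fb = compute_band_edges(
        condition.n_bands, *band_range_hz, fir_order=fir_order
    )
    bands = apply_filterbank(work, fb)
    envs = extract_envelopes(bands, rate_hz=PROCESSING_RATE_HZ)
    carriers = carrier_table(condition.n_tones)
    mapping = envelope_to_band_mapping(condition.n_bands, condition.n_tones)
    mixed = modulate_and_mix(envs, carriers, mapping)
    if not np.any(mixed):
        raise ValueError("vocoded signal is silent (no band energy)")
    nominal = scale_to_rms_level(
        AudioSignal(mixed, PROCESSING_RATE_HZ, Unit.ACCELERATION_MS2),
        level_spec.nominal_db,
    )
    offset = 0.0
    out = nominal
    if apply_rove and level_spec.rove_db > 0:
        if rng is None:
            raise ValueError("rove requested but no rng supplied")
        out, offset = rove_level(nominal, level_spec, rng)
    meta = {
        "condition": condition.name,
        "band_edges_hz": list(fb.edges_hz),
        "fir_order": fir_order,
        "carrier_freqs_hz": list(carriers.freqs_hz),
        "carrier_gains_db": list(carriers.gains_db),
        "nominal_db": level_spec.nominal_db,
        "rove_db_half_range": level_spec.rove_db,
        "applied_rove_db": offset,
        "nominal_rms_ms2": accel_db_to_ms2(level_spec.nominal_db),
        "rate_hz": PROCESSING_RATE_HZ,
    }
    return TactileStimulus(
        signal=out, condition=condition, applied_rove_db=offset, metadata=meta
    )
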