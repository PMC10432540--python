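"""Acoustic analyses: F0 tracking, long-term average spectrum, tactile spectrogram.

The fundamental-frequency tracker uses a frame-wise normalized correlation
function (NCF): each 30-ms Hamming-windowed frame is autocorrelated over
the 60–400 Hz lag range and F0 is read off the lag of the NCF maximum
(parabolically interpolated).  The NCF peak value doubles as a harmonic
ratio in [0, 1]; frames with HR > 0.75 count as voiced, and F0 summary
statistics are taken over voiced frames only.

The long-term average spectrum (LTAS) is a Hann-windowed Welch mean power
spectral density over all supplied tokens, Gaussian-smoothed on the
log-frequency axis at 1/3-octave resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hamming, hann

from .audio_io import AudioSignal
from .envelopes import EnvelopeSet
from .synthesis import CarrierSet, envelope_to_band_mapping

__all__ = [
    "F0Track",
    "F0Summary",
    "LtasResult",
    "TactileSpectrogram",
    "f0_ncf",
    "summarize_f0",
    "ltas",
    "tactile_spectrogram",
]

VOICED_HR_THRESHOLD = 0.75
PITCH_FMIN_HZ = 60.0
PITCH_FMAX_HZ = 400.0


@dataclass(frozen=True)
class F0Track:
    """Per-frame F0 and harmonic-ratio estimates."""

    frame_times_s: np.ndarray
    f0_hz: np.ndarray
    harmonic_ratio: np.ndarray
    hr_threshold: float = VOICED_HR_THRESHOLD

    @property
    def voiced_mask(self) -> np.ndarray:
        return self.harmonic_ratio > self.hr_threshold


@dataclass(frozen=True)
class F0Summary:
    mean_hz: float
    sd_hz: float
    min_hz: float
    max_hz: float
    n_voiced: int


@dataclass(frozen=True)
class LtasResult:
    freqs_hz: np.ndarray
    level_db: np.ndarray  # smoothed mean PSD, dB (relative)


@dataclass(frozen=True)
class TactileSpectrogram:
    """Channel envelopes laid out at their carrier frequencies, in dB re max."""

    times_s: np.ndarray
    freqs_hz: np.ndarray
    level_db: np.ndarray  # shape (n_tones, n_samples)


def f0_ncf(
    sig: AudioSignal,
    win_ms: float = 30.0,
    overlap_ms: float = 25.0,
    fmin_hz: float = PITCH_FMIN_HZ,
    fmax_hz: float = PITCH_FMAX_HZ,
) -> F0Track:
    """Normalized-correlation-function pitch track.

    A 30-ms Hamming window with 25-ms overlap gives a 5-ms hop.  For each
    frame, NCF(k) = sum(y[n] y[n+k]) / sqrt(sum(y[:N-k]^2) sum(y[k:]^2));
    F0 = rate / argmax over the pitch lag range, HR = the maximum itself.
    """
    rate = sig.rate_hz
    if rate < 8000:
        raise ValueError("F0 analysis expects a rate of at least 8 kHz")
    win = int(round(win_ms / 1000.0 * rate))
    hop = win - int(round(overlap_ms / 1000.0 * rate))
    if hop <= 0:
        raise ValueError("overlap must be shorter than the window")
    x = sig.samples
    if x.size < win:
        raise ValueError("signal shorter than one analysis window")

    lag_min = max(int(np.floor(rate / fmax_hz)), 1)
    lag_max = min(int(np.ceil(rate / fmin_hz)), win - 1)
    n_frames = 1 + (x.size - win) // hop
    starts = np.arange(n_frames) * hop
    window = hamming(win, sym=False)
    frames = np.lib.stride_tricks.sliding_window_view(x, win)[starts]
    frames = frames * window

    # all-lag autocorrelation via FFT, per frame
    nfft = int(2 ** np.ceil(np.log2(2 * win)))
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    acorr = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=1)[:, : win]

    # energy terms e1[k] = sum(y[:N-k]^2), e2[k] = sum(y[k:]^2)
    sq = np.square(frames)
    csum = np.cumsum(sq, axis=1)
    total = csum[:, -1:]
    lags = np.arange(lag_min, lag_max + 1)
    e1 = csum[:, win - 1 - lags]
    e2 = total - np.where(lags[None, :] > 0, csum[:, lags - 1], 0.0)
    denom = np.sqrt(e1 * e2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncf = np.where(denom > 0, acorr[:, lags] / denom, 0.0)

    # The raw (tapered) NCF picks the pitch lag: the window taper penalizes
    # longer lags, which conveniently discourages subharmonic (octave-down)
    # choices.  The harmonic ratio, however, is read from the taper-
    # compensated NCF — dividing by the window's own NCF (the value a
    # perfectly periodic input would reach) — so that low-F0 frames are not
    # pushed below the voicing threshold by the taper alone.
    wsq = np.square(window)
    wc = np.correlate(window, window, mode="full")[win - 1 + lag_min : win - 1 + lag_max + 1]
    wcs = np.cumsum(wsq)
    we1 = wcs[win - 1 - lags]
    we2 = wcs[-1] - wcs[lags - 1]
    window_ncf = wc / np.sqrt(we1 * we2)

    best = np.argmax(ncf, axis=1)
    hr = np.clip(ncf[np.arange(n_frames), best] / window_ncf[best], 0.0, 1.0)

    # parabolic interpolation of the NCF peak for sub-sample lag
    lag_hat = lags[best].astype(np.float64)
    interior = (best > 0) & (best < lags.size - 1)
    i = np.nonzero(interior)[0]
    if i.size:
        y0 = ncf[i, best[i] - 1]
        y1 = ncf[i, best[i]]
        y2 = ncf[i, best[i] + 1]
        denom_p = y0 - 2.0 * y1 + y2
        ok = np.abs(denom_p) > 1e-12
        shift = np.zeros_like(y1)
        shift[ok] = 0.5 * (y0[ok] - y2[ok]) / denom_p[ok]
        lag_hat[i] += np.clip(shift, -1.0, 1.0)

    f0 = rate / lag_hat
    silent = total[:, 0] <= 0
    hr = np.where(silent, 0.0, hr)
    f0 = np.where(silent, 0.0, f0)
    times = (starts + win / 2.0) / rate
    return F0Track(frame_times_s=times, f0_hz=f0, harmonic_ratio=hr)


def summarize_f0(track: F0Track) -> F0Summary:
    """Mean/SD/min/max F0 over voiced frames (HR above threshold)."""
    voiced = track.f0_hz[track.voiced_mask]
    if voiced.size == 0:
        raise ValueError("no voiced frames (harmonic ratio never exceeded threshold)")
    return F0Summary(
        mean_hz=float(np.mean(voiced)),
        sd_hz=float(np.std(voiced, ddof=1)) if voiced.size > 1 else 0.0,
        min_hz=float(np.min(voiced)),
        max_hz=float(np.max(voiced)),
        n_voiced=int(voiced.size),
    )


def _gaussian_smooth_log_freq(
    freqs: np.ndarray, psd: np.ndarray, resolution_octaves: float
) -> np.ndarray:
    """Smooth a PSD with a Gaussian on the log2-frequency axis.

    ``resolution_octaves`` is the FWHM of the kernel; sigma = FWHM / 2.355.
    """
    sigma = resolution_octaves / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    logf = np.log2(freqs)
    d = (logf[:, None] - logf[None, :]) / sigma
    w = np.exp(-0.5 * d * d)
    w /= w.sum(axis=1, keepdims=True)
    return w @ psd


def ltas(
    signals,
    rate_hz: float,
    nfft: int = 4096,
    hop: int = 2048,
    resolution_octaves: float = 1.0 / 3.0,
) -> LtasResult:
    """Long-term average spectrum over one or more tokens.

    Hann-windowed mean PSD over every full frame of every token (Welch
    without overlap correction beyond the hop), then 1/3-octave Gaussian
    smoothing on log frequency.  Levels are relative dB: no normalization
    is applied, so scaling the input by g shifts the result by 20 log10 g.
    """
    window = hann(nfft, sym=False)
    win_power = np.sum(np.square(window))
    acc = np.zeros(nfft // 2 + 1)
    n_frames = 0
    for sig in signals:
        x = sig.samples if isinstance(sig, AudioSignal) else np.asarray(sig, float)
        for start in range(0, x.size - nfft + 1, hop):
            seg = x[start : start + nfft] * window
            acc += np.square(np.abs(np.fft.rfft(seg)))
            n_frames += 1
    if n_frames < 10:
        raise ValueError("too little material for an LTAS (need >= 10 frames)")
    psd = acc / (n_frames * win_power * rate_hz)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate_hz)
    smoothed = _gaussian_smooth_log_freq(freqs[1:], psd[1:], resolution_octaves)
    return LtasResult(
        freqs_hz=freqs[1:], level_db=10.0 * np.log10(np.maximum(smoothed, 1e-300))
    )


def tactile_spectrogram(
    envs: EnvelopeSet, carriers: CarrierSet, floor_db: float = -80.0
) -> TactileSpectrogram:
    """Envelope-per-carrier image, dB re the maximum envelope amplitude.

    No windowing: the rows are the raw envelopes at the full envelope rate.
    A single-band envelope set is broadcast to every carrier, mirroring the
    one-band conditions.
    """
    if envs.n_samples == 0:
        raise ValueError("empty envelope set")
    mapping = envelope_to_band_mapping(envs.n_bands, carriers.n_tones)
    rows = envs.envelopes[list(mapping), :]
    peak = rows.max()
    if peak == 0:
        level = np.full(rows.shape, floor_db)
    else:
        with np.errstate(divide="ignore"):
            level = 20.0 * np.log10(rows / peak)
        level = np.maximum(level, floor_db)
    times = np.arange(envs.n_samples) / envs.rate_hz
    return TactileSpectrogram(
        times_s=times, freqs_hz=np.asarray(carriers.freqs_hz), level_db=level
    )
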