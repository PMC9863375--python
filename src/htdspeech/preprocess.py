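"""Waveform conditioning before time-frequency analysis.

Mirrors the corpus preparation applied to the isolated-word recordings:
stereo mixdown, optional resampling, removal of leading/trailing silence,
and exclusion of noisy takes. The silence and noise criteria here are
automatic stand-ins (frame-RMS endpointing, a spectral noise-floor SNR
estimate) for what was originally a manual screening step.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import resample_poly, welch

from .signal_io import PreprocessParams, Waveform

__all__ = ["to_mono", "resample", "trim_silence", "exclude_noisy", "AllSilentError"]


class AllSilentError(ValueError):
    """Raised when an utterance contains no frame above the silence threshold."""


def to_mono(w: Waveform) -> Waveform:
    """Average the channels of a stereo waveform; mono passes through unchanged."""
    if w.channels == 1:
        return w if w.samples.ndim == 1 else Waveform(w.samples[:, 0], w.rate)
    return Waveform(w.samples.mean(axis=1), w.rate)


def resample(w: Waveform, target_rate: int) -> Waveform:
    """Polyphase resampling to ``target_rate`` (identity if rates match)."""
    if target_rate == w.rate:
        return w
    from math import gcd

    g = gcd(target_rate, w.rate)
    out = resample_poly(w.samples, target_rate // g, w.rate // g, axis=0)
    return Waveform(out, target_rate)


def _frame_rms(x: np.ndarray, frame_len: int) -> np.ndarray:
    n_frames = max(1, int(np.ceil(len(x) / frame_len)))
    padded = np.zeros(n_frames * frame_len)
    padded[: len(x)] = x
    frames = padded.reshape(n_frames, frame_len)
    return np.sqrt((frames**2).mean(axis=1))


def trim_silence(w: Waveform, p: PreprocessParams | None = None) -> Waveform:
    """Drop leading and trailing frames whose RMS sits below the threshold.

    The threshold is ``silence_threshold_db`` relative to the loudest frame's
    RMS; interior frames are never touched, so trimming is idempotent.
    Raises :class:`AllSilentError` when every frame is sub-threshold (the
    all-silent case is treated as a non-quantifiable sample and excluded).
    """
    p = p or PreprocessParams()
    if w.channels != 1:
        raise ValueError("trim_silence expects a mono waveform")
    frame_len = max(1, int(round(p.frame_ms * 1e-3 * w.rate)))
    rms = _frame_rms(w.samples, frame_len)
    peak = rms.max()
    if peak <= 0:
        raise AllSilentError("utterance is digital silence")
    thresh = peak * 10.0 ** (p.silence_threshold_db / 20.0)
    active = np.flatnonzero(rms >= thresh)
    if active.size == 0:
        raise AllSilentError("no frame above silence threshold")
    start = active[0] * frame_len
    stop = min(len(w.samples), (active[-1] + 1) * frame_len)
    return Waveform(w.samples[start:stop], w.rate)


def exclude_noisy(w: Waveform, p: PreprocessParams | None = None) -> tuple[bool, float]:
    """Keep/discard decision with an estimated SNR in dB.

    The noise floor is taken from the spectrum: broadband noise lifts the
    median of the power spectral density, while speech (or any tonal signal)
    concentrates its power in a minority of bins. Noise power is the median
    density integrated over the band, signal power the remainder, and the
    utterance is kept iff their ratio is at least ``snr_floor_db``.
    Returns ``(keep, snr_db)``.
    """
    p = p or PreprocessParams()
    if w.channels != 1:
        raise ValueError("exclude_noisy expects a mono waveform")
    if np.isneginf(p.snr_floor_db):
        return True, float("inf")
    total = float(np.mean(w.samples**2))
    if total <= 0 or w.n_samples < 16:
        return False, float("-inf")
    nperseg = min(w.n_samples, max(64, int(round(p.frame_ms * 1e-3 * w.rate)) * 4))
    freqs, psd = welch(w.samples, fs=w.rate, nperseg=nperseg)
    noise_power = float(np.median(psd)) * (freqs[-1] - freqs[0])
    signal_power = max(total - noise_power, 0.0)
    if noise_power <= 0:
        return True, float("inf")
    snr_db = 10.0 * np.log10(signal_power / noise_power) if signal_power > 0 else float("-inf")
    return bool(snr_db >= p.snr_floor_db), float(snr_db)
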