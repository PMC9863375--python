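"""Hyperbolic T-distribution (HTD) time-frequency engine.

The HTD is a Cohen-class quadratic time-frequency distribution obtained by
smoothing the Wigner-Ville distribution (WVD) in time only:

    rho(t, f) = F_{tau->f} [ G(t, tau) *_t K_z(t, tau) ]

where K_z(t, tau) = z(t + tau/2) z*(t - tau/2) is the instantaneous
autocorrelation product of the analytic signal z(t), *_t is convolution in
time, and the time-lag kernel is lag-independent:

    G(t, tau) = R_sigma(t) = k_sigma / cosh^(2 sigma)(t),
    k_sigma   = Gamma(2 sigma) / (2^(2 sigma - 1) Gamma(sigma)^2).

k_sigma makes the kernel a unit-mass time smoother (integral of
cosh^(-2 sigma) over the line equals 1/k_sigma), so the WVD's frequency
marginal is preserved up to edge effects while the oscillatory cross-terms —
which alternate sign along time — are attenuated. Larger sigma narrows the
kernel; sigma -> infinity recovers the (lag-windowed) WVD.

Discrete conventions: half-lags are realized on the integer grid as
K[n, m] = z[n+m] conj(z[n-m]), i.e. lag tau = 2m/rate, so an FFT of length
nfft over m yields frequency bins f_k = k * rate / (2 nfft) covering
[0, rate/2). Values are scaled by the lag step 2/rate so that the sum of
rho over time and frequency bins times (hop/rate) * (rate/(2 nfft))
approximates the analytic-signal energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image
from scipy.signal import fftconvolve, get_window, hilbert
from scipy.special import gammaln

from .signal_io import RunConfig, Waveform

__all__ = [
    "AnalyticSignal",
    "HTDKernel",
    "TFDGrid",
    "TFImage",
    "analytic_signal",
    "kernel_norm",
    "kernel_weights",
    "inst_autocorrelation",
    "compute_htd",
    "wvd_reference",
    "render_tf_image",
]


@dataclass(frozen=True)
class AnalyticSignal:
    """Complex signal with no negative-frequency content; real part = source."""

    values: np.ndarray
    rate: int

    @property
    def energy(self) -> float:
        """Integral of |z|^2 dt (discrete sum / rate), in amplitude^2 * s."""
        return float(np.sum(np.abs(self.values) ** 2) / self.rate)


@dataclass(frozen=True)
class HTDKernel:
    """Sampled unit-mass smoothing kernel R_sigma on a uniform time grid."""

    sigma: float
    k_sigma: float
    truncation_eps: float
    times: np.ndarray  # seconds, symmetric about 0
    weights: np.ndarray  # discrete weights, sum(weights) * dt == 1


@dataclass(frozen=True)
class TFDGrid:
    """Real-valued time x frequency energy surface.

    values[i, k]: frame i (center times[i] seconds), frequency bin freqs[k]
    Hz, bins covering [0, rate/2) half-open.
    """

    values: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    rate: int
    hop: int
    lag_window: int
    nfft: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TFD grid contains non-finite entries")


@dataclass(frozen=True)
class TFImage:
    """Fixed-size 3-channel rendering of a TFD grid (uint8, H = W)."""

    pixels: np.ndarray
    colormap: str
    floor_db: float


def analytic_signal(w: Waveform) -> AnalyticSignal:
    """Analytic signal via the frequency-domain construction: positive
    frequencies doubled, negative zeroed, DC and Nyquist kept."""
    if w.channels != 1:
        raise ValueError("analytic_signal expects a mono waveform")
    x = np.asarray(w.samples, dtype=np.float64)
    if x.size < 2:
        raise ValueError("signal too short for analytic continuation")
    return AnalyticSignal(values=hilbert(x), rate=w.rate)


def kernel_norm(sigma: float) -> float:
    """Closed-form normalization k_sigma = Gamma(2s) / (2^(2s-1) Gamma(s)^2).

    This is the reciprocal of integral cosh^(-2 sigma)(t) dt, so that
    R_sigma(t) = k_sigma / cosh^(2 sigma)(t) has unit mass. Uses log-gamma
    for numerical range.
    """
    if sigma <= 0:
        raise ValueError("sigma must be a positive real number")
    log_k = gammaln(2.0 * sigma) - (2.0 * sigma - 1.0) * np.log(2.0) - 2.0 * gammaln(sigma)
    return float(np.exp(log_k))


def kernel_weights(sigma: float, time_grid: np.ndarray, truncation_eps: float = 1e-4) -> HTDKernel:
    """Sample R_sigma on a uniform, zero-centered grid; truncate and renormalize.

    ``time_grid`` is in kernel (dimensionless) units. Weights below
    ``truncation_eps`` times the peak are dropped; the surviving support is
    renormalized to unit discrete mass (sum * dt = 1).
    """
    t = np.asarray(time_grid, dtype=np.float64)
    if t.size < 3:
        raise ValueError("kernel grid too coarse: need >= 3 points")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0]):
        raise ValueError("kernel grid must be uniform")
    if abs(t[t.size // 2]) > 1e-12 or t.size % 2 == 0:
        raise ValueError("kernel grid must be odd-length and centered at 0")
    k = kernel_norm(sigma)
    # log-space evaluation: cosh^(2s) overflows for large |t| * sigma
    log_w = np.log(k) - 2.0 * sigma * (np.abs(t) + np.log1p(np.exp(-2.0 * np.abs(t))) - np.log(2.0))
    w = np.exp(log_w)
    keep = w >= truncation_eps * w.max()
    if keep.sum() < 3:
        raise ValueError("kernel grid too coarse: fewer than 3 points in truncated support")
    t_kept, w_kept = t[keep], w[keep]
    w_kept = w_kept / (w_kept.sum() * dt[0])
    return HTDKernel(sigma=sigma, k_sigma=k, truncation_eps=truncation_eps, times=t_kept, weights=w_kept)


def inst_autocorrelation(z: AnalyticSignal, lag_window: int) -> np.ndarray:
    """Instantaneous autocorrelation K[n, m] = z[n+m] conj(z[n-m]).

    Returns the non-negative half-lags m = 0..(lag_window-1)//2 for every
    sample n, zero-padded at the signal edges; the negative half follows by
    Hermitian symmetry K[n, -m] = conj(K[n, m]).
    """
    if lag_window % 2 == 0:
        raise ValueError("lag_window must be odd")
    v = z.values
    n = v.size
    half = (lag_window - 1) // 2
    zp = np.concatenate([np.zeros(half, complex), v, np.zeros(half, complex)])
    idx = np.arange(n) + half
    m = np.arange(half + 1)
    return zp[idx[:, None] + m[None, :]] * np.conj(zp[idx[:, None] - m[None, :]])


def _frame_centers(n: int, hop: int) -> np.ndarray:
    return np.arange(hop // 2, n, hop)


def _tfd_from_half_lags(
    k_half: np.ndarray, centers: np.ndarray, rate: int, hop: int, lag_window: int, nfft: int
) -> TFDGrid:
    half = k_half.shape[1] - 1
    # symmetric lag taper, unity at m = 0, suppresses lag-truncation ripple
    win = get_window("hann", 2 * half + 1, fftbins=False)[half:]
    kw = k_half[centers] * win[None, :]
    full = np.zeros((centers.size, nfft), dtype=complex)
    full[:, : half + 1] = kw
    full[:, nfft - half :] = np.conj(kw[:, 1:][:, ::-1])
    spec = np.fft.fft(full, axis=1) * (2.0 / rate)  # lag step tau = 2/rate
    resid = np.abs(spec.imag).max()
    scale = np.abs(spec.real).max()
    if scale > 0 and resid > 1e-6 * scale:
        raise ArithmeticError(f"imaginary residue {resid / scale:.2e} exceeds tolerance; TFD assembly inconsistent")
    values = spec.real
    freqs = np.arange(nfft) * rate / (2.0 * nfft)
    return TFDGrid(
        values=values,
        times=centers / rate,
        freqs=freqs,
        rate=rate,
        hop=hop,
        lag_window=lag_window,
        nfft=nfft,
    )


def compute_htd(w: Waveform, cfg: RunConfig | None = None) -> TFDGrid:
    """HTD of a preprocessed mono waveform on a (frame, frequency-bin) grid.

    For each half-lag the autocorrelation sequence is convolved along time
    with the sampled kernel (edge-normalized so the unit-mass property holds
    up to the signal boundary), then an FFT over lags gives frequency.
    """
    cfg = cfg or RunConfig()
    if w.channels != 1:
        raise ValueError("compute_htd expects a mono waveform")
    if w.n_samples < cfg.lag_window:
        raise ValueError(f"waveform ({w.n_samples} samples) shorter than lag window ({cfg.lag_window})")
    z = analytic_signal(w)
    k = inst_autocorrelation(z, cfg.lag_window)
    # kernel sampled at the signal's time step, in kernel units
    du = 1.0 / (w.rate * cfg.kernel_time_scale)
    u_max = np.arccosh(max(1.0, cfg.truncation_eps ** (-1.0 / (2.0 * cfg.sigma))))
    half_n = max(1, int(np.ceil(u_max / du)))
    grid = np.arange(-half_n, half_n + 1) * du
    kern = kernel_weights(cfg.sigma, grid, cfg.truncation_eps)
    wts = kern.weights * du  # discrete weights summing to 1
    sm = fftconvolve(k, wts[:, None], mode="same", axes=0)
    # edge renormalization: near the boundary only part of the kernel mass
    # overlaps the signal; divide by the overlapping mass
    cover = fftconvolve(np.ones(k.shape[0]), wts, mode="same")
    sm = sm / np.maximum(cover, 1e-12)[:, None]
    centers = _frame_centers(w.n_samples, cfg.hop)
    return _tfd_from_half_lags(sm, centers, w.rate, cfg.hop, cfg.lag_window, cfg.nfft_effective)


def wvd_reference(w: Waveform, cfg: RunConfig | None = None) -> TFDGrid:
    """Lag-windowed Wigner-Ville distribution on the same grid as compute_htd.

    This is the no-smoothing limit G(t, tau) = delta(t) of the HTD and serves
    as the sigma -> infinity oracle.
    """
    cfg = cfg or RunConfig()
    if w.channels != 1:
        raise ValueError("wvd_reference expects a mono waveform")
    if w.n_samples < cfg.lag_window:
        raise ValueError(f"waveform ({w.n_samples} samples) shorter than lag window ({cfg.lag_window})")
    z = analytic_signal(w)
    k = inst_autocorrelation(z, cfg.lag_window)
    centers = _frame_centers(w.n_samples, cfg.hop)
    return _tfd_from_half_lags(k, centers, w.rate, cfg.hop, cfg.lag_window, cfg.nfft_effective)


def render_tf_image(
    g: TFDGrid, size: int = 224, colormap: str = "viridis", floor_db: float = 60.0
) -> TFImage:
    """Render a TFD grid as a square RGB image.

    Negative values (quadratic-TFD interference residue) are clipped to zero,
    the surface is log-compressed over a ``floor_db`` dynamic range,
    min-max normalized, mapped through a fixed perceptual colormap and
    bilinearly resized. Rows are frequency (highest at the top), columns are
    time. Deterministic for fixed inputs; an all-zero grid renders as a
    uniform background.
    """
    v = np.clip(g.values, 0.0, None).T[::-1]  # (freq, time), high f on top
    peak = v.max()
    if peak <= 0:
        levels = np.zeros_like(v)
    else:
        db = 10.0 * np.log10(np.maximum(v / peak, 10.0 ** (-floor_db / 10.0)))
        levels = (db + floor_db) / floor_db  # [0, 1]
    rgba = colormaps[colormap](levels.astype(np.float64))
    rgb8 = (rgba[:, :, :3] * 255.0 + 0.5).astype(np.uint8)
    img = Image.fromarray(rgb8).resize((size, size), Image.BILINEAR)
    return TFImage(pixels=np.asarray(img), colormap=colormap, floor_db=floor_db)
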