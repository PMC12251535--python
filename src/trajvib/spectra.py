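"""Time-independent vibrational power spectra of generalized mode velocities.

The spectrum of a mode is the Fourier transform of its velocity
autocorrelation function (Wiener–Khinchin). The default estimator is the
Hann-windowed periodogram, which equals the ACF→FT route up to the window;
the literal ACF route is also provided and the two are tested equal when no
window is applied. Frequencies are reported as wavenumbers,
ν̃[cm⁻¹] = f[fs⁻¹]/c with c = 2.99792458×10⁻⁵ cm/fs.

Normalization: with no window, Σ power·Δν̃ equals the mean square of the
input series; the Hann window is power-corrected so the same identity holds
for stationary signals. Zero-padding (default ×4) interpolates the spectrum
for peak-position readability — it adds no resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.fft

from .constants import C_CM_PER_FS
from .gnm import ModeVelocitySeries


class SpectrumError(ValueError):
    pass


@dataclass
class PowerSpectrum:
    """One-sided spectral density on a wavenumber grid spanning [0, Nyquist]."""

    wavenumber: np.ndarray  # cm⁻¹, strictly increasing
    power: np.ndarray  # ≥ 0, units (input²)·cm
    mode_index: int | None = None
    estimator_meta: dict | None = None

    def peak_wavenumber(self, band: tuple[float, float] | None = None) -> float:
        """Wavenumber of maximal power, optionally within a band (cm⁻¹)."""
        mask = (
            (self.wavenumber >= band[0]) & (self.wavenumber <= band[1])
            if band
            else np.ones_like(self.wavenumber, dtype=bool)
        )
        if not mask.any():
            raise SpectrumError("band does not overlap the wavenumber grid")
        sub = np.where(mask, self.power, -np.inf)
        return float(self.wavenumber[np.argmax(sub)])

    def to_tsv(self, path: str | Path) -> None:
        meta = self.estimator_meta or {}
        header = "# " + " ".join(f"{k}={v}" for k, v in meta.items())
        body = "\n".join(
            f"{w:.8g}\t{p:.8g}" for w, p in zip(self.wavenumber, self.power)
        )
        Path(path).write_text(f"{header}\nwavenumber_cm-1\tpower\n{body}\n")


def autocorrelation(x: np.ndarray) -> np.ndarray:
    """Biased autocorrelation C(τ) = (1/N)·Σ_t x(t)x(t+τ), τ = 0…N−1.

    Computed via FFT with zero-padding to at least 2N so circular wrap-around
    cannot contaminate any lag.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise SpectrumError("autocorrelation needs at least 2 samples")
    nfft = scipy.fft.next_fast_len(2 * n)
    X = scipy.fft.rfft(x, nfft)
    c = scipy.fft.irfft(X * np.conj(X), nfft)[:n]
    return c / n


def autocorrelation_bruteforce(x: np.ndarray) -> np.ndarray:
    """O(N²) direct-sum ACF; independent oracle for the FFT path."""
    x = np.asarray(x, dtype=float)
    n = x.size
    return np.array([np.dot(x[: n - tau], x[tau:]) / n for tau in range(n)])


def _window(name: str, n: int) -> np.ndarray:
    if name == "none":
        return np.ones(n)
    if name == "hann":
        return np.hanning(n)
    raise SpectrumError(f"unknown window {name!r} (use 'none' or 'hann')")


def periodogram(
    x: np.ndarray,
    dt: float,
    *,
    window: str = "hann",
    pad_factor: int = 4,
) -> PowerSpectrum:
    """Windowed, zero-padded periodogram of a real series on a wavenumber axis."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise SpectrumError("series too short")
    w = _window(window, n)
    nfft = scipy.fft.next_fast_len(pad_factor * n)
    X = scipy.fft.rfft(x * w, nfft)
    p = np.abs(X) ** 2
    scale = np.full(p.shape, 2.0)
    scale[0] = 1.0
    if nfft % 2 == 0:
        scale[-1] = 1.0
    power = p * scale * dt * C_CM_PER_FS / (n * np.mean(w**2))
    freq = scipy.fft.rfftfreq(nfft, dt)  # fs⁻¹
    return PowerSpectrum(
        freq / C_CM_PER_FS,
        power,
        estimator_meta={
            "estimator": "periodogram",
            "window": window,
            "pad_factor": pad_factor,
            "n": n,
            "dt_fs": dt,
        },
    )


def acf_spectrum(x: np.ndarray, dt: float, *, pad_factor: int = 4) -> PowerSpectrum:
    """Literal ACF→FT estimator: even-symmetrized biased ACF, cosine transform.

    Only the τ ≥ 0 half of the ACF is computed; even symmetry makes the
    transform real, and the result equals the unwindowed periodogram (the
    Wiener–Khinchin identity, asserted in the tests). Tiny negative values
    from rounding are clipped to zero.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    c = autocorrelation(x)
    nfft = scipy.fft.next_fast_len(pad_factor * n)
    ext = np.zeros(nfft)
    ext[:n] = c
    ext[-(n - 1):] = c[1:][::-1]  # even extension C(−τ) = C(τ)
    spec = scipy.fft.rfft(ext).real
    np.clip(spec, 0.0, None, out=spec)
    p = spec.copy()
    scale = np.full(p.shape, 2.0)
    scale[0] = 1.0
    if nfft % 2 == 0:
        scale[-1] = 1.0
    power = p * scale * dt * C_CM_PER_FS
    freq = scipy.fft.rfftfreq(nfft, dt)
    return PowerSpectrum(
        freq / C_CM_PER_FS,
        power,
        estimator_meta={
            "estimator": "acf",
            "window": "none",
            "pad_factor": pad_factor,
            "n": n,
            "dt_fs": dt,
        },
    )


def power_spectrum(
    series: ModeVelocitySeries,
    channel: int,
    *,
    window: str = "hann",
    method: str = "periodogram",
    pad_factor: int = 4,
) -> PowerSpectrum:
    """Power spectrum of one generalized-mode velocity channel."""
    if not 0 <= channel < series.n_channels:
        raise IndexError(f"channel {channel} out of range ({series.n_channels})")
    x = series.series[:, channel]
    if method == "periodogram":
        ps = periodogram(x, series.dt, window=window, pad_factor=pad_factor)
    elif method == "acf":
        if window != "none":
            raise SpectrumError("the ACF route does not support windowing")
        ps = acf_spectrum(x, series.dt, pad_factor=pad_factor)
    else:
        raise SpectrumError(f"unknown method {method!r}")
    ps.mode_index = int(series.mode_index_map[channel])
    return ps
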