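"""Continuous wavelet transform scalograms of heartbeat segments.

The CWT of a signal x is the inner product with a scaled, shifted mother
wavelet,

    C(a, b) = a^{-1/2} \\int x(t) \\psi((t - b) / a) dt,

evaluated here on the discrete sample grid (t in sample units, so the
scale ``a`` is dimensionless) with trapezoid quadrature over the full
signal support.  The magnitude |C| over a grid of 100 scales is resized
to a square image and min-max normalized — the scalogram the
convolutional branch of the classifier consumes.

Wavelet families follow their standard definitions: ``gausN`` is the
N-th derivative of a Gaussian normalized to unit L2 norm, ``mexh`` the
Mexican hat, and ``morl`` the cosine-modulated Gaussian (real Morlet,
omega0 = 5).  Center frequencies are measured from the FFT peak of the
sampled wavelet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable

import numpy as np
from numpy.polynomial.hermite import Hermite
from scipy.integrate import quad
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import fftconvolve
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "WaveletSpec",
    "ScaleGrid",
    "CwtResult",
    "Scalogram",
    "SUPPORTED_WAVELETS",
    "get_wavelet",
    "make_scales",
    "scale_to_frequency",
    "compute_cwt",
    "compute_cwt_batch",
    "make_scalogram",
    "ScalogramTransformer",
]

SUPPORTED_WAVELETS = ("gaus8", "gaus4", "mexh", "morl")

#: effective support half-width (in wavelet time units) used when
#: sampling a wavelet to locate its spectral peak.
_SUPPORT = 8.0


@dataclass(frozen=True)
class WaveletSpec:
    """A mother wavelet: name, psi(t) callable and center frequency.

    ``fc`` is in cycles per unit of the wavelet's own time axis; with
    scales in sample units the pseudo-frequency of scale ``a`` at
    sampling rate ``fs`` is ``fc * fs / a``.
    """

    name: str
    psi: Callable[[np.ndarray], np.ndarray]
    fc: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.fc > 0:
            raise ValueError("center frequency must be positive")


def _gaussian_derivative(order: int) -> Callable[[np.ndarray], np.ndarray]:
    # d^n/dt^n e^{-t^2} = (-1)^n H_n(t) e^{-t^2}  (physicists' Hermite)
    herm = Hermite.basis(order)
    sign = (-1.0) ** order
    norm_sq, _ = quad(lambda t: (herm(t) * np.exp(-t * t)) ** 2, -np.inf, np.inf)
    scale = 1.0 / np.sqrt(norm_sq)

    def psi(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return scale * sign * herm(t) * np.exp(-t * t)

    return psi


def _mexh(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return (2.0 / (np.sqrt(3.0) * np.pi**0.25)) * (1.0 - t * t) * np.exp(-t * t / 2.0)


def _morl(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.exp(-t * t / 2.0) * np.cos(5.0 * t)


def _fft_center_frequency(psi: Callable, support: float = _SUPPORT) -> float:
    """Locate the dominant frequency of psi from a dense, zero-padded FFT."""
    n = 1 << 16
    span = 8 * support  # long span -> fine frequency resolution (1/span)
    t = np.linspace(-span, span, n)
    spectrum = np.abs(np.fft.rfft(psi(t)))
    freqs = np.fft.rfftfreq(n, d=t[1] - t[0])
    return float(freqs[int(np.argmax(spectrum))])


@lru_cache(maxsize=None)
def get_wavelet(name: str) -> WaveletSpec:
    """Return the registry entry for a supported mother wavelet."""
    if name == "gaus8":
        psi, params = _gaussian_derivative(8), {"order": 8}
    elif name == "gaus4":
        psi, params = _gaussian_derivative(4), {"order": 4}
    elif name == "mexh":
        psi, params = _mexh, {"sigma": 1.0}
    elif name == "morl":
        psi, params = _morl, {"omega0": 5.0}
    else:
        raise ValueError(
            f"unsupported wavelet {name!r}; supported: {', '.join(SUPPORTED_WAVELETS)}"
        )
    return WaveletSpec(name=name, psi=psi, fc=_fft_center_frequency(psi), params=params)


@dataclass(frozen=True)
class ScaleGrid:
    """Strictly increasing, positive wavelet scales (dimensionless)."""

    scales: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "scales", np.asarray(self.scales, dtype=float))
        if self.scales.ndim != 1 or self.scales.size < 1:
            raise ValueError("scales must be a 1-D sequence")
        if np.any(self.scales <= 0):
            raise ValueError("scales must be positive")
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")

    @property
    def n(self) -> int:
        return self.scales.size

    @property
    def lo(self) -> float:
        return float(self.scales[0])

    @property
    def hi(self) -> float:
        return float(self.scales[-1])


def make_scales(n: int = 100, lo: float = 2.16, hi: float = 216.0) -> ScaleGrid:
    """Linearly spaced scale grid including both endpoints.

    The default — 100 values from 2.16 to 216 — spans roughly 1 Hz to
    100 Hz of pseudo-frequency for a unit-fc wavelet at 360 Hz sampling.
    """
    if lo <= 0:
        raise ValueError("lo must be positive")
    if not lo < hi:
        raise ValueError("need lo < hi")
    if n < 2:
        raise ValueError("need at least 2 scales")
    return ScaleGrid(np.linspace(lo, hi, n))


def scale_to_frequency(a, wavelet: WaveletSpec, fs: float):
    """Pseudo-frequency in Hz of scale ``a``: ``fc * fs / a``."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("scale must be positive")
    out = wavelet.fc * fs / a
    return float(out) if out.ndim == 0 else out


@dataclass
class CwtResult:
    """CWT coefficients (n_scales x n_times) with their axes."""

    coefficients: np.ndarray
    scales: ScaleGrid
    frequencies: np.ndarray
    wavelet: str

    def __post_init__(self) -> None:
        if self.coefficients.shape[0] != self.scales.n:
            raise ValueError("coefficient rows must match scale count")


def _trapezoid_weights(n: int) -> np.ndarray:
    w = np.ones(n)
    w[0] = w[-1] = 0.5
    return w


def compute_cwt(
    segment: np.ndarray,
    grid: ScaleGrid | None = None,
    wavelet: WaveletSpec | str = "gaus8",
    fs: float = 360.0,
) -> CwtResult:
    """CWT of one segment over a scale grid.

    Discrete convention (fixed): time in sample units, the integral
    approximated by trapezoid quadrature over the signal's own support,

        C[i, b] = a_i^{-1/2} * sum_n w_n x[n] psi((n - b) / a_i),

    with w the trapezoid weights.  Evaluated for every integer shift b
    via FFT convolution with the wavelet sampled on the full signal
    support (no kernel truncation).
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1 or segment.size < 2:
        raise ValueError("segment must be 1-D with at least 2 samples")
    coeffs = compute_cwt_batch(segment[None, :], grid, wavelet, fs)
    grid = grid or make_scales()
    spec = get_wavelet(wavelet) if isinstance(wavelet, str) else wavelet
    return CwtResult(
        coefficients=coeffs[0],
        scales=grid,
        frequencies=scale_to_frequency(grid.scales, spec, fs),
        wavelet=spec.name,
    )


def compute_cwt_batch(
    segments: np.ndarray,
    grid: ScaleGrid | None = None,
    wavelet: WaveletSpec | str = "gaus8",
    fs: float = 360.0,
) -> np.ndarray:
    """Vectorized CWT of a batch: (B, N) -> (B, n_scales, N)."""
    grid = grid or make_scales()
    spec = get_wavelet(wavelet) if isinstance(wavelet, str) else wavelet
    x = np.asarray(segments, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("segments must be (B, N) with N >= 2")
    b_, n = x.shape
    xw = x * _trapezoid_weights(n)
    m = np.arange(-(n - 1), n)  # kernel support: every shift seen by the signal
    out = np.empty((b_, grid.n, n))
    for i, a in enumerate(grid.scales):
        kernel = spec.psi(m / a)
        # C[b] = sum_n xw[n] k[n - b]  ==  full-conv(xw, k[::-1])[n-1 : 2n-1]
        conv = fftconvolve(xw, kernel[::-1][None, :], axes=1)
        out[:, i, :] = conv[:, n - 1 : 2 * n - 1] / np.sqrt(a)
    return out


@dataclass
class Scalogram:
    """Min-max-normalized |CWT| image in [0, 1]."""

    values: np.ndarray
    wavelet: str
    segment_id: str | None = None

    def __post_init__(self) -> None:
        v = self.values
        if not (np.all(np.isfinite(v)) and v.min() >= 0 and v.max() <= 1):
            raise ValueError("scalogram values must be finite and within [0, 1]")


def _bilinear_resize(arr: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    h, w = arr.shape
    interp = RegularGridInterpolator(
        (np.linspace(0, 1, h), np.linspace(0, 1, w)), arr, method="linear"
    )
    yy, xx = np.meshgrid(
        np.linspace(0, 1, out_shape[0]), np.linspace(0, 1, out_shape[1]),
        indexing="ij",
    )
    return interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(out_shape)


def make_scalogram(
    result: CwtResult,
    out_shape: tuple[int, int] = (100, 100),
    segment_id: str | None = None,
) -> Scalogram:
    """Magnitude image: |C|, bilinear-resized, min-max mapped to [0, 1].

    Constant-magnitude (zero-range) inputs map to an all-zero image.
    """
    values = scalogram_array(np.abs(result.coefficients), out_shape)
    return Scalogram(values=values, wavelet=result.wavelet, segment_id=segment_id)


def scalogram_array(mag: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Resize + min-max normalize a magnitude map (helper for batches)."""
    mag = np.asarray(mag, dtype=float)
    if mag.ndim != 2 or mag.shape[0] < 2 or mag.shape[1] < 2:
        raise ValueError("need a 2-D magnitude map with at least 2 rows and columns")
    img = _bilinear_resize(mag, out_shape)
    rng = img.max() - img.min()
    # constant maps (range 0 up to float wobble) normalize to all-zero
    if rng <= 1e-12 * max(1.0, abs(img.max())):
        return np.zeros(out_shape)
    return np.clip((img - img.min()) / rng, 0.0, 1.0)


class ScalogramTransformer(TransformerMixin, BaseEstimator):
    """Turn beat waveforms into flattened scalogram images.

    A stateless sklearn transformer: ``transform`` maps an ``(n_samples,
    segment_len)`` array of beats to ``(n_samples, h * w)`` flattened
    scalograms (reshape with ``image_shape_``).

    Parameters
    ----------
    wavelet : str, default "gaus8"
        Mother wavelet name (gaus8, gaus4, mexh or morl).
    n_scales, scale_lo, scale_hi :
        Scale grid; defaults 100 scales from 2.16 to 216.
    fs : float, default 360
        Sampling rate used only for the frequency axis metadata.
    out_shape : tuple, default (100, 100)
        Output image shape.
    """

    def __init__(
        self,
        wavelet: str = "gaus8",
        n_scales: int = 100,
        scale_lo: float = 2.16,
        scale_hi: float = 216.0,
        fs: float = 360.0,
        out_shape: tuple[int, int] = (100, 100),
    ):
        self.wavelet = wavelet
        self.n_scales = n_scales
        self.scale_lo = scale_lo
        self.scale_hi = scale_hi
        self.fs = fs
        self.out_shape = out_shape

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, segment_len)")
        self.n_features_in_ = X.shape[1]
        self.image_shape_ = tuple(self.out_shape)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, segment_len)")
        grid = make_scales(self.n_scales, self.scale_lo, self.scale_hi)
        coeffs = compute_cwt_batch(X, grid, self.wavelet, self.fs)
        out = np.empty((X.shape[0], self.out_shape[0] * self.out_shape[1]))
        for i in range(X.shape[0]):
            out[i] = scalogram_array(np.abs(coeffs[i]), tuple(self.out_shape)).ravel()
        self.image_shape_ = tuple(self.out_shape)
        return out
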