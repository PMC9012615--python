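"""Continuous-wavelet-transform encoding of beats as fixed-size images.

A segmented beat x(t) is mapped to the scalogram

    C(a, b) = (1 / sqrt(a)) * sum_t  x(t) * psi((t - b) / a)

for an ordered grid of scales ``a`` and one translation ``b`` per input
sample; the matrix of coefficient magnitudes |C| is min-max normalised,
resized with bilinear interpolation to a square image (224 x 224 by
default) and expanded to three channels.  Because the output size is
fixed, beats of unequal length (a consequence of rate-adaptive
segmentation) all become comparable network inputs.

The transform is computed exactly as the discretised correlation above
(full-support kernels via FFT convolution), so it agrees with a direct
double-sum evaluation to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["CWTConfig", "ScalogramImage", "cwt_scalogram", "render_image",
           "CWTScalogram", "morlet", "mexican_hat", "default_scales"]


def morlet(t: np.ndarray) -> np.ndarray:
    """Real Morlet wavelet exp(-t^2/2) cos(5 t)."""
    t = np.asarray(t, dtype=np.float64)
    return np.exp(-0.5 * t * t) * np.cos(5.0 * t)


def mexican_hat(t: np.ndarray) -> np.ndarray:
    """Mexican-hat (Ricker) wavelet, L2-normalised."""
    t = np.asarray(t, dtype=np.float64)
    return (2.0 / (np.sqrt(3.0) * np.pi ** 0.25)) * (1.0 - t * t) * np.exp(-0.5 * t * t)


_WAVELETS = {"morlet": morlet, "mexican_hat": mexican_hat}
#: centre frequency in cycles/sample at scale 1 (for pseudo-frequency grids)
_CENTER_FREQ = {"morlet": 5.0 / (2.0 * np.pi), "mexican_hat": np.sqrt(2.5) / (2.0 * np.pi)}


def default_scales(n_scales: int = 64, fmin: float = 0.5, fmax: float = 45.0,
                   sampling_rate: float = 360.0, wavelet: str = "morlet") -> np.ndarray:
    """Log-spaced scales covering pseudo-frequencies [fmin, fmax] Hz.

    The grid spans the ECG band (sub-hertz baseline drift up to the
    ~40 Hz QRS content) and is returned in increasing-scale order
    (decreasing frequency), matching the row order of the scalogram.
    """
    fc = _CENTER_FREQ[wavelet]
    freqs = np.geomspace(fmax, fmin, n_scales)
    return fc * sampling_rate / freqs


@dataclass
class CWTConfig:
    """Wavelet family and scale grid for the beat-to-scalogram transform."""

    wavelet: str = "morlet"
    scales: np.ndarray = field(default_factory=default_scales)

    def __post_init__(self):
        self.scales = np.asarray(self.scales, dtype=np.float64)
        if self.wavelet not in _WAVELETS:
            raise ValueError(f"unknown wavelet {self.wavelet!r}; "
                             f"choose from {sorted(_WAVELETS)}")
        if self.scales.size < 2:
            raise ValueError("need at least 2 scales")
        if np.any(self.scales <= 0):
            raise ValueError("scales must be positive")


@dataclass
class ScalogramImage:
    """A rendered beat image plus its label and provenance."""

    pixels: np.ndarray  # (3, H, W) float32 in [0, 1]
    label: str
    record_id: str = ""
    r_current: int = -1
    augmentation: str = "original"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != 3:
            raise ValueError(f"pixels must be (3, H, W), got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")


def cwt_scalogram(samples: np.ndarray, config: CWTConfig | None = None) -> np.ndarray:
    """Magnitude scalogram |C(a_i, b_j)| of shape (n_scales, n_samples)."""
    config = config or CWTConfig()
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("samples must be a 1-D sequence of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    psi = _WAVELETS[config.wavelet]
    n = x.size
    m = np.arange(-(n - 1), n, dtype=np.float64)  # full support: no truncation
    out = np.empty((config.scales.size, n), dtype=np.float64)
    for i, a in enumerate(config.scales):
        kernel = psi(m / a) / np.sqrt(a)
        conv = fftconvolve(x, kernel[::-1], mode="full")
        out[i] = conv[n - 1 : 2 * n - 1]
    return np.abs(out)


def _bilinear_resize_2d(mat: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resampling with half-pixel centres (align_corners=False)."""
    h, w = mat.shape

    def coeffs(size, out):
        pos = np.clip((np.arange(out) + 0.5) * (size / out) - 0.5, 0, size - 1)
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, size - 1)
        return lo, hi, pos - lo

    y0, y1, wy = coeffs(h, out_h)
    x0, x1, wx = coeffs(w, out_w)
    wy = wy[:, None]
    wx = wx[None, :]
    return (mat[np.ix_(y0, x0)] * (1 - wy) * (1 - wx)
            + mat[np.ix_(y0, x1)] * (1 - wy) * wx
            + mat[np.ix_(y1, x0)] * wy * (1 - wx)
            + mat[np.ix_(y1, x1)] * wy * wx)


def render_image(scalogram: np.ndarray, size: int = 224,
                 channel_mode: str = "replicate", label: str = "N",
                 record_id: str = "", r_current: int = -1) -> ScalogramImage:
    """Normalise, resize and channel-expand a scalogram into an image.

    Min-max normalisation maps the matrix onto [0, 1]; a constant matrix
    (no dynamic range) maps to all zeros.  `channel_mode='replicate'`
    copies the grey image into 3 identical channels; `'colormap'` applies
    the matplotlib viridis map for RGB rendering.
    """
    mat = np.asarray(scalogram, dtype=np.float64)
    if mat.ndim != 2 or mat.size == 0:
        raise ValueError("scalogram must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(mat)):
        raise ValueError("scalogram must be finite")
    lo, hi = mat.min(), mat.max()
    norm = np.zeros_like(mat) if hi == lo else (mat - lo) / (hi - lo)
    resized = np.clip(_bilinear_resize_2d(norm, size, size), 0.0, 1.0)
    if channel_mode == "replicate":
        pixels = np.repeat(resized[None], 3, axis=0)
    elif channel_mode == "colormap":
        import matplotlib.cm as cm
        pixels = np.moveaxis(cm.viridis(resized)[..., :3], -1, 0)
    else:
        raise ValueError(f"unknown channel_mode {channel_mode!r}")
    return ScalogramImage(pixels=pixels.astype(np.float32), label=label,
                          record_id=record_id, r_current=r_current)


class CWTScalogram(BaseEstimator, TransformerMixin):
    """Transformer: segmented beats -> stacked scalogram images.

    A stateless sklearn transformer; `transform` accepts a list of
    :class:`~raecg.segmentation.Beat` (or raw 1-D arrays) and returns a
    list of :class:`ScalogramImage`.
    """

    def __init__(self, wavelet: str = "morlet", n_scales: int = 64,
                 fmin: float = 0.5, fmax: float = 45.0,
                 sampling_rate: float = 360.0, image_size: int = 224,
                 channel_mode: str = "replicate"):
        self.wavelet = wavelet
        self.n_scales = n_scales
        self.fmin = fmin
        self.fmax = fmax
        self.sampling_rate = sampling_rate
        self.image_size = image_size
        self.channel_mode = channel_mode

    def _config(self) -> CWTConfig:
        return CWTConfig(wavelet=self.wavelet,
                         scales=default_scales(self.n_scales, self.fmin, self.fmax,
                                               self.sampling_rate, self.wavelet))

    def fit(self, X=None, y=None):
        self.config_ = self._config()
        return self

    def transform(self, X) -> list[ScalogramImage]:
        config = getattr(self, "config_", None) or self._config()
        out = []
        for item in X:
            if hasattr(item, "samples"):
                samples, label = item.samples, item.label
                rec, r = item.record_id, item.r_current
            else:
                samples, label, rec, r = item, "N", "", -1
            mat = cwt_scalogram(samples, config)
            out.append(render_image(mat, size=self.image_size,
                                    channel_mode=self.channel_mode,
                                    label=label, record_id=rec, r_current=r))
        return out
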