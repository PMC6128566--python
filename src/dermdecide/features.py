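"""Wavelet sub-band statistics: the 1152-dimensional texture feature bank.

A canonical 512x512 RGB frame is decomposed channel-by-channel (R, G, B and
Rec.601 luminance) with a 6-level separable 2-D discrete wavelet transform.
Each level yields four sub-bands (LL, LH, HL, HH); from every band twelve
statistics are taken: four global moments of the coefficients (mean,
absolute mean, energy, variance) and the mean and variance of the per-row
and per-column skewness and kurtosis.  6 levels x 4 bands x 4 channels x 12
statistics = 1152 features.

Two transform back-ends are provided:

* ``fir`` — orthonormal finite filter banks (Haar, Daubechies-4, symlet-4,
  discrete Meyer), taps taken from PyWavelets, applied as circular
  (periodic) correlation with stride-2 downsampling.  The analysis operator
  is orthogonal, so the synthesis is its adjoint and energy is conserved
  per level.
* ``fourier`` — the Shannon (ideal half-band) wavelet evaluated exactly in
  the Fourier domain.  On the periodic power-of-two frames used here the
  half-band split is exact; the boundary frequency bin is divided between
  the bands (cosine component to the low band, sine to the high band) so
  the transform stays orthogonal.

The default wavelet is ``shannon``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt

from .errors import InvalidInputError

__all__ = [
    "WaveletFilter",
    "SubbandSet",
    "get_filter",
    "available_filters",
    "dwt_level",
    "idwt_level",
    "multilevel_decompose",
    "multilevel_reconstruct",
    "subband_statistics",
    "extract_features",
    "feature_schema",
    "STATISTIC_NAMES",
    "BAND_NAMES",
    "CHANNEL_NAMES",
    "N_FEATURES",
]

BAND_NAMES = ("LL", "LH", "HL", "HH")
CHANNEL_NAMES = ("R", "G", "B", "Luma")
STATISTIC_NAMES = (
    "mean", "abs_mean", "energy", "variance",
    "mean_row_skew", "var_row_skew", "mean_col_skew", "var_col_skew",
    "mean_row_kurt", "var_row_kurt", "mean_col_kurt", "var_col_kurt",
)
N_FEATURES = 6 * 4 * 4 * 12  # levels x bands x channels x statistics

# Rec.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])

_FIR_FAMILIES = {"haar": "haar", "db4": "db4", "sym4": "sym4", "dmey": "dmey"}


@dataclass(frozen=True)
class WaveletFilter:
    """An analysis filter pair.  For ``mode='fir'`` the low-pass taps sum to
    sqrt(2) and the high-pass is the quadrature mirror of the low-pass; for
    ``mode='fourier'`` the taps are unused and the ideal half-band split is
    applied spectrally."""

    name: str
    lowpass: np.ndarray | None
    highpass: np.ndarray | None
    mode: str  # "fir" | "fourier"

    def __post_init__(self):
        if self.mode not in ("fir", "fourier"):
            raise InvalidInputError(f"unknown filter mode {self.mode!r}")
        if self.mode == "fir":
            a, b = np.asarray(self.lowpass), np.asarray(self.highpass)
            if abs(a.sum() - np.sqrt(2)) > 1e-7:
                raise InvalidInputError("low-pass taps must sum to sqrt(2)")
            if a.shape != b.shape:
                raise InvalidInputError("filter taps must have equal length")


def available_filters() -> tuple[str, ...]:
    return ("shannon",) + tuple(_FIR_FAMILIES)


def get_filter(name: str) -> WaveletFilter:
    """Look up a wavelet by name; ``shannon`` is the spectral half-band
    transform, anything else resolves through the PyWavelets registry."""
    name = name.lower()
    if name == "shannon":
        return WaveletFilter("shannon", None, None, "fourier")
    if name in _FIR_FAMILIES:
        w = pywt.Wavelet(_FIR_FAMILIES[name])
        return WaveletFilter(name, np.asarray(w.dec_lo), np.asarray(w.dec_hi), "fir")
    raise InvalidInputError(
        f"unknown wavelet {name!r}; available: {', '.join(available_filters())}"
    )


@dataclass
class SubbandSet:
    """The four sub-bands of one decomposition level (all of equal shape)."""

    level: int
    LL: np.ndarray
    LH: np.ndarray
    HL: np.ndarray
    HH: np.ndarray

    def bands(self) -> dict[str, np.ndarray]:
        return {"LL": self.LL, "LH": self.LH, "HL": self.HL, "HH": self.HH}


# ---------------------------------------------------------------------------
# 1-D analysis / synthesis along an axis

def _fir_analysis(x: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    # periodic correlation then stride-2 downsampling:
    #   y[n] = sum_m h[m] x[(2n + m) mod N]
    acc = np.zeros_like(x, dtype=float)
    for m, h in enumerate(taps):
        acc += h * np.roll(x, -m, axis=axis)
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(0, None, 2)
    return acc[tuple(sl)]


def _fir_synthesis(y: np.ndarray, taps: np.ndarray, axis: int, n: int) -> np.ndarray:
    # adjoint of _fir_analysis: upsample by 2 then periodic convolution
    shape = list(y.shape)
    shape[axis] = n
    up = np.zeros(shape, dtype=float)
    sl = [slice(None)] * y.ndim
    sl[axis] = slice(0, None, 2)
    up[tuple(sl)] = y
    acc = np.zeros_like(up)
    for m, h in enumerate(taps):
        acc += h * np.roll(up, m, axis=axis)
    return acc


def _fourier_analysis(x: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact Shannon half-band split along *axis*; returns (low, high), each
    of half length.  The boundary bin N/4 contributes its cosine component
    to the low band and its sine component to the high band, keeping the
    transform orthogonal."""
    n = x.shape[axis]
    if n % 4 != 0:
        raise InvalidInputError(
            f"Shannon transform needs an axis length divisible by 4, got {n}"
        )
    m = n // 2
    X = np.fft.fft(x, axis=axis)
    X = np.moveaxis(X, axis, -1)
    s = 1.0 / np.sqrt(2.0)

    low = np.zeros(X.shape[:-1] + (m,), dtype=complex)
    low[..., : m // 2] = s * X[..., : m // 2]
    low[..., m // 2] = X[..., n // 4].real          # boundary cosine
    low[..., m // 2 + 1:] = s * X[..., n - m // 2 + 1:]

    high = np.zeros_like(low)
    high[..., 0] = X[..., n // 4].imag              # boundary sine
    high[..., 1: m] = s * X[..., m // 2 + 1: m // 2 + m]

    low_t = np.fft.ifft(low, axis=-1).real
    high_t = np.fft.ifft(high, axis=-1).real
    return np.moveaxis(low_t, -1, axis), np.moveaxis(high_t, -1, axis)


def _fourier_synthesis(low: np.ndarray, high: np.ndarray, axis: int) -> np.ndarray:
    """Inverse of :func:`_fourier_analysis`."""
    m = low.shape[axis]
    n = 2 * m
    L = np.moveaxis(np.fft.fft(low, axis=axis), axis, -1)
    H = np.moveaxis(np.fft.fft(high, axis=axis), axis, -1)
    r2 = np.sqrt(2.0)
    X = np.zeros(L.shape[:-1] + (n,), dtype=complex)
    X[..., : m // 2] = r2 * L[..., : m // 2]
    X[..., n - m // 2 + 1:] = r2 * L[..., m // 2 + 1:]
    X[..., n // 4] = L[..., m // 2].real + 1j * H[..., 0].real
    X[..., 3 * n // 4] = np.conj(X[..., n // 4])
    X[..., m // 2 + 1: m // 2 + m] = r2 * H[..., 1: m]
    x = np.fft.ifft(X, axis=-1).real
    return np.moveaxis(x, -1, axis)


# ---------------------------------------------------------------------------
# 2-D one-level transform

def dwt_level(channel_matrix: np.ndarray, filt: WaveletFilter,
              level: int = 1, literal_normalisation: bool = False) -> SubbandSet:
    """One separable 2-D decomposition level.

    Filtering is applied first along rows (axis 1) and then along columns
    (axis 0); in the band names the first letter is the column-direction
    (vertical) filter and the second the row-direction one, so HL holds
    vertical detail.  Boundary handling is periodic.

    With ``literal_normalisation`` the sub-bands carry an extra factor of
    sqrt(2) per 1-D stage (2 per level) and a one-sample circular shift,
    reproducing the transform written with an explicit leading factor 2 and
    the ``m - 2n + 2`` index convention instead of the orthonormal one.
    """
    x = np.asarray(channel_matrix, dtype=float)
    if x.ndim != 2:
        raise InvalidInputError("dwt_level expects a 2-D matrix")
    h, w = x.shape
    if h < 2 or w < 2 or h % 2 or w % 2:
        raise InvalidInputError(f"matrix dimensions must be even and >= 2, got {x.shape}")

    if filt.mode == "fir":
        lo_r = _fir_analysis(x, filt.lowpass, axis=1)
        hi_r = _fir_analysis(x, filt.highpass, axis=1)
        ll = _fir_analysis(lo_r, filt.lowpass, axis=0)
        hl = _fir_analysis(lo_r, filt.highpass, axis=0)
        lh = _fir_analysis(hi_r, filt.lowpass, axis=0)
        hh = _fir_analysis(hi_r, filt.highpass, axis=0)
    else:
        lo_r, hi_r = _fourier_analysis(x, axis=1)
        ll, hl = _fourier_analysis(lo_r, axis=0)
        lh, hh = _fourier_analysis(hi_r, axis=0)

    if literal_normalisation:
        ll, lh, hl, hh = (2.0 * np.roll(b, (1, 1), axis=(0, 1))
                          for b in (ll, lh, hl, hh))
    return SubbandSet(level=level, LL=ll, LH=lh, HL=hl, HH=hh)


def idwt_level(bands: SubbandSet, filt: WaveletFilter) -> np.ndarray:
    """Invert one (orthonormal-convention) decomposition level."""
    ll, lh, hl, hh = bands.LL, bands.LH, bands.HL, bands.HH
    h2, w2 = ll.shape
    if filt.mode == "fir":
        lo_r = (_fir_synthesis(ll, filt.lowpass, 0, 2 * h2)
                + _fir_synthesis(hl, filt.highpass, 0, 2 * h2))
        hi_r = (_fir_synthesis(lh, filt.lowpass, 0, 2 * h2)
                + _fir_synthesis(hh, filt.highpass, 0, 2 * h2))
        return (_fir_synthesis(lo_r, filt.lowpass, 1, 2 * w2)
                + _fir_synthesis(hi_r, filt.highpass, 1, 2 * w2))
    lo_r = _fourier_synthesis(ll, hl, axis=0)
    hi_r = _fourier_synthesis(lh, hh, axis=0)
    return _fourier_synthesis(lo_r, hi_r, axis=1)


def multilevel_decompose(channel_matrix: np.ndarray, filt: WaveletFilter,
                         levels: int = 6,
                         literal_normalisation: bool = False) -> list[SubbandSet]:
    """Recursive decomposition: level j+1 is computed from level j's LL band.
    For a 512x512 input and 6 levels the final bands are 8x8."""
    x = np.asarray(channel_matrix, dtype=float)
    if levels < 1:
        raise InvalidInputError("levels must be >= 1")
    side = min(x.shape)
    if side % (2 ** levels):
        raise InvalidInputError(
            f"{levels} levels need dimensions divisible by {2 ** levels}, got {x.shape}"
        )
    out: list[SubbandSet] = []
    current = x
    for j in range(1, levels + 1):
        bands = dwt_level(current, filt, level=j,
                          literal_normalisation=literal_normalisation)
        out.append(bands)
        current = bands.LL
    return out


def multilevel_reconstruct(pyramid: Sequence[SubbandSet],
                           filt: WaveletFilter) -> np.ndarray:
    """Invert :func:`multilevel_decompose` (orthonormal convention only)."""
    current = pyramid[-1].LL
    for bands in reversed(pyramid):
        bands = SubbandSet(bands.level, current, bands.LH, bands.HL, bands.HH)
        current = idwt_level(bands, filt)
    return current


# ---------------------------------------------------------------------------
# statistics

def _axis_moments(band: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Population skewness and raw kurtosis of every 1-D slice along *axis*.
    Slices with zero variance contribute 0 for both (constant padding must
    yield finite features)."""
    mu = band.mean(axis=axis, keepdims=True)
    d = band - mu
    m2 = np.mean(d ** 2, axis=axis)
    m3 = np.mean(d ** 3, axis=axis)
    m4 = np.mean(d ** 4, axis=axis)
    ok = m2 > 0
    skew = np.zeros_like(m2)
    kurt = np.zeros_like(m2)
    np.divide(m3, m2 ** 1.5, out=skew, where=ok)
    np.divide(m4, m2 ** 2, out=kurt, where=ok)
    return skew, kurt


def subband_statistics(band: np.ndarray) -> np.ndarray:
    """The 12 per-band statistics, in canonical order (see
    :data:`STATISTIC_NAMES`).

    Energy is the mean of squared coefficients; variance, skewness and
    kurtosis use population (biased) moment estimators and kurtosis is raw
    (a Gaussian has kurtosis 3).  Row statistics summarise each horizontal
    slice, column statistics each vertical slice.
    """
    band = np.asarray(band, dtype=float)
    if band.ndim != 2 or band.shape[0] < 2 or band.shape[1] < 2:
        raise InvalidInputError(f"band must be at least 2x2, got {band.shape}")
    row_skew, row_kurt = _axis_moments(band, axis=1)
    col_skew, col_kurt = _axis_moments(band, axis=0)
    return np.array([
        band.mean(),
        np.abs(band).mean(),
        np.mean(band ** 2),
        band.var(),
        row_skew.mean(), row_skew.var(),
        col_skew.mean(), col_skew.var(),
        row_kurt.mean(), row_kurt.var(),
        col_kurt.mean(), col_kurt.var(),
    ])


def _channels(image: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "R": image[..., 0],
        "G": image[..., 1],
        "B": image[..., 2],
        "Luma": image @ _LUMA,
    }


def extract_features(image: np.ndarray, filt: WaveletFilter | str = "shannon",
                     levels: int = 6,
                     literal_normalisation: bool = False) -> np.ndarray:
    """The full feature vector of a canonical 512x512x3 frame.

    Features are ordered by (level, band, channel, statistic) with bands in
    LL, LH, HL, HH order, channels R, G, B, Luma and statistics as in
    :data:`STATISTIC_NAMES`; :func:`feature_schema` names every position.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise InvalidInputError(f"expected an HxWx3 image, got shape {image.shape}")
    if isinstance(filt, str):
        filt = get_filter(filt)
    pyramids = {
        name: multilevel_decompose(chan, filt, levels, literal_normalisation)
        for name, chan in _channels(image).items()
    }
    out = []
    for level in range(levels):
        for band in BAND_NAMES:
            for channel in CHANNEL_NAMES:
                out.append(subband_statistics(pyramids[channel][level].bands()[band]))
    return np.concatenate(out)


def feature_schema(levels: int = 6) -> list[str]:
    """Column names ``L{level}_{band}_{channel}_{stat}`` in extraction order."""
    return [
        f"L{level}_{band}_{channel}_{stat}"
        for level in range(1, levels + 1)
        for band in BAND_NAMES
        for channel in CHANNEL_NAMES
        for stat in STATISTIC_NAMES
    ]
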