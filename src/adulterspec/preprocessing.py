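"""Spectral preprocessing: Savitzky–Golay smoothing/derivatives and a
single-scale continuous wavelet transform at dyadic scales 2^1..2^9.

The study's preprocessing menu is: raw (full spectrum), SG smoothing
(window 15, polynomial degree 2), SG first and second derivatives, and
SG followed by a CWT at one of nine dyadic scales ("SG–CWT (L1..L9)").
Each method maps a spectrum to an equal-length vector, so the 2068-point
grid is preserved throughout.

Notes on conventions:

* SG derivatives are returned in per-index units (no division by Δλ): the
  downstream regressions are scale-invariant, and this avoids assuming a
  uniform grid.
* The CWT at scale a is the L1-normalised correlation
  c[n] = (1/a) Σ_k x[k] ψ((k−n)/a) over a symmetric boundary extension.
  L1 normalisation makes the transform a genuine smoother: the white-noise
  coefficient variance falls ~1/a as the scale grows.
* The mother wavelet defaults to the Mexican hat ("mexh"), the usual choice
  for peak-shaped spectra; any real-valued continuous wavelet known to
  PyWavelets may be named instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy.signal import fftconvolve, savgol_filter

from .spectra_core import SpectraDataset

__all__ = [
    "PreprocessSpec",
    "METHODS",
    "sg_filter",
    "cwt_transform",
    "preprocess",
    "standard_method_specs",
]

METHODS = ("raw", "sg", "sg_1st", "sg_2nd", "sg_cwt")


@dataclass(frozen=True)
class PreprocessSpec:
    """One preprocessing method and its parameters.

    ``cwt_level`` L means dyadic scale a = 2^L; only meaningful (and
    required) for method "sg_cwt".
    """

    method: str = "raw"
    sg_window: int = 15
    sg_polyorder: int = 2
    cwt_level: int = None
    wavelet_name: str = "mexh"

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected {METHODS}")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if self.method == "sg_cwt":
            if self.cwt_level is None or not 1 <= int(self.cwt_level) <= 9:
                raise ValueError("sg_cwt requires cwt_level in [1, 9]")

    @property
    def label(self) -> str:
        names = {"raw": "FS", "sg": "SG", "sg_1st": "SG-1st", "sg_2nd": "SG-2nd"}
        if self.method == "sg_cwt":
            return f"SG-CWT (L{self.cwt_level})"
        return names[self.method]


def standard_method_specs(sg_window: int = 15, sg_polyorder: int = 2,
                          wavelet_name: str = "mexh") -> list:
    """The 13-method comparison menu: FS, SG, SG-1st, SG-2nd, SG-CWT L1..L9."""
    base = dict(sg_window=sg_window, sg_polyorder=sg_polyorder,
                wavelet_name=wavelet_name)
    specs = [PreprocessSpec("raw", **base), PreprocessSpec("sg", **base),
             PreprocessSpec("sg_1st", **base), PreprocessSpec("sg_2nd", **base)]
    specs += [PreprocessSpec("sg_cwt", cwt_level=level, **base)
              for level in range(1, 10)]
    return specs


def sg_filter(x: np.ndarray, window: int = 15, polyorder: int = 2,
              deriv: int = 0) -> np.ndarray:
    """Savitzky–Golay filtering: per-point least-squares polynomial fit over a
    centred window, evaluated (deriv-th derivative, per-index units) at the
    centre; edges by polynomial extrapolation of the terminal windows."""
    x = np.asarray(x, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and > polyorder")
    if deriv not in (0, 1, 2):
        raise ValueError("deriv must be 0, 1 or 2")
    if x.shape[-1] < window:
        raise ValueError(f"signal length {x.shape[-1]} < window {window}")
    return savgol_filter(x, window, polyorder, deriv=deriv, delta=1.0,
                         axis=-1, mode="interp")


def _wavelet_kernel(level: int, wavelet_name: str) -> np.ndarray:
    try:
        wav = pywt.ContinuousWavelet(wavelet_name)
    except ValueError as exc:
        raise ValueError(
            f"unknown wavelet {wavelet_name!r}; supported continuous wavelets: "
            f"{pywt.wavelist(kind='continuous')}") from exc
    psi, t = wav.wavefun(10)
    if np.iscomplexobj(psi):
        raise ValueError(f"wavelet {wavelet_name!r} is complex-valued; "
                         f"use a real wavelet such as 'mexh' or 'morl'")
    a = 2.0 ** level
    half = int(np.ceil(max(abs(t[0]), abs(t[-1])) * a))
    offsets = np.arange(-half, half + 1)
    kernel = np.interp(offsets / a, t, psi, left=0.0, right=0.0) / a
    return kernel


def cwt_transform(x: np.ndarray, level: int, wavelet_name: str = "mexh") -> np.ndarray:
    """Continuous wavelet coefficients of x at single dyadic scale 2^level.

    Same length as x; the signal is extended symmetrically at both ends so
    boundary coefficients are defined. Works on a vector or row-wise on a
    matrix (last axis = wavelength).
    """
    x = np.asarray(x, dtype=float)
    if not 1 <= int(level) <= 9:
        raise ValueError("level must be in [1, 9]")
    n = x.shape[-1]
    if n <= 2 ** level:
        raise ValueError(f"signal length {n} must exceed scale 2^{level}")
    kernel = _wavelet_kernel(level, wavelet_name)
    half = (len(kernel) - 1) // 2
    pad = [(0, 0)] * (x.ndim - 1) + [(half, half)]
    xp = np.pad(x, pad, mode="symmetric")
    # correlation with the translated wavelet == convolution with its mirror
    flipped = kernel[::-1]
    if x.ndim == 1:
        return fftconvolve(xp, flipped, mode="valid")
    return fftconvolve(xp, flipped[None, :], mode="valid", axes=-1)


def preprocess(ds: SpectraDataset, spec: PreprocessSpec) -> SpectraDataset:
    """Apply one preprocessing method row-wise; grid and metadata unchanged."""
    if spec.method == "raw":
        return ds.with_X(ds.X.copy())
    deriv = {"sg": 0, "sg_1st": 1, "sg_2nd": 2, "sg_cwt": 0}[spec.method]
    X = sg_filter(ds.X, spec.sg_window, spec.sg_polyorder, deriv=deriv)
    if spec.method == "sg_cwt":
        X = cwt_transform(X, spec.cwt_level, spec.wavelet_name)
    return ds.with_X(X)
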