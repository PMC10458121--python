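"""Synthetic oil spectra emulating the adulteration study design.

No public dataset of the measured oil spectra exists, so this module
generates absorbance spectra with the structure the study describes: five
absorption bands near 250 nm (UV), 430 and 660 nm (Vis), and 930 and 1050 nm
(NIR); camellia oil differing most from soybean/rapeseed/corn at the 430 nm
band and from peanut at the 660 nm band; blends at 14 ratios from 1% to 90%
with four replicates each, plus four replicates of each pure endpoint —
64 samples per adulterant set, 256 in total.

Pure-oil curves are sums of Gaussian bands over a shared smooth baseline;
mixtures are linear in absorbance (Beer–Lambert additivity for
non-interacting oils). Replicate noise is i.i.d. Gaussian per point plus a
smooth per-sample baseline drift (constant + tilt + curvature).

The per-oil band-amplitude tables are module-level data (``AMPLITUDES``) and
deliberately simple to edit: the sign and size of (adulterant − camellia) at
each band sets the sign and strength of the absorbance-vs-content
correlation at that band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra_core import (ADULTERANTS, OIL_TYPES, SpectraDataset, SpectraError,
                           Spectrum, WavelengthGrid, default_grid)

__all__ = [
    "PureOilProfile",
    "MixDesign",
    "PEAK_CENTERS_NM",
    "PEAK_WIDTHS_NM",
    "AMPLITUDES",
    "make_pure_profile",
    "mix_spectra",
    "generate_adulterant_set",
    "generate_full_study",
]

#: the five absorption band centres (nm): UV, Vis, Vis, NIR, NIR
PEAK_CENTERS_NM = np.array([250.0, 430.0, 660.0, 930.0, 1050.0])
#: Gaussian standard deviations per band (nm)
PEAK_WIDTHS_NM = np.array([16.0, 20.0, 18.0, 22.0, 18.0])

# Band amplitudes (absorbance) per oil. Chosen so that, relative to camellia:
# soybean/rapeseed/corn differ most at 430 nm, peanut at 660 nm; for soybean
# the |difference| ordering is Vis(430) > NIR(930) > UV(250), reproducing the
# reported Vis >= NIR >= UV correlation-strength ordering; rapeseed and
# peanut differ with positive sign in the UV/Vis where the study reports
# positive correlations.
AMPLITUDES = {
    "camellia": np.array([1.20, 0.80, 0.50, 0.45, 0.35]),
    "soybean":  np.array([1.12, 0.50, 0.38, 0.30, 0.25]),
    "corn":     np.array([1.15, 0.52, 0.40, 0.32, 0.26]),
    "rapeseed": np.array([1.30, 0.48, 0.36, 0.29, 0.23]),
    "peanut":   np.array([1.26, 0.92, 0.80, 0.35, 0.28]),
}

#: default blend ratios: 1%..90% adulterant in camellia oil
DEFAULT_RATIOS = (0.01, 0.03, 0.05, 0.07, 0.10, 0.15, 0.20,
                  0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90)

_BASELINE_LEVEL = 0.25
_BASELINE_UV_EDGE = 0.15  # decaying UV absorption edge


@dataclass(frozen=True)
class PureOilProfile:
    """Parametric description of one pure oil's absorbance curve."""

    oil_type: str
    peak_centers: np.ndarray = field(default_factory=lambda: PEAK_CENTERS_NM.copy())
    peak_amplitudes: np.ndarray = None
    peak_widths: np.ndarray = field(default_factory=lambda: PEAK_WIDTHS_NM.copy())
    baseline: float = _BASELINE_LEVEL

    def __post_init__(self):
        if self.oil_type not in OIL_TYPES:
            raise SpectraError(
                f"unknown oil type {self.oil_type!r}; expected one of {OIL_TYPES}")
        if self.peak_amplitudes is None:
            object.__setattr__(self, "peak_amplitudes",
                               AMPLITUDES[self.oil_type].copy())
        if np.any(np.asarray(self.peak_amplitudes) < 0):
            raise SpectraError("peak amplitudes must be non-negative")

    def evaluate(self, grid: WavelengthGrid) -> np.ndarray:
        lam = grid.values
        a = np.full_like(lam, self.baseline)
        a += _BASELINE_UV_EDGE * np.exp(-(lam - lam[0]) / 180.0)
        for c, amp, w in zip(self.peak_centers, self.peak_amplitudes,
                             self.peak_widths):
            a += amp * np.exp(-0.5 * ((lam - c) / w) ** 2)
        return a


@dataclass(frozen=True)
class MixDesign:
    """Blend-ratio design and noise settings for one adulterant set."""

    ratios: tuple = DEFAULT_RATIOS
    replicates_per_ratio: int = 4
    replicates_per_pure: int = 4
    noise_sd: float = 0.005
    baseline_drift_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        r = np.asarray(self.ratios, dtype=float)
        if np.any(np.diff(r) <= 0):
            raise SpectraError("blend ratios must be strictly increasing")
        if np.any((r <= 0) | (r >= 1)):
            raise SpectraError("blend ratios must lie strictly in (0, 1)")
        if self.replicates_per_ratio < 1 or self.replicates_per_pure < 1:
            raise SpectraError("replicate counts must be >= 1")
        if self.noise_sd < 0 or self.baseline_drift_sd < 0:
            raise SpectraError("noise standard deviations must be >= 0")

    @property
    def n_samples(self) -> int:
        return (len(self.ratios) * self.replicates_per_ratio
                + 2 * self.replicates_per_pure)


def make_pure_profile(oil_type: str, grid: WavelengthGrid) -> Spectrum:
    """Deterministic noise-free absorbance curve of one pure oil."""
    return Spectrum(grid, PureOilProfile(oil_type).evaluate(grid))


def mix_spectra(camellia: Spectrum, adulterant: Spectrum, ratio: float) -> Spectrum:
    """Linear absorbance blend: ratio·adulterant + (1−ratio)·camellia."""
    if not np.array_equal(camellia.grid.values, adulterant.grid.values):
        raise SpectraError("mixture components must share one wavelength grid")
    if not 0.0 <= ratio <= 1.0:
        raise SpectraError(f"blend ratio {ratio} outside [0, 1]")
    return Spectrum(camellia.grid,
                    ratio * adulterant.absorbance
                    + (1.0 - ratio) * camellia.absorbance)


def _smooth_drift(rng: np.random.Generator, lam: np.ndarray, sd: float) -> np.ndarray:
    # constant + tilt + curvature on a normalised axis; coefficient scales
    # taper so the constant term carries most of the drift budget
    t = (lam - lam.mean()) / ((lam[-1] - lam[0]) / 2.0)
    c0, c1, c2 = rng.normal(0.0, [sd, sd / 2.0, sd / 4.0])
    return c0 + c1 * t + c2 * (t ** 2 - 1.0 / 3.0)


def generate_adulterant_set(adulterant_type: str,
                            design: MixDesign = MixDesign(),
                            grid: WavelengthGrid = None,
                            rng: np.random.Generator = None) -> SpectraDataset:
    """One adulterant set: blends at every design ratio plus pure endpoints.

    Row order: for each ratio, ``replicates_per_ratio`` rows; then pure
    camellia (y=0, label "none"); then pure adulterant (y=1). With the
    default design that is 14×4 + 4 + 4 = 64 rows.
    """
    if adulterant_type not in ADULTERANTS:
        raise SpectraError(
            f"adulterant must be one of {ADULTERANTS}, got {adulterant_type!r}")
    if grid is None:
        grid = default_grid()
    if rng is None:
        rng = np.random.default_rng(design.seed)
    cam = make_pure_profile("camellia", grid)
    adu = make_pure_profile(adulterant_type, grid)

    ys, labels, reps, rows = [], [], [], []
    for ratio in design.ratios:
        for r in range(design.replicates_per_ratio):
            rows.append(mix_spectra(cam, adu, ratio).absorbance)
            ys.append(ratio)
            labels.append(adulterant_type)
            reps.append(r)
    for r in range(design.replicates_per_pure):
        rows.append(cam.absorbance)
        ys.append(0.0)
        labels.append("none")
        reps.append(r)
    for r in range(design.replicates_per_pure):
        rows.append(adu.absorbance)
        ys.append(1.0)
        labels.append(adulterant_type)
        reps.append(r)

    X = np.asarray(rows)
    lam = grid.values
    for i in range(X.shape[0]):
        X[i] += _smooth_drift(rng, lam, design.baseline_drift_sd)
        X[i] += rng.normal(0.0, design.noise_sd, size=lam.size)
    return SpectraDataset(grid, X, np.asarray(ys), np.asarray(labels, dtype=object),
                          np.asarray(reps))


def generate_full_study(design: MixDesign = MixDesign(),
                        grid: WavelengthGrid = None,
                        share_camellia: bool = False) -> dict:
    """All four adulterant sets (soybean, rapeseed, corn, peanut).

    Each set gets an independent noise stream derived from ``design.seed``.
    With ``share_camellia=True`` the pure-camellia replicate rows (noise
    included) are identical across the four sets, emulating a study that
    measured one shared camellia batch.
    """
    if grid is None:
        grid = default_grid()
    children = np.random.SeedSequence(design.seed).spawn(len(ADULTERANTS) + 1)
    shared_block = None
    out = {}
    for name, ss in zip(ADULTERANTS, children):
        ds = generate_adulterant_set(name, design, grid,
                                     rng=np.random.default_rng(ss))
        if share_camellia:
            mask = np.flatnonzero(ds.adulterant == "none")
            if shared_block is None:
                cam_rng = np.random.default_rng(children[-1])
                cam = make_pure_profile("camellia", grid).absorbance
                shared_block = np.array([
                    cam + _smooth_drift(cam_rng, grid.values, design.baseline_drift_sd)
                    + cam_rng.normal(0.0, design.noise_sd, size=len(grid))
                    for _ in range(design.replicates_per_pure)])
            ds.X[mask] = shared_block
        out[name] = ds
    return out
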