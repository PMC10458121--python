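"""Domain containers and absorbance primitives for UV-Vis-NIR transmission spectra.

The instrument records three intensity vectors on a shared wavelength grid —
the sample scan S(λ), a dark scan D(λ) and an empty-cuvette reference R(λ) —
from which absorbance is computed as

    A(λ) = -log10( (S(λ) - D(λ)) / (R(λ) - D(λ)) )

Downstream stages work on a :class:`SpectraDataset`: an (n_samples ×
n_wavelengths) absorbance matrix with the adulteration fraction y ∈ [0, 1],
an adulterant label and a replicate id per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "RawMeasurement",
    "Spectrum",
    "SpectraDataset",
    "SpectraError",
    "AbsorbanceDomainError",
    "SpectraParseError",
    "ADULTERANTS",
    "OIL_TYPES",
    "default_grid",
    "compute_absorbance",
    "average_replicate_scans",
    "read_spectra_csv",
    "write_spectra_csv",
]

ADULTERANTS = ("soybean", "rapeseed", "corn", "peanut")
OIL_TYPES = ("camellia",) + ADULTERANTS

#: number of detector pixels over the instrument's 200-1100 nm scan range
DEFAULT_N_POINTS = 2068
DEFAULT_RANGE_NM = (200.0, 1100.0)

_FLOAT_FMT = "%.17g"  # round-trips doubles exactly -> byte-stable rewrite


class SpectraError(ValueError):
    """Base class for domain-level spectra errors."""


class AbsorbanceDomainError(SpectraError):
    """Non-positive transmittance: absorbance is undefined at some wavelengths."""

    def __init__(self, message: str, wavelengths_nm: np.ndarray):
        super().__init__(message)
        self.wavelengths_nm = np.asarray(wavelengths_nm)


class SpectraParseError(SpectraError):
    """Malformed spectra / metadata CSV."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly ascending wavelength axis in nanometres."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise SpectraError("wavelength grid must be 1-D with at least 2 points")
        if not np.all(np.isfinite(values)):
            raise SpectraError("wavelength grid contains non-finite values")
        if np.any(np.diff(values) <= 0):
            raise SpectraError("wavelength grid must be strictly increasing")
        if values[0] < 100.0 or values[-1] > 2500.0:
            raise SpectraError("wavelengths must lie within [100, 2500] nm")

    def __len__(self) -> int:
        return self.values.size

    def band_masks(self, uv_vis_cut: float = 400.0, vis_nir_cut: float = 780.0):
        """Boolean masks for the UV (<400 nm), Vis (400-780 nm), NIR (>780 nm) bands."""
        v = self.values
        uv = v < uv_vis_cut
        vis = (v >= uv_vis_cut) & (v <= vis_nir_cut)
        nir = v > vis_nir_cut
        return uv, vis, nir

    def nearest_index(self, wavelength_nm: float) -> int:
        return int(np.argmin(np.abs(self.values - wavelength_nm)))


def default_grid(n_points: int = DEFAULT_N_POINTS,
                 low_nm: float = DEFAULT_RANGE_NM[0],
                 high_nm: float = DEFAULT_RANGE_NM[1]) -> WavelengthGrid:
    """Evenly spaced grid; 2068 points over 200-1100 nm by default.

    The real detector grid is slightly pixel-nonlinear; a uniform grid is the
    neutral stand-in and no operation in this package assumes uniform spacing.
    """
    return WavelengthGrid(np.linspace(low_nm, high_nm, n_points))


@dataclass(frozen=True)
class RawMeasurement:
    """Intensity triplet (sample S, dark D, reference R) on one grid."""

    grid: WavelengthGrid
    sample_intensity: np.ndarray
    dark_intensity: np.ndarray
    reference_intensity: np.ndarray

    def __post_init__(self):
        n = len(self.grid)
        for name in ("sample_intensity", "dark_intensity", "reference_intensity"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (n,):
                raise SpectraError(f"{name} length {v.shape} != grid length {n}")
        denom = self.reference_intensity - self.dark_intensity
        if np.any(denom <= 0):
            bad = self.grid.values[denom <= 0]
            raise AbsorbanceDomainError(
                f"reference - dark must be positive everywhere; "
                f"violated at {bad.size} wavelengths (first: {bad[:5]} nm)", bad)


@dataclass(frozen=True)
class Spectrum:
    """A single absorbance spectrum A(λ) on a wavelength grid."""

    grid: WavelengthGrid
    absorbance: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "absorbance", a)
        if a.shape != (len(self.grid),):
            raise SpectraError("absorbance length does not match grid")
        if not np.all(np.isfinite(a)):
            raise SpectraError("absorbance contains non-finite values")


@dataclass
class SpectraDataset:
    """Absorbance matrix with per-sample adulteration metadata.

    X is (n_samples × n_wavelengths); ``y`` is the adulteration fraction in
    [0, 1] (0 = pure camellia, 1 = pure adulterant); ``adulterant`` is the
    adulterant oil per sample ("none" for pure camellia rows).
    """

    grid: WavelengthGrid
    X: np.ndarray
    y: np.ndarray
    adulterant: np.ndarray
    replicate_id: np.ndarray
    sample_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.adulterant = np.asarray(self.adulterant, dtype=object)
        self.replicate_id = np.asarray(self.replicate_id, dtype=int)
        n = self.X.shape[0]
        if self.X.ndim != 2 or self.X.shape[1] != len(self.grid):
            raise SpectraError("X must be (n_samples, n_wavelengths) matching the grid")
        if self.y.shape != (n,):
            raise SpectraError("y length must equal number of rows of X")
        if np.any(~np.isfinite(self.X)):
            raise SpectraError("X contains NaN/inf")
        if np.any((self.y < 0) | (self.y > 1)):
            raise SpectraError("adulteration fractions must lie in [0, 1]")
        bad = set(map(str, self.adulterant)) - set(ADULTERANTS) - {"none"}
        if bad:
            raise SpectraError(f"unknown adulterant labels: {sorted(bad)}")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i:04d}" for i in range(n)], dtype=object)
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
            if len(set(self.sample_ids)) != n:
                raise SpectraError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]

    def subset_wavelengths(self, indices) -> "SpectraDataset":
        idx = np.asarray(indices, dtype=int)
        return SpectraDataset(WavelengthGrid(self.grid.values[idx]),
                              self.X[:, idx], self.y, self.adulterant,
                              self.replicate_id, self.sample_ids)

    def with_X(self, X: np.ndarray) -> "SpectraDataset":
        return SpectraDataset(self.grid, X, self.y, self.adulterant,
                              self.replicate_id, self.sample_ids)


def compute_absorbance(m: RawMeasurement) -> Spectrum:
    """Absorbance A = -log10((S - D) / (R - D)); errors if transmittance <= 0."""
    numer = m.sample_intensity - m.dark_intensity
    if np.any(numer <= 0):
        bad = m.grid.values[numer <= 0]
        raise AbsorbanceDomainError(
            f"sample - dark must be positive everywhere; violated at "
            f"{bad.size} wavelengths (first: {bad[:5]} nm)", bad)
    denom = m.reference_intensity - m.dark_intensity
    return Spectrum(m.grid, -np.log10(numer / denom))


def average_replicate_scans(spectra: list, expected_count: int = 3) -> Spectrum:
    """Element-wise mean of repeated scans of one sample (instrument protocol
    averages three). A count other than ``expected_count`` warns, not errors."""
    if not spectra:
        raise SpectraError("no spectra to average")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if not np.array_equal(s.grid.values, grid.values):
            raise SpectraError("replicate scans must share one wavelength grid")
    if len(spectra) != expected_count:
        warnings.warn(
            f"averaging {len(spectra)} scans, expected {expected_count}",
            stacklevel=2)
    return Spectrum(grid, np.mean([s.absorbance for s in spectra], axis=0))


# ---------------------------------------------------------------------------
# CSV I/O: wide spectra file (wavelength_nm + one column per sample) plus a
# companion metadata file (sample_id, adulterant, fraction, replicate).
# ---------------------------------------------------------------------------

def write_spectra_csv(ds: SpectraDataset, path, metadata_path) -> None:
    ids = [str(s) for s in ds.sample_ids]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(["wavelength_nm"] + ids) + "\n")
        for j in range(ds.n_wavelengths):
            row = [_FLOAT_FMT % ds.grid.values[j]]
            row += [_FLOAT_FMT % v for v in ds.X[:, j]]
            fh.write(",".join(row) + "\n")
    with open(metadata_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id,adulterant,fraction,replicate\n")
        for i in range(ds.n_samples):
            fh.write(f"{ids[i]},{ds.adulterant[i]},"
                     f"{_FLOAT_FMT % ds.y[i]},{ds.replicate_id[i]}\n")


def read_spectra_csv(path, metadata_path) -> SpectraDataset:
    try:
        wide = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas reports the offending line itself
        raise SpectraParseError(f"{path}: {exc}") from exc
    if wide.columns[0] != "wavelength_nm":
        raise SpectraParseError(
            f"{path}: line 1: first column must be 'wavelength_nm', "
            f"got {wide.columns[0]!r}")
    sample_cols = list(wide.columns[1:])
    if len(set(sample_cols)) != len(sample_cols):
        raise SpectraParseError(f"{path}: line 1: duplicate sample ids in header")
    for col in wide.columns:
        if not pd.api.types.is_numeric_dtype(wide[col]):
            bad = wide.index[pd.to_numeric(wide[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise SpectraParseError(
                f"{path}: line {line}: non-numeric value in column {col!r}")
        if wide[col].isna().any():
            line = int(wide.index[wide[col].isna()][0]) + 2
            raise SpectraParseError(f"{path}: line {line}: missing value in {col!r}")

    try:
        meta = pd.read_csv(metadata_path, float_precision="round_trip")
    except Exception as exc:
        raise SpectraParseError(f"{metadata_path}: {exc}") from exc
    required = ["sample_id", "adulterant", "fraction", "replicate"]
    if list(meta.columns) != required:
        raise SpectraParseError(
            f"{metadata_path}: line 1: expected columns {required}, "
            f"got {list(meta.columns)}")
    meta = meta.set_index("sample_id")
    missing = [s for s in sample_cols if s not in meta.index]
    if missing:
        raise SpectraParseError(
            f"{metadata_path}: no metadata rows for samples {missing[:5]}")
    meta = meta.loc[sample_cols]
    frac = meta["fraction"].to_numpy(dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        bad = int(np.argmax((frac < 0) | (frac > 1)))
        raise SpectraParseError(
            f"{metadata_path}: sample {sample_cols[bad]!r}: fraction "
            f"{frac[bad]} outside [0, 1]")
    grid = WavelengthGrid(wide["wavelength_nm"].to_numpy(dtype=float))
    X = wide[sample_cols].to_numpy(dtype=float).T
    return SpectraDataset(grid, X, frac,
                          meta["adulterant"].to_numpy(dtype=object),
                          meta["replicate"].to_numpy(dtype=int),
                          np.array(sample_cols, dtype=object))
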