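"""Spectral pretreatment: normalization, Savitzky-Golay smoothing and second
derivative, wavenumber-region selection, mean centering.

The canonical chain, applied in this order, is

1. unit-vector (2-norm) normalization of each raw spectrum over the full
   recorded range (removes film-thickness / global amplitude variation),
2. Savitzky-Golay smoothing, 5 points, polynomial order 2,
3. Savitzky-Golay second derivative, 7 points, polynomial order 2
   (sharpens and resolves overlapping bands; band maxima become derivative
   minima),
4. restriction to the modelling region (closed wavenumber interval),
5. mean centering with the *training* column means.

Steps 1-4 are sample-wise and stateless; only the centering means are fitted
state, so a fitted pipeline transforms held-out samples without touching
their labels or leaking their values into the training statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigError, DegenerateInputError, RegionError
from .io import Spectrum, SpectralDataset


@dataclass(frozen=True)
class PreprocessConfig:
    norm: str = "unit-vector"  # "unit-vector" | "none"
    smooth_window: int = 5
    smooth_polyorder: int = 2
    deriv_window: int = 7
    deriv_polyorder: int = 2
    deriv_order: int = 2
    region: tuple[float, float] = (1528.0, 1624.0)
    mean_center: bool = True

    def __post_init__(self) -> None:
        if self.norm not in ("unit-vector", "none"):
            raise ConfigError(f"unknown normalization {self.norm!r}")
        for w, p, nm in [
            (self.smooth_window, self.smooth_polyorder, "smooth"),
            (self.deriv_window, self.deriv_polyorder, "deriv"),
        ]:
            if w != 1 and (w % 2 == 0 or w <= p):
                raise ConfigError(f"{nm}_window must be odd and > {nm}_polyorder (got {w})")
        if self.deriv_order != 2:
            raise ConfigError("deriv_order is fixed at 2")
        lo, hi = self.region
        if lo >= hi:
            raise ConfigError(f"region lower bound {lo} must be < upper bound {hi}")


def normalize(spectrum: Spectrum, kind: str = "unit-vector") -> Spectrum:
    """Scale a spectrum to unit Euclidean norm (or return it unchanged)."""
    if kind == "none":
        return spectrum
    nrm = np.linalg.norm(spectrum.absorbance)
    if nrm == 0:
        raise DegenerateInputError(f"sample {spectrum.sample_id!r}: all-zero spectrum")
    return Spectrum(spectrum.wavenumbers.copy(), spectrum.absorbance / nrm, spectrum.sample_id)


def _sg(values: np.ndarray, window: int, polyorder: int, deriv: int, delta: float) -> np.ndarray:
    if window == 1:
        if deriv:
            raise ConfigError("window=1 cannot estimate a derivative")
        return np.asarray(values, float).copy()
    if window % 2 == 0 or window <= polyorder:
        raise ConfigError(f"SG window must be odd and > polyorder (window={window}, polyorder={polyorder})")
    if np.asarray(values).shape[-1] < window:
        raise ConfigError(f"spectrum shorter than SG window {window}")
    # mode="interp": edge points come from the polynomial fitted to the
    # terminal window, keeping the output grid identical to the input grid.
    return savgol_filter(values, window, polyorder, deriv=deriv, delta=delta,
                         mode="interp", axis=-1)


def sg_filter(spectrum: Spectrum, window: int, polyorder: int, deriv_order: int = 0) -> Spectrum:
    """Savitzky-Golay filter on the spectrum's own grid.

    Derivatives are scaled by the grid step, so a second derivative is in
    absorbance per (cm^-1)^2.  The wavenumber axis direction does not affect
    even-order derivatives.
    """
    out = _sg(spectrum.absorbance, window, polyorder, deriv_order, spectrum.step)
    return Spectrum(spectrum.wavenumbers.copy(), out, spectrum.sample_id)


def select_region(obj, lo: float, hi: float):
    """Restrict a Spectrum or SpectralDataset to lo <= wavenumber <= hi."""
    if lo >= hi:
        raise ConfigError(f"region [{lo}, {hi}] is empty")
    mask = (obj.wavenumbers >= lo) & (obj.wavenumbers <= hi)
    if not np.any(mask):
        raise RegionError(f"region [{lo}, {hi}] does not overlap the grid")
    if isinstance(obj, Spectrum):
        return Spectrum(obj.wavenumbers[mask], obj.absorbance[mask], obj.sample_id)
    if isinstance(obj, SpectralDataset):
        return SpectralDataset(obj.wavenumbers[mask], obj.absorbance[:, mask],
                               list(obj.sample_ids), list(obj.labels))
    raise TypeError(f"cannot select a region of {type(obj).__name__}")


def mean_center(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center columns to zero mean; returns (centered, column_means)."""
    X = np.asarray(matrix, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DegenerateInputError("mean centering needs >= 2 samples")
    mu = X.mean(axis=0)
    return X - mu, mu


@dataclass
class FittedPipeline:
    """Preprocessing state fitted on a training set.

    ``matrix`` is the fully pretreated training matrix; ``transform`` applies
    the identical chain (with the stored training means) to new samples.
    """

    config: PreprocessConfig
    wavenumbers: np.ndarray  # region grid, descending
    matrix: np.ndarray
    column_means: np.ndarray
    _full_grid: np.ndarray = field(repr=False, default=None)

    def transform(self, dataset: SpectralDataset) -> np.ndarray:
        if dataset.wavenumbers.shape != self._full_grid.shape or not np.allclose(
            dataset.wavenumbers, self._full_grid
        ):
            raise RegionError("dataset grid does not match the fitted pipeline's grid")
        Z = _stateless_chain(dataset, self.config)
        return Z - self.column_means if self.config.mean_center else Z


def _stateless_chain(dataset: SpectralDataset, config: PreprocessConfig) -> np.ndarray:
    """Steps 1-4 of the chain (everything except centering), vectorized."""
    X = dataset.absorbance
    if config.norm == "unit-vector":
        nrm = np.linalg.norm(X, axis=1, keepdims=True)
        if np.any(nrm == 0):
            bad = dataset.sample_ids[int(np.argmin(nrm))]
            raise DegenerateInputError(f"sample {bad!r}: all-zero spectrum")
        X = X / nrm
    step = float(np.median(np.abs(np.diff(dataset.wavenumbers))))
    X = _sg(X, config.smooth_window, config.smooth_polyorder, 0, step)
    X = _sg(X, config.deriv_window, config.deriv_polyorder, config.deriv_order, step)
    lo, hi = config.region
    mask = (dataset.wavenumbers >= lo) & (dataset.wavenumbers <= hi)
    if not np.any(mask):
        raise RegionError(f"region [{lo}, {hi}] does not overlap the grid")
    return X[:, mask]


def preprocess_pipeline(dataset: SpectralDataset, config: PreprocessConfig) -> FittedPipeline:
    """Fit the pretreatment chain on a training set."""
    Z = _stateless_chain(dataset, config)
    if config.mean_center:
        Z, mu = mean_center(Z)
    else:
        mu = np.zeros(Z.shape[1])
    lo, hi = config.region
    mask = (dataset.wavenumbers >= lo) & (dataset.wavenumbers <= hi)
    return FittedPipeline(config, dataset.wavenumbers[mask], Z, mu, dataset.wavenumbers.copy())
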