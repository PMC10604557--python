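"""Spectra and dataset containers plus the delimited-text on-disk dialect.

A dataset is stored as a plain CSV whose header is
``sample_id,label,<wavenumber_1>,...`` with one spectrum per row.  Wavenumber
columns are written in descending order (the conventional mid-IR plotting
direction) with fixed ``%.10g`` formatting, so files round-trip through
read/write to float precision and diff cleanly.  Class labels are serialized
as their tokens (``FM``/``LC``/``HC``), never as numeric codes; the dummy
coding (HC=0, FM=1, LC=2) is applied at model time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DatasetFormatError, GridError, LabelError

#: dummy class coding used by the discriminant model (FM vs LC classifier
#: regresses onto 1/2; HC kept at 0 for completeness)
LABEL_CODES: dict[str, int] = {"HC": 0, "FM": 1, "LC": 2}

_MIN_POINTS = 7  # smallest Savitzky-Golay window used anywhere downstream


def _validate_grid(wavenumbers: np.ndarray) -> np.ndarray:
    wn = np.asarray(wavenumbers, dtype=float)
    if wn.ndim != 1 or wn.size < _MIN_POINTS:
        raise GridError(f"grid must be 1-D with >= {_MIN_POINTS} points, got shape {wn.shape}")
    if not np.all(np.isfinite(wn)):
        raise GridError("grid contains non-finite values")
    d = np.diff(wn)
    if np.all(d > 0):
        wn = wn[::-1]  # normalize to descending
    elif not np.all(d < 0):
        raise DatasetFormatError("wavenumber grid is not strictly monotone")
    return wn


@dataclass
class Spectrum:
    """A single absorbance spectrum on a strictly monotone wavenumber grid.

    The grid is stored descending regardless of input order.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        wn = _validate_grid(self.wavenumbers)
        ab = np.asarray(self.absorbance, dtype=float)
        if ab.shape != np.asarray(self.wavenumbers).shape:
            raise DatasetFormatError(
                f"sample {self.sample_id!r}: absorbance length {ab.size} != grid length"
            )
        if not np.all(np.isfinite(ab)):
            raise DatasetFormatError(f"sample {self.sample_id!r}: non-finite absorbance")
        if wn is not self.wavenumbers and np.any(np.diff(np.asarray(self.wavenumbers, float)) > 0):
            ab = ab[::-1]
        self.wavenumbers = wn
        self.absorbance = ab

    @property
    def step(self) -> float:
        """Median absolute grid spacing in cm^-1."""
        return float(np.median(np.abs(np.diff(self.wavenumbers))))


@dataclass
class SpectralDataset:
    """Labelled collection of spectra sharing one wavenumber grid.

    ``absorbance`` is an ``(n_samples, n_points)`` matrix aligned with the
    descending ``wavenumbers`` grid.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    labels: list[str]
    truth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.wavenumbers = _validate_grid(self.wavenumbers)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.size and self.absorbance.shape[1] != self.wavenumbers.size:
            raise GridError("absorbance matrix width does not match grid length")
        n = self.absorbance.shape[0] if self.absorbance.size else 0
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise DatasetFormatError("labels/sample_ids length does not match sample count")
        for lab in self.labels:
            if lab not in LABEL_CODES:
                raise LabelError(f"unknown class label {lab!r} (expected one of {sorted(LABEL_CODES)})")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def y(self) -> np.ndarray:
        """Numeric dummy coding of the labels (HC=0, FM=1, LC=2)."""
        return np.array([LABEL_CODES[lab] for lab in self.labels], dtype=float)

    def spectra(self) -> list[Spectrum]:
        return [
            Spectrum(self.wavenumbers.copy(), row.copy(), sid)
            for row, sid in zip(self.absorbance, self.sample_ids)
        ]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavenumbers.copy(), self.absorbance[i].copy(), self.sample_ids[i])

    def subset(self, indices) -> "SpectralDataset":
        idx = np.asarray(indices, dtype=int)
        return SpectralDataset(
            self.wavenumbers.copy(),
            self.absorbance[idx].copy(),
            [self.sample_ids[i] for i in idx],
            [self.labels[i] for i in idx],
        )

    def select_class(self, label: str) -> "SpectralDataset":
        idx = [i for i, lab in enumerate(self.labels) if lab == label]
        if not idx:
            raise LabelError(f"class {label!r} absent from dataset")
        return self.subset(idx)

    @classmethod
    def from_spectra(cls, spectra: list[Spectrum], labels: list[str]) -> "SpectralDataset":
        if not spectra:
            raise DatasetFormatError("cannot build a dataset from zero spectra")
        grid = spectra[0].wavenumbers
        for sp in spectra[1:]:
            if sp.wavenumbers.shape != grid.shape or not np.allclose(sp.wavenumbers, grid):
                raise GridError(f"sample {sp.sample_id!r} is not on the shared grid")
        return cls(
            grid.copy(),
            np.vstack([sp.absorbance for sp in spectra]),
            [sp.sample_id for sp in spectra],
            list(labels),
        )


def write_dataset(dataset: SpectralDataset, path) -> None:
    """Write a dataset to CSV with descending wavenumber columns.

    An empty dataset produces a header-only file.
    """
    cols = ["sample_id", "label"] + [f"{w:.10g}" for w in dataset.wavenumbers]
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for sid, lab, row in zip(dataset.sample_ids, dataset.labels, dataset.absorbance):
            fh.write(sid + "," + lab + "," + ",".join(f"{v:.10g}" for v in row) + "\n")


def read_dataset(path) -> SpectralDataset:
    """Read a dataset CSV; grid order is normalized to descending.

    Raises :class:`DatasetFormatError` naming the offending row for ragged or
    non-numeric rows and :class:`LabelError` for unknown label tokens.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # ragged row etc.
        raise DatasetFormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 2 or list(df.columns[:2]) != ["sample_id", "label"]:
        raise DatasetFormatError(f"{path}: header must start with 'sample_id,label'")
    try:
        grid = np.array([float(c) for c in df.columns[2:]])
    except ValueError as exc:
        raise DatasetFormatError(f"{path}: non-numeric wavenumber column header: {exc}") from exc
    _validate_grid(grid)
    rows = []
    for i, (_, rec) in enumerate(df.iterrows()):
        sid = rec.iloc[0]
        vals = rec.iloc[2:].to_numpy()
        try:
            row = vals.astype(float)
        except ValueError as exc:
            raise DatasetFormatError(f"row for sample {sid!r}: non-numeric cell ({exc})") from exc
        if not np.all(np.isfinite(row)):
            raise DatasetFormatError(f"row for sample {sid!r}: missing or non-finite cell")
        rows.append(row)
    mat = np.vstack(rows) if rows else np.empty((0, grid.size))
    if grid.size > 1 and grid[0] < grid[-1]:  # stored ascending: flip to descending
        grid = grid[::-1]
        mat = mat[:, ::-1]
    return SpectralDataset(grid, mat, list(df["sample_id"]), list(df["label"]))
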