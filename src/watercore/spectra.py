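"""Core spectral containers and plain-text I/O.

A :class:`WavelengthGrid` fixes the abscissa (default 350--1050 nm at 1 nm,
701 points, matching the spectrometer's stated range).  A :class:`Spectrum`
is one transmitted-intensity vector on a grid; a :class:`SpectraSet` is a
sample x wavelength matrix with optional grade labels (1--4) and optional
ground-truth watercore volume fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_WL_MIN = 350.0
DEFAULT_WL_MAX = 1050.0
DEFAULT_N_BANDS = 701


class SpectraError(ValueError):
    """Invalid spectral container contents."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength abscissa in nm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise SpectraError("wavelength grid must be a 1-D array with >= 2 points")
        if not np.all(np.diff(vals) > 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if vals[0] < 300.0 or vals[-1] > 1100.0:
            raise SpectraError(
                f"wavelengths must lie within [300, 1100] nm, got "
                f"[{vals[0]:g}, {vals[-1]:g}]"
            )

    @classmethod
    def default(cls) -> "WavelengthGrid":
        return cls(np.linspace(DEFAULT_WL_MIN, DEFAULT_WL_MAX, DEFAULT_N_BANDS))

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.shape, self.values.tobytes()))


@dataclass
class Spectrum:
    """A single transmission spectrum on a wavelength grid."""

    grid: WavelengthGrid
    intensity: np.ndarray
    sample_id: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1 or self.intensity.size != len(self.grid):
            raise SpectraError(
                f"intensity length {self.intensity.size} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise SpectraError("intensity must be finite")


@dataclass
class SpectraSet:
    """n x P spectral matrix with optional labels and true watercore ratios."""

    grid: WavelengthGrid
    X: np.ndarray
    labels: np.ndarray | None = None
    true_ratio: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.grid):
            raise SpectraError(
                f"X must be n x {len(self.grid)}, got shape {self.X.shape}"
            )
        n = self.X.shape[0]
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise SpectraError("labels length mismatch")
            if not np.all(np.isin(self.labels, [1, 2, 3, 4])):
                raise SpectraError("labels must be in {1,2,3,4}")
        if self.true_ratio is not None:
            self.true_ratio = np.asarray(self.true_ratio, dtype=float)
            if self.true_ratio.shape != (n,):
                raise SpectraError("true_ratio length mismatch")
            if np.any((self.true_ratio < 0) | (self.true_ratio >= 1)):
                raise SpectraError("true_ratio must lie in [0, 1)")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(n)]
        elif len(self.sample_ids) != n:
            raise SpectraError("sample_ids length mismatch")

    def __len__(self) -> int:
        return int(self.X.shape[0])

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.X[i], sample_id=self.sample_ids[i])

    def subset(self, idx: np.ndarray) -> "SpectraSet":
        idx = np.asarray(idx, dtype=int)
        return SpectraSet(
            grid=self.grid,
            X=self.X[idx].copy(),
            labels=None if self.labels is None else self.labels[idx].copy(),
            true_ratio=None if self.true_ratio is None else self.true_ratio[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
        )


def write_csv(sset: SpectraSet, spectra_path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write spectra (first row = wavelengths) and a companion metadata CSV."""
    spectra_path = Path(spectra_path)
    header = ",".join(f"{w:.6g}" for w in sset.grid.values)
    with open(spectra_path, "w") as fh:
        fh.write(header + "\n")
        for row in sset.X:
            fh.write(",".join(f"{v:.10g}" for v in row) + "\n")
    if meta_path is not None:
        meta = pd.DataFrame({"sample_id": sset.sample_ids})
        meta["label"] = sset.labels if sset.labels is not None else ""
        meta["true_ratio"] = sset.true_ratio if sset.true_ratio is not None else ""
        meta.to_csv(meta_path, index=False)


def read_csv(spectra_path: str | Path, meta_path: str | Path | None = None) -> SpectraSet:
    """Read a spectra CSV (first row = wavelengths) and optional metadata CSV."""
    arr = np.loadtxt(spectra_path, delimiter=",", ndmin=2)
    grid = WavelengthGrid(arr[0])
    X = arr[1:]
    labels = true_ratio = None
    sample_ids: list[str] = []
    if meta_path is not None:
        meta = pd.read_csv(meta_path)
        sample_ids = [str(s) for s in meta["sample_id"]]
        if "label" in meta and meta["label"].notna().all():
            labels = meta["label"].to_numpy(dtype=int)
        if "true_ratio" in meta and meta["true_ratio"].notna().all():
            true_ratio = meta["true_ratio"].to_numpy(dtype=float)
    return SpectraSet(grid=grid, X=X, labels=labels, true_ratio=true_ratio, sample_ids=sample_ids)
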