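"""Chemometric preprocessing operators and length resampling.

All standard deviations use the sample (n-1) convention.  The fitted
operators (MSC reference, standardization parameters) persist their state so
the transform learned on a calibration set is applied unchanged to held-out
data; both round-trip through plain JSON dicts.
"""

from __future__ import annotations

import numpy as np

from watercore.spectra import SpectraSet, Spectrum


class DegenerateInputError(ValueError):
    """Input has no variance where the operator needs some."""


# ---------------------------------------------------------------------------
# per-spectrum operators
# ---------------------------------------------------------------------------

def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: centre and scale each spectrum to sd 1."""
    x = s.intensity
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("SNV undefined for a constant spectrum")
    return Spectrum(s.grid, (x - x.mean()) / sd, sample_id=s.sample_id, replicate=s.replicate)


def minmax(s: Spectrum) -> Spectrum:
    """Max-min normalization onto [0, 1]."""
    x = s.intensity
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateInputError("min-max undefined for a constant spectrum")
    return Spectrum(s.grid, (x - lo) / (hi - lo), sample_id=s.sample_id, replicate=s.replicate)


def snv_matrix(X: np.ndarray) -> np.ndarray:
    """Row-wise SNV on an n x P matrix."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateInputError("SNV undefined for constant rows")
    return (X - X.mean(axis=1, keepdims=True)) / sd


def minmax_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    if np.any(hi == lo):
        raise DegenerateInputError("min-max undefined for constant rows")
    return (X - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# fitted set-level operators
# ---------------------------------------------------------------------------

class MSCModel:
    """Multiplicative scatter correction against a fitted mean reference.

    Each spectrum x is regressed on the reference by ordinary least squares,
    x ~ a*ref + b, and replaced by (x - b) / a.
    """

    def __init__(self, reference: np.ndarray | None = None):
        self.reference = None if reference is None else np.asarray(reference, dtype=float)

    def fit(self, X: np.ndarray) -> "MSCModel":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 1:
            raise DegenerateInputError("MSC needs at least one spectrum")
        self.reference = X.mean(axis=0)
        if self.reference.std(ddof=1) == 0:
            raise DegenerateInputError("MSC reference spectrum has zero variance")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.reference is None:
            raise RuntimeError("MSCModel must be fitted before transform")
        X = np.asarray(X, dtype=float)
        ref = self.reference
        ref_c = ref - ref.mean()
        denom = float(ref_c @ ref_c)
        a = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
        b = X.mean(axis=1) - a * ref.mean()
        return (X - b[:, None]) / a[:, None]

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_dict(self) -> dict:
        return {"reference": self.reference.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "MSCModel":
        return cls(reference=np.asarray(d["reference"]))


def msc(sset: SpectraSet) -> SpectraSet:
    """MSC with the set's own mean as reference; single spectra pass through."""
    if len(sset) == 1:
        return sset
    corrected = MSCModel().fit_transform(sset.X)
    return SpectraSet(
        grid=sset.grid, X=corrected, labels=sset.labels,
        true_ratio=sset.true_ratio, sample_ids=list(sset.sample_ids),
    )


class Standardizer:
    """Per-wavelength column standardization, fitted once, reusable."""

    def __init__(self, mean: np.ndarray | None = None, sd: np.ndarray | None = None):
        self.mean = None if mean is None else np.asarray(mean, dtype=float)
        self.sd = None if sd is None else np.asarray(sd, dtype=float)

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise DegenerateInputError("standardization needs >= 2 spectra")
        sd = X.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise DegenerateInputError(
                f"zero-variance wavelength column(s): {bad[:5].tolist()}"
            )
        self.mean = X.mean(axis=0)
        self.sd = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("Standardizer must be fitted before transform")
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(mean=np.asarray(d["mean"]), sd=np.asarray(d["sd"]))


def standardize(sset: SpectraSet) -> tuple[SpectraSet, Standardizer]:
    """Column-standardize a set; returns the transformed set and fitted params."""
    model = Standardizer()
    Z = model.fit_transform(sset.X)
    out = SpectraSet(
        grid=sset.grid, X=Z, labels=sset.labels,
        true_ratio=sset.true_ratio, sample_ids=list(sset.sample_ids),
    )
    return out, model


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_to_length(x: np.ndarray, length: int) -> np.ndarray:
    """Linearly interpolate a vector onto ``length`` evenly spaced points.

    Endpoints are preserved; ``length == len(x)`` is the identity.
    """
    x = np.asarray(x, dtype=float)
    if length < 2:
        raise ValueError("target length must be >= 2")
    if length == x.size:
        return x.copy()
    old = np.linspace(0.0, 1.0, x.size)
    new = np.linspace(0.0, 1.0, length)
    return np.interp(new, old, x)


def resample_matrix(X: np.ndarray, length: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if length == X.shape[1]:
        return X.copy()
    return np.stack([resample_to_length(row, length) for row in X])


METHODS = ("none", "minmax", "snv", "msc", "standardize")


def apply_method(
    X: np.ndarray, method: str, fitted: dict | None = None
) -> tuple[np.ndarray, dict | None]:
    """Dispatch a named preprocessing method on a matrix.

    Returns the transformed matrix and, for fitted methods, a JSON-ready dict
    of the fitted parameters (pass it back in to reuse on held-out data).
    """
    if method == "none":
        return np.asarray(X, dtype=float).copy(), None
    if method == "minmax":
        return minmax_matrix(X), None
    if method == "snv":
        return snv_matrix(X), None
    if method == "msc":
        model = MSCModel.from_dict(fitted) if fitted else MSCModel().fit(X)
        return model.transform(X), model.to_dict()
    if method == "standardize":
        model = Standardizer.from_dict(fitted) if fitted else Standardizer().fit(X)
        return model.transform(X), model.to_dict()
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
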