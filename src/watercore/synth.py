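"""Synthetic labelled Vis/NIR transmission spectra.

The generator does not model tissue optics; it only reproduces the
statistical structure a watercore classifier sees: a smooth broadband
transmission envelope, water-absorption bands near 760 and 970 nm whose
depth grows monotonically with the watercore volume fraction, plus
multiplicative/additive scatter and per-band sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from watercore.spectra import SpectraSet, Spectrum, WavelengthGrid
from watercore.volume3d import NORMAL_EPSILON, grade_from_ratio

#: per-grade ratio sampling intervals (level 1 is exactly 0)
GRADE_RATIO_RANGES = {
    2: (NORMAL_EPSILON, 0.03),
    3: (0.03, 0.06),
    4: (0.06, 0.12),
}

# water absorption band centres (nm) and Gaussian widths
_BAND_CENTRES = (760.0, 970.0)
_BAND_WIDTHS = (20.0, 35.0)
_BAND_WEIGHTS = (0.35, 1.0)  # 970 nm overtone dominates


class GeneratorError(ValueError):
    """Invalid generator configuration or argument."""


@dataclass
class GeneratorConfig:
    n_per_class: int = 200
    noise_sd: float = 0.01
    scatter_mult_sd: float = 0.05
    scatter_add_sd: float = 0.01
    absorption_gain: float = 8.0
    level4_ratio_cap: float = 0.12
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise GeneratorError("n_per_class must be >= 1")
        for name in ("noise_sd", "scatter_mult_sd", "scatter_add_sd", "absorption_gain"):
            if getattr(self, name) < 0:
                raise GeneratorError(f"{name} must be >= 0")
        if not (0.06 < self.level4_ratio_cap < 1.0):
            raise GeneratorError("level4_ratio_cap must lie in (0.06, 1)")
        if self.n_replicates < 1:
            raise GeneratorError("n_replicates must be >= 1")


def template_spectrum(
    ratio: float,
    grid: WavelengthGrid | None = None,
    absorption_gain: float = 8.0,
) -> Spectrum:
    """Deterministic noise-free spectrum for a given watercore fraction.

    Beer-Lambert-style model: a broadband envelope attenuated by a baseline
    absorbance plus water bands whose absorbance scales linearly with
    ``ratio`` - so transmitted intensity at the band centres decreases
    strictly monotonically with ratio.
    """
    if not (0.0 <= ratio < 1.0):
        raise GeneratorError(f"ratio must lie in [0, 1), got {ratio}")
    if grid is None:
        grid = WavelengthGrid.default()
    wl = grid.values
    envelope = 0.15 + np.exp(-(((wl - 700.0) / 220.0) ** 2))
    bands = sum(
        w * np.exp(-(((wl - c) / s) ** 2))
        for c, s, w in zip(_BAND_CENTRES, _BAND_WIDTHS, _BAND_WEIGHTS)
    )
    absorbance = 0.05 * bands + absorption_gain * ratio * bands
    intensity = envelope * np.exp(-absorbance)
    return Spectrum(grid=grid, intensity=intensity)


def sample_ratio(level: int, rng: np.random.Generator, cap: float = 0.12) -> float:
    """Draw a watercore fraction consistent with a grade level."""
    if level == 1:
        return 0.0
    if level not in GRADE_RATIO_RANGES:
        raise GeneratorError(f"level must be in 1..4, got {level}")
    lo, hi = GRADE_RATIO_RANGES[level]
    if level == 4:
        hi = cap
    return float(rng.uniform(lo, hi))


def generate_dataset(cfg: GeneratorConfig, grid: WavelengthGrid | None = None) -> SpectraSet:
    """Generate ``4 * n_per_class`` labelled spectra, grades 1-4.

    Each sample: draw a ratio inside the grade's interval, evaluate the
    noise-free template, then apply a multiplicative scatter factor, an
    additive baseline shift and per-band relative noise; with
    ``n_replicates > 1`` the noisy acquisitions are averaged.
    """
    if grid is None:
        grid = WavelengthGrid.default()
    rng = np.random.default_rng(cfg.seed)
    P = len(grid)
    n_total = 4 * cfg.n_per_class
    X = np.empty((n_total, P))
    labels = np.empty(n_total, dtype=int)
    ratios = np.empty(n_total)

    row = 0
    for level in (1, 2, 3, 4):
        for _ in range(cfg.n_per_class):
            ratio = sample_ratio(level, rng, cap=cfg.level4_ratio_cap)
            clean = template_spectrum(ratio, grid, cfg.absorption_gain).intensity
            reps = np.empty((cfg.n_replicates, P))
            for r in range(cfg.n_replicates):
                mult = 1.0 + rng.normal(0.0, cfg.scatter_mult_sd)
                add = rng.normal(0.0, cfg.scatter_add_sd)
                noise = rng.normal(0.0, cfg.noise_sd, size=P)
                reps[r] = clean * mult * (1.0 + noise) + add
            X[row] = np.maximum(reps.mean(axis=0), 0.0)
            labels[row] = level
            ratios[row] = ratio
            row += 1

    assert all(grade_from_ratio(r) == lv for r, lv in zip(ratios, labels))
    return SpectraSet(grid=grid, X=X, labels=labels, true_ratio=ratios)
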