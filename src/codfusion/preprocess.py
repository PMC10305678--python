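"""EEM scatter removal, cubic-spline upsampling, and absorption augmentation.

Scatter ridges (first/second-order Rayleigh, Raman) are located from a
deionized-water blank, masked, and filled by Delaunay-triangulation
barycentric-linear interpolation in the (excitation, emission) wavelength
plane.  Raw 32x9 EEMs are expanded to a fine square grid (default
2217x2217) by separable cubic splines.  The absorption dataset is densified
to a 0.01 mg/L COD-label grid by per-wavelength cubic splines across labels,
anchored at the blank, and split into train/test by uniform sampling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import (CubicSpline, LinearNDInterpolator, interp1d,
                               make_interp_spline)

from .chem import fill_count, label_grid
from .synth import EEM, AbsorptionSpectrum

log = logging.getLogger(__name__)

UPSAMPLED_SIDE = 2217


@dataclass(frozen=True)
class ScatterBands:
    """Per-order scatter band: line em = order*ex, perpendicular half-width (nm)."""

    half_width_1: float = 0.0
    half_width_2: float = 0.0

    def __post_init__(self) -> None:
        if self.half_width_1 < 0 or self.half_width_2 < 0:
            raise ValueError("half-widths must be non-negative")

    def half_width(self, order: int) -> float:
        return {1: self.half_width_1, 2: self.half_width_2}[order]


@dataclass
class AugmentedDataset:
    """Label-sorted spectra on the augmentation grid; knot flags mark measured rows."""

    spectra: list[AbsorptionSpectrum]
    step: float
    knot_flags: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.cod_label for s in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)


def _perp_distance(ex: np.ndarray, em: np.ndarray, order: int) -> np.ndarray:
    """Perpendicular distance (nm) from (ex, em) points to the line em = order*ex."""
    return np.abs(em - order * ex) / np.sqrt(1.0 + order * order)


def detect_scatter_bands(blank: EEM, k: float = 3.0) -> ScatterBands:
    """Locate Rayleigh scatter bands from a deionized-water blank.

    Cells brighter than mean + k*sd of the blank are assigned to the nearest
    order line (minimum perpendicular distance); each order's half-width is
    the maximum perpendicular extent of its assigned cells.  A flat blank
    yields empty bands.
    """
    z = blank.intensity
    thresh = z.mean() + k * z.std()
    exg, emg = np.meshgrid(blank.ex_wavelengths, blank.em_wavelengths)
    hot = z > thresh
    if not hot.any():
        return ScatterBands(0.0, 0.0)
    d1 = _perp_distance(exg, emg, 1)
    d2 = _perp_distance(exg, emg, 2)
    widths = {1: 0.0, 2: 0.0}
    order1 = d1 <= d2
    for order, sel in ((1, order1), (2, ~order1)):
        cells = hot & sel
        if cells.any():
            d = _perp_distance(exg[cells], emg[cells], order)
            widths[order] = float(d.max())
    return ScatterBands(widths[1], widths[2])


def scatter_mask(eem: EEM, bands: ScatterBands) -> np.ndarray:
    """Boolean mask of cells lying within any scatter band."""
    exg, emg = np.meshgrid(eem.ex_wavelengths, eem.em_wavelengths)
    mask = np.zeros(eem.intensity.shape, dtype=bool)
    for order in (1, 2):
        hw = bands.half_width(order)
        if hw > 0:
            mask |= _perp_distance(exg, emg, order) <= hw
    return mask


def remove_scatter(eem: EEM, bands: ScatterBands) -> EEM:
    """Mask scatter-band cells and fill them by Delaunay-linear interpolation.

    Unmasked cells pass through bit-exactly; masked cells outside the convex
    hull of the unmasked points are set to 0.  Idempotent for fixed bands.
    """
    mask = scatter_mask(eem, bands)
    if not mask.any():
        return eem
    keep = ~mask
    if keep.sum() < 3:
        raise ValueError("fewer than 3 unmasked cells; cannot interpolate")
    exg, emg = np.meshgrid(eem.ex_wavelengths, eem.em_wavelengths)
    pts = np.column_stack([exg[keep], emg[keep]])
    interp = LinearNDInterpolator(pts, eem.intensity[keep], fill_value=0.0)
    z = eem.intensity.copy()
    z[mask] = interp(exg[mask], emg[mask])
    return EEM(eem.ex_wavelengths, eem.em_wavelengths, z)


def upsample_eem(eem: EEM, out_side: int = UPSAMPLED_SIDE) -> EEM:
    """Separable cubic-spline upsampling onto uniform out_side x out_side grids.

    Emission axis first, then excitation; grids span the raw wavelength
    ranges, knots are reproduced, negative interpolants are clipped to 0
    (clipping is logged).  An axis with fewer than 4 points falls back to
    linear interpolation with a warning.
    """
    em_fine = np.linspace(eem.em_wavelengths[0], eem.em_wavelengths[-1], out_side)
    ex_fine = np.linspace(eem.ex_wavelengths[0], eem.ex_wavelengths[-1], out_side)

    def _interp(grid: np.ndarray, values: np.ndarray, fine: np.ndarray, axis: int) -> np.ndarray:
        if grid.size >= 4:
            return CubicSpline(grid, values, axis=axis)(fine)
        log.warning("axis with %d points: falling back to linear interpolation", grid.size)
        return interp1d(grid, values, axis=axis, kind="linear")(fine)

    z = _interp(eem.em_wavelengths, eem.intensity, em_fine, axis=0)
    z = _interp(eem.ex_wavelengths, z, ex_fine, axis=1)
    n_neg = int((z < 0).sum())
    if n_neg:
        log.info("clipped %d negative interpolants to 0", n_neg)
        z = np.clip(z, 0.0, None)
    return EEM(ex_fine, em_fine, z)


def augment_absorption(
    measured: list[AbsorptionSpectrum], step: float = 0.01
) -> AugmentedDataset:
    """Densify the absorption dataset to a COD-label grid of the given spacing.

    For each wavelength channel a cubic spline of absorbance versus COD label
    is fit through all measured spectra (the label-0 blank included) and
    evaluated on ``label_grid(max label, step)`` — the half-open grid
    (0, max]; measured spectra are re-inserted bit-exactly at the nearest
    grid label.  Total count equals ``fill_count(0, max label, step)``.
    """
    if len(measured) < 2:
        raise ValueError("need at least 2 measured spectra")
    order = np.argsort([s.cod_label for s in measured])
    measured = [measured[i] for i in order]
    labels = np.array([s.cod_label for s in measured])
    if np.any(np.diff(labels) <= 0):
        raise ValueError("duplicate COD labels among measured spectra")
    if labels[0] != 0.0:
        raise ValueError("augmentation requires the blank (label 0) as anchor")
    wl = measured[0].wavelengths
    y = np.stack([s.absorbance for s in measured])       # (n_measured, n_wl)
    grid = label_grid(float(labels[-1]), step)
    k = min(3, len(measured) - 1)   # spline order degrades below 4 knots
    spline = make_interp_spline(labels, y, k=k, axis=0)
    dense = spline(grid)
    knot_flags = np.zeros(grid.size, dtype=bool)
    spectra: list[AbsorptionSpectrum] = [None] * grid.size
    # re-insert measured knots bit-exactly at the nearest grid label
    for s in measured[1:]:
        idx = int(np.argmin(np.abs(grid - s.cod_label)))
        knot_flags[idx] = True
        spectra[idx] = AbsorptionSpectrum(wl, s.absorbance, s.cod_label, s.provenance)
    for i, lab in enumerate(grid):
        if spectra[i] is None:
            spectra[i] = AbsorptionSpectrum(wl, dense[i], float(lab), "interpolated")
    n_expected = fill_count(0.0, float(labels[-1]), step)
    assert len(spectra) == n_expected
    return AugmentedDataset(spectra=spectra, step=step, knot_flags=knot_flags)


def split_test(
    dataset: AugmentedDataset, n: int = 1000, seed: int = 0
) -> tuple[list[AbsorptionSpectrum], list[AbsorptionSpectrum]]:
    """Uniform test split without replacement; returns (train, test)."""
    size = len(dataset)
    if n >= size:
        raise ValueError(f"test size {n} must be smaller than dataset size {size}")
    rng = np.random.default_rng(seed)
    test_idx = np.sort(rng.choice(size, size=n, replace=False))
    test_set = set(test_idx.tolist())
    train = [s for i, s in enumerate(dataset.spectra) if i not in test_set]
    test = [dataset.spectra[i] for i in test_idx]
    return train, test
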