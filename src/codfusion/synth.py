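"""Synthetic absorption spectra and fluorescence EEMs for the amino-acid system.

Generates data with the statistical structure the retrieval method assumes:

* absorption — Beer–Lambert additive Gaussian bands per compound on the
  200–700 nm grid (2559 points, 1 cm path), plus optional Gaussian noise;
* fluorescence — excitation–emission matrices (EEMs) built from separable
  Gaussian fluorophore peaks, optionally distorted by the inner filter
  effect (IFE) and contaminated with first/second-order Rayleigh ridges and
  a water Raman band, plus noise.

Every generator is a pure function of its inputs and seed.  Default
photophysics approximates literature UV bands and fluorescence peaks of
phenylalanine, tyrosine and tryptophan; all values are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import MixtureSpec, measured_coefficients, mixture_cod

N_ABS_POINTS = 2559
ABS_RANGE_NM = (200.0, 700.0)
N_EX_RAW = 9
N_EM_RAW = 32
EX_RANGE_NM = (255.0, 380.0)   # LED excitation array span
EM_RANGE_NM = (200.0, 700.0)
RAMAN_SHIFT_CM = 3400.0        # water OH stretch


def absorption_grid() -> np.ndarray:
    return np.linspace(*ABS_RANGE_NM, N_ABS_POINTS)


def raw_ex_grid(n: int = N_EX_RAW, rng_nm: tuple[float, float] = EX_RANGE_NM) -> np.ndarray:
    return np.linspace(rng_nm[0], rng_nm[1], n)


def raw_em_grid(n: int = N_EM_RAW, rng_nm: tuple[float, float] = EM_RANGE_NM) -> np.ndarray:
    return np.linspace(rng_nm[0], rng_nm[1], n)


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """A 2559-point absorbance vector with its COD label."""

    wavelengths: np.ndarray      # nm, strictly increasing
    absorbance: np.ndarray       # AU
    cod_label: float             # mg/L
    provenance: str = "synthetic"  # measured | interpolated | synthetic

    def __post_init__(self) -> None:
        if self.wavelengths.ndim != 1 or self.absorbance.shape != self.wavelengths.shape:
            raise ValueError("wavelengths and absorbance must be matching 1-D arrays")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")
        if self.cod_label < 0:
            raise ValueError("cod_label must be non-negative")


@dataclass(frozen=True)
class EEM:
    """Excitation–emission matrix; intensity rows = emission, cols = excitation."""

    ex_wavelengths: np.ndarray
    em_wavelengths: np.ndarray
    intensity: np.ndarray        # shape (n_em, n_ex)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.ex_wavelengths) <= 0) or np.any(np.diff(self.em_wavelengths) <= 0):
            raise ValueError("wavelength grids must be strictly increasing")
        if self.intensity.shape != (self.em_wavelengths.size, self.ex_wavelengths.size):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match grids "
                f"({self.em_wavelengths.size}, {self.ex_wavelengths.size})"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")


@dataclass(frozen=True)
class Band:
    center_nm: float
    width_nm: float              # Gaussian sigma
    peak: float                  # specific absorbance, L mg^-1 cm^-1

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("band width must be positive")
        if self.peak < 0:
            raise ValueError("band peak must be non-negative")


@dataclass(frozen=True)
class Fluorophore:
    ex_center_nm: float
    ex_width_nm: float
    em_center_nm: float
    em_width_nm: float
    yield_scale: float           # a.u. per mg/L at band centers

    def __post_init__(self) -> None:
        if self.ex_width_nm <= 0 or self.em_width_nm <= 0:
            raise ValueError("fluorophore widths must be positive")
        if self.em_center_nm < self.ex_center_nm:
            raise ValueError("Stokes shift violated: em center < ex center")


@dataclass(frozen=True)
class PhotophysicsSpec:
    """Per-compound absorption bands and a single fluorophore."""

    absorption: Mapping[str, tuple[Band, ...]]
    fluorophores: Mapping[str, Fluorophore]


@dataclass(frozen=True)
class NoiseSpec:
    gaussian_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be non-negative")


@dataclass(frozen=True)
class ScatterSpec:
    """Amplitudes and perpendicular half-widths (sigma) of the scatter ridges."""

    rayleigh1_amp: float = 200.0
    rayleigh2_amp: float = 60.0
    raman_amp: float = 30.0
    width_nm: float = 10.0


def default_photophysics() -> PhotophysicsSpec:
    """Literature-typical aromatic amino-acid UV bands and fluorescence peaks.

    Peak specific absorbances are molar absorptivities divided by molecular
    mass (e.g. tryptophan 280 nm, ~5600 M^-1 cm^-1 / 204 g/mol); far-UV bands
    are included so that inner-filter attenuation at short excitation
    wavelengths is realistic.
    """
    absorption = {
        "phenylalanine": (
            Band(206.0, 5.0, 0.057),   # ~9400 M^-1 cm^-1
            Band(257.0, 6.0, 0.0012),  # ~200
        ),
        "tyrosine": (
            Band(222.0, 6.0, 0.044),   # ~8000
            Band(274.0, 7.0, 0.0077),  # ~1400
        ),
        "tryptophan": (
            Band(219.0, 7.0, 0.17),    # ~35000
            Band(280.0, 9.0, 0.027),   # ~5600
        ),
    }
    fluorophores = {
        "phenylalanine": Fluorophore(258.0, 8.0, 282.0, 10.0, 2.0),
        "tyrosine": Fluorophore(275.0, 9.0, 303.0, 12.0, 20.0),
        "tryptophan": Fluorophore(280.0, 10.0, 350.0, 28.0, 60.0),
    }
    return PhotophysicsSpec(absorption=absorption, fluorophores=fluorophores)


def _gauss(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _clean_absorbance(mixture: MixtureSpec, photo: PhotophysicsSpec,
                      wavelengths: np.ndarray) -> np.ndarray:
    a = np.zeros_like(wavelengths)
    for name, conc in mixture.components:
        if name not in photo.absorption:
            raise KeyError(f"no photophysics entry for compound {name!r}")
        for band in photo.absorption[name]:
            a += conc * band.peak * _gauss(wavelengths, band.center_nm, band.width_nm)
    return a


def simulate_absorption(
    mixture: MixtureSpec,
    photo: PhotophysicsSpec | None = None,
    noise: NoiseSpec = NoiseSpec(),
    cod_label: float | None = None,
) -> AbsorptionSpectrum:
    """Beer–Lambert additive absorbance over a 1 cm path, plus Gaussian noise.

    The noiseless output is exactly additive over mixture components; the
    label defaults to the mixture COD under the shipped measured coefficients.
    """
    photo = photo if photo is not None else default_photophysics()
    wl = absorption_grid()
    a = _clean_absorbance(mixture, photo, wl)
    if noise.gaussian_sd > 0:
        rng = np.random.default_rng(noise.seed)
        a = a + rng.normal(0.0, noise.gaussian_sd, size=a.shape)
    if cod_label is None:
        cod_label = mixture_cod(mixture, measured_coefficients()) if mixture.components else 0.0
    return AbsorptionSpectrum(wl, a, cod_label, provenance="synthetic")


def _scatter_field(ex: np.ndarray, em: np.ndarray, spec: ScatterSpec) -> np.ndarray:
    exg, emg = np.meshgrid(ex, em)          # (n_em, n_ex)
    out = np.zeros_like(exg)
    for order, amp in ((1, spec.rayleigh1_amp), (2, spec.rayleigh2_amp)):
        d_perp = np.abs(emg - order * exg) / np.sqrt(1.0 + order * order)
        out += amp * np.exp(-0.5 * (d_perp / spec.width_nm) ** 2)
    # Raman band: fixed wavenumber shift from the excitation line
    em_raman = 1.0 / (1.0 / exg - RAMAN_SHIFT_CM * 1e-7)   # nm
    out += spec.raman_amp * np.exp(-0.5 * ((emg - em_raman) / spec.width_nm) ** 2)
    return out


def simulate_eem(
    mixture: MixtureSpec,
    photo: PhotophysicsSpec | None = None,
    ife: bool = False,
    scatter: bool = False,
    noise: NoiseSpec = NoiseSpec(),
    scatter_spec: ScatterSpec = ScatterSpec(),
    ex_grid: np.ndarray | None = None,
    em_grid: np.ndarray | None = None,
) -> EEM:
    """Raw-grid EEM of a mixture.

    F(ex, em) = sum_i c_i * yield_i * G_i(ex) * G_i(em); with ``ife`` the
    field is attenuated by 10^(-(A(ex)+A(em))/2) using the mixture's own
    synthetic absorbance (primary + secondary inner-filter effect); with
    ``scatter`` Rayleigh/Raman ridges are added; noise is added last.
    """
    photo = photo if photo is not None else default_photophysics()
    ex = ex_grid if ex_grid is not None else raw_ex_grid()
    em = em_grid if em_grid is not None else raw_em_grid()
    exg, emg = np.meshgrid(ex, em)
    f = np.zeros_like(exg)
    for name, conc in mixture.components:
        if name not in photo.fluorophores:
            raise KeyError(f"no photophysics entry for compound {name!r}")
        fl = photo.fluorophores[name]
        f += (conc * fl.yield_scale
              * _gauss(exg, fl.ex_center_nm, fl.ex_width_nm)
              * _gauss(emg, fl.em_center_nm, fl.em_width_nm))
    if ife and mixture.components:
        wl = absorption_grid()
        a = _clean_absorbance(mixture, photo, wl)
        a_ex = np.interp(ex, wl, a)
        a_em = np.interp(em, wl, a)
        f = f * 10.0 ** (-(a_ex[None, :] + a_em[:, None]) / 2.0)
    if scatter:
        f = f + _scatter_field(ex, em, scatter_spec)
    if noise.gaussian_sd > 0:
        rng = np.random.default_rng(noise.seed)
        f = f + rng.normal(0.0, noise.gaussian_sd, size=f.shape)
    return EEM(ex, em, f)


def simulate_blank(
    scatter: bool = True,
    noise: NoiseSpec = NoiseSpec(),
    scatter_spec: ScatterSpec = ScatterSpec(),
    ex_grid: np.ndarray | None = None,
    em_grid: np.ndarray | None = None,
) -> EEM:
    """Deionized-water EEM: scatter ridges and noise only, no fluorophores."""
    return simulate_eem(MixtureSpec(), ife=False, scatter=scatter, noise=noise,
                        scatter_spec=scatter_spec, ex_grid=ex_grid, em_grid=em_grid)


def generate_design_dataset(
    design: Sequence[MixtureSpec],
    photo: PhotophysicsSpec | None = None,
    noise_abs: NoiseSpec = NoiseSpec(),
    noise_eem: NoiseSpec = NoiseSpec(),
    ife: bool = True,
    scatter: bool = True,
    coefficients: Mapping[str, float] | None = None,
) -> tuple[list[AbsorptionSpectrum], list[EEM], pd.DataFrame]:
    """One absorption spectrum + one EEM per design mixture, sorted by label.

    Returns (spectra, eems, manifest); the manifest records compositions,
    labels and per-row seeds (derived from the NoiseSpec seeds by row index).
    Duplicate labels are kept with a warning, tie broken by row order.
    """
    if not design:
        raise ValueError("design must be non-empty")
    coefficients = coefficients if coefficients is not None else measured_coefficients()
    rows, spectra, eems = [], [], []
    labelled = sorted(
        enumerate(design),
        key=lambda t: (mixture_cod(t[1], coefficients), t[0]),
    )
    labels = [mixture_cod(m, coefficients) for _, m in labelled]
    if len(set(np.round(labels, 9))) != len(labels):
        import warnings

        warnings.warn("duplicate COD labels in design; tie broken by row order")
    compound_names = sorted({n for m in design for n, _ in m.components})
    for out_idx, (orig_idx, mixture) in enumerate(labelled):
        label = labels[out_idx]
        seed_a = noise_abs.seed + 2 * orig_idx
        seed_e = noise_eem.seed + 2 * orig_idx + 1
        spec = simulate_absorption(
            mixture, photo, NoiseSpec(noise_abs.gaussian_sd, seed_a), cod_label=label
        )
        eem = simulate_eem(
            mixture, photo, ife=ife, scatter=scatter,
            noise=NoiseSpec(noise_eem.gaussian_sd, seed_e),
        )
        spectra.append(spec)
        eems.append(eem)
        row = {"id": out_idx, "cod_label": label, "seed_abs": seed_a, "seed_eem": seed_e}
        conc = dict(mixture.components)
        for name in compound_names:
            row[name] = conc.get(name, 0.0)
        rows.append(row)
    return spectra, eems, pd.DataFrame(rows)
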