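"""COD conversion-coefficient chemistry and augmentation label arithmetic.

Chemical oxygen demand (COD, mg O2 per litre) of a pure organic CmHnOl is
tied to its stoichiometric oxidation to CO2 and H2O:

    CmHnOl + (2m + n/2 - l) O -> m CO2 + (n/2) H2O

so the theoretical conversion coefficient (mg O2 consumed per mg compound) is

    alpha_COD = (2m + n/2 - l) * Mr(O) / Mr(CmHnOl)

with Mr(O) = 16.00.  For nitrogen-bearing amino acids the formula is applied
verbatim to the C/H/O counts; measured dichromate-digestion coefficients are
used for dataset labelling, the theoretical values are informational.

The module also owns the arithmetic of the 0.01 mg/L label grid used to
augment the absorption dataset: counts are computed on an integer
centi-(mg/L) grid over half-open intervals (low, high], which makes segment
counts exactly additive and free of float drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Relative atomic mass of oxygen used throughout (matches the integer usage
#: of the stoichiometric balance; not the CODATA 15.999).
MR_OXYGEN = 16.00


@dataclass(frozen=True)
class Compound:
    """A pure organic compound CmHnOl with optional measured COD coefficient."""

    name: str
    m: int            # carbon atoms
    nH: int           # hydrogen atoms
    l: int            # oxygen atoms
    Mr: float         # relative molecular mass, g/mol
    alpha_measured: float | None = None  # mg O2 / mg, dichromate digestion

    def __post_init__(self) -> None:
        if self.m < 1 or self.nH < 0 or self.l < 0:
            raise ValueError(f"invalid formula counts for {self.name!r}")
        if self.Mr <= 0:
            raise ValueError(f"Mr must be positive for {self.name!r}")
        if self.alpha_measured is not None and self.alpha_measured <= 0:
            raise ValueError(f"alpha_measured must be positive for {self.name!r}")


@dataclass(frozen=True)
class MixtureSpec:
    """A mixture as (compound name, concentration mg/L) pairs."""

    components: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.components]
        if len(set(names)) != len(names):
            raise ValueError("compound names must be unique within a mixture")
        if any(c < 0 for _, c in self.components):
            raise ValueError("concentrations must be non-negative")

    @classmethod
    def of(cls, **conc_mg_per_L: float) -> "MixtureSpec":
        return cls(tuple((k, float(v)) for k, v in conc_mg_per_L.items()))


def theoretical_cod_coefficient(compound: Compound) -> float:
    """Stoichiometric COD coefficient (2m + n/2 - l) * Mr(O) / Mr, mg O2 / mg.

    Zero for fully oxidized stoichiometry (e.g. CO2 itself); a negative
    balance means the formula holds more oxygen than full oxidation needs
    and is rejected as invalid.
    """
    oxygen_atoms = 2 * compound.m + compound.nH / 2.0 - compound.l
    if oxygen_atoms < 0:
        raise ValueError(
            f"invalid stoichiometry for {compound.name!r}: "
            f"oxygen balance {oxygen_atoms} < 0"
        )
    return oxygen_atoms * MR_OXYGEN / compound.Mr


def mixture_cod(mixture: MixtureSpec, coefficients: Mapping[str, float]) -> float:
    """COD (mg/L) of a mixture: sum of concentration * coefficient."""
    total = 0.0
    for name, conc in mixture.components:
        if name not in coefficients:
            raise KeyError(f"no COD coefficient for compound {name!r}")
        total += conc * coefficients[name]
    return total


def _centi(x: float) -> int:
    return int(round(100.0 * x))


def fill_count(label_low: float, label_high: float, step: float = 0.01) -> int:
    """Number of augmentation labels in the half-open interval (low, high].

    Computed as round((high - low) / step); for the canonical 0.01 mg/L step
    this is evaluated on the integer centi-(mg/L) grid so that segment counts
    are exactly additive.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if label_low < 0 or label_high < label_low:
        raise ValueError("need 0 <= label_low <= label_high")
    if abs(step - 0.01) < 1e-12:
        return _centi(label_high) - _centi(label_low)
    return int(round((label_high - label_low) / step))


def label_grid(cod_max: float, step: float = 0.01) -> np.ndarray:
    """Strictly increasing COD labels over (0, cod_max] at the given spacing.

    Length equals ``fill_count(0, cod_max, step)``.  For steps that do not
    divide cod_max exactly the last label is the nearest multiple of step
    (within step/2 of cod_max).
    """
    if cod_max <= 0:
        raise ValueError("cod_max must be positive")
    n = fill_count(0.0, cod_max, step)
    return step * np.arange(1, n + 1)


def load_compound_registry() -> dict[str, Compound]:
    """The three-amino-acid registry shipped with the package."""
    with resources.files("codfusion.data").joinpath("compounds.csv").open() as fh:
        df = pd.read_csv(fh)
    return {
        row["name"]: Compound(
            name=row["name"],
            m=int(row["m"]),
            nH=int(row["nH"]),
            l=int(row["l"]),
            Mr=float(row["Mr"]),
            alpha_measured=float(row["alpha_measured"]),
        )
        for _, row in df.iterrows()
    }


def measured_coefficients(
    registry: Mapping[str, Compound] | None = None,
) -> dict[str, float]:
    registry = registry if registry is not None else load_compound_registry()
    out = {}
    for name, c in registry.items():
        if c.alpha_measured is None:
            raise ValueError(f"compound {name!r} has no measured coefficient")
        out[name] = c.alpha_measured
    return out


def load_mixture_design() -> pd.DataFrame:
    """The ten-mixture design table shipped with the package.

    Columns: id, one column per compound (mg/L), cod_printed (the label as
    originally reported; see :func:`check_design_consistency`).
    """
    with resources.files("codfusion.data").joinpath("design.csv").open() as fh:
        return pd.read_csv(fh)


def design_mixtures(design: pd.DataFrame | None = None) -> list[MixtureSpec]:
    design = design if design is not None else load_mixture_design()
    comp_cols = [c for c in design.columns if c not in ("id", "cod_printed")]
    out = []
    for _, row in design.iterrows():
        out.append(
            MixtureSpec(
                tuple((c, float(row[c])) for c in comp_cols if row[c] > 0)
            )
        )
    return out


def check_design_consistency(
    design: pd.DataFrame | None = None,
    coefficients: Mapping[str, float] | None = None,
    atol: float = 0.005,
) -> pd.DataFrame:
    """Recompute design labels from coefficients and flag mismatches.

    Three of the ten shipped design rows carry printed labels that disagree
    with the coefficient arithmetic (9.34 vs 9.39, 29.60 vs 32.44, 136.05 vs
    138.05); this package labels spectra with the recomputed values and keeps
    the printed ones for reference.
    """
    design = design if design is not None else load_mixture_design()
    coefficients = coefficients if coefficients is not None else measured_coefficients()
    mixtures = design_mixtures(design)
    recomputed = [mixture_cod(m, coefficients) for m in mixtures]
    out = design.copy()
    out["cod_recomputed"] = np.round(recomputed, 10)
    out["consistent"] = np.abs(out["cod_recomputed"] - out["cod_printed"]) <= atol
    return out


def design_labels(
    design: pd.DataFrame | None = None,
    coefficients: Mapping[str, float] | None = None,
) -> list[float]:
    """Recomputed COD labels of the design rows, sorted ascending."""
    checked = check_design_consistency(design, coefficients)
    return sorted(float(v) for v in checked["cod_recomputed"])
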