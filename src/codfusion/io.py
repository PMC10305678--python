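"""CSV/YAML/JSON dialects and atomic file writes.

Absorption spectra are two-column CSVs (wavelength_nm, absorbance); EEMs are
matrix CSVs whose first row is the excitation wavelength header and first
column the emission wavelengths; the dataset manifest is a plain CSV.  All
writes go through a temp-file + rename so partial artifacts never appear.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .synth import EEM, AbsorptionSpectrum


class FormatError(ValueError):
    pass


def atomic_write_text(path: Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_absorption_csv(path: Path, spectrum: AbsorptionSpectrum) -> None:
    lines = ["wavelength_nm,absorbance"]
    lines += [f"{float(w)!r},{float(a)!r}"
              for w, a in zip(spectrum.wavelengths, spectrum.absorbance)]
    atomic_write_text(Path(path), "\n".join(lines) + "\n")


def read_absorption_csv(path: Path, cod_label: float = 0.0,
                        provenance: str = "measured") -> AbsorptionSpectrum:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["wavelength_nm", "absorbance"]:
        raise FormatError(f"{path}: expected header wavelength_nm,absorbance "
                          f"(line 1), got {list(df.columns)}")
    wl = df["wavelength_nm"].to_numpy(float)
    bad = np.nonzero(np.diff(wl) <= 0)[0]
    if bad.size:
        raise FormatError(f"{path}: wavelength grid not strictly increasing "
                          f"at line {bad[0] + 3}")
    return AbsorptionSpectrum(wl, df["absorbance"].to_numpy(float),
                              cod_label, provenance)


def write_eem_csv(path: Path, eem: EEM) -> None:
    lines = ["em_nm\\ex_nm," + ",".join(repr(float(x)) for x in eem.ex_wavelengths)]
    for em, row in zip(eem.em_wavelengths, eem.intensity):
        lines.append(f"{float(em)!r}," + ",".join(repr(float(v)) for v in row))
    atomic_write_text(Path(path), "\n".join(lines) + "\n")


def read_eem_csv(path: Path) -> EEM:
    df = pd.read_csv(path, float_precision="round_trip")
    ex = np.array([float(c) for c in df.columns[1:]])
    em = df.iloc[:, 0].to_numpy(float)
    for name, grid in (("excitation", ex), ("emission", em)):
        bad = np.nonzero(np.diff(grid) <= 0)[0]
        if bad.size:
            raise FormatError(
                f"{path}: {name} grid not strictly increasing near entry {bad[0] + 1}")
    return EEM(ex, em, df.iloc[:, 1:].to_numpy(float))


def write_manifest(path: Path, manifest: pd.DataFrame) -> None:
    atomic_write_text(Path(path), manifest.to_csv(index=False))


def read_manifest(path: Path, check_paths: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    if check_paths:
        missing = []
        for col in ("absorption_path", "eem_path"):
            if col in df.columns:
                missing += [p for p in df[col] if not Path(p).exists()]
        if missing:
            raise FormatError(f"manifest references missing files: {missing}")
    return df


def write_matrix(path: Path, matrix: np.ndarray) -> None:
    """Feature matrices / blocks as .npy (binary) or .csv by extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".npy":
        fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.",
                                   suffix=".npy")
        try:
            with os.fdopen(fd, "wb") as fh:
                np.save(fh, matrix)
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise
    else:
        atomic_write_text(path, "\n".join(
            ",".join(repr(float(v)) for v in row) for row in np.atleast_2d(matrix)
        ) + "\n")


def read_matrix(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    return np.loadtxt(path, delimiter=",", ndmin=2)


def write_yaml(path: Path, payload: dict[str, Any]) -> None:
    atomic_write_text(Path(path), yaml.safe_dump(payload, sort_keys=True))


def read_yaml(path: Path) -> dict[str, Any]:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_json(path: Path, payload: dict[str, Any]) -> None:
    atomic_write_text(Path(path), json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_response_pngs(outdir: Path, responses: np.ndarray) -> list[Path]:
    """Export 0-255 grayscale responses as 8-bit PNGs for inspection."""
    from skimage.io import imsave

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, img in enumerate(responses):
        p = outdir / f"response_{i:02d}.png"
        imsave(p, img.astype(np.uint8), check_contrast=False)
        paths.append(p)
    return paths
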