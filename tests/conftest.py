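import numpy as np
import pytest

from codfusion import chem, synth


@pytest.fixture(scope="session")
def registry():
    return chem.load_compound_registry()


@pytest.fixture(scope="session")
def coefficients(registry):
    return chem.measured_coefficients(registry)


@pytest.fixture(scope="session")
def photo():
    return synth.default_photophysics()


@pytest.fixture(scope="session")
def design_mixtures():
    return chem.design_mixtures()


@pytest.fixture(scope="session")
def design_spectra(design_mixtures, photo):
    """Noisy synthetic absorption spectra + EEMs for the shipped design."""
    return synth.generate_design_dataset(
        design_mixtures, photo,
        noise_abs=synth.NoiseSpec(5e-4, 100),
        noise_eem=synth.NoiseSpec(0.5, 200),
        ife=True, scatter=True,
    )


@pytest.fixture(scope="session")
def blank_absorption(design_spectra):
    spectra = design_spectra[0]
    return synth.AbsorptionSpectrum(
        spectra[0].wavelengths, np.zeros_like(spectra[0].absorbance), 0.0, "measured")
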