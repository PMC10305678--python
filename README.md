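# codfusion

Chemical oxygen demand (COD) retrieval for water samples from **fused
UV-Vis absorption and fluorescence excitation–emission spectra**, built
around a 2D Gabor filter-bank feature extractor and a dual-branch 1D
convolutional fusion network. The package is aimed at environmental
chemometrics work: calibrating optical COD sensors against
dichromate-digestion labels, and studying when adding an EEM channel helps
over absorption alone (fluorescent analytes, inner-filter distortion at
high concentration).

## The method

COD labels come from stoichiometry: for CmHnOl oxidized to CO₂ and H₂O,

    α_COD = (2m + n/2 − l) · Mr(O) / Mr(CmHnOl),   Mr(O) = 16.00

and a mixture's COD is Σ cᵢ·αᵢ over its components (measured dichromate
coefficients for N-containing amino acids). The regression inputs are:

* **Absorption branch** – the 2559-point spectrum X_abs ∈ R^(n×1) through
  four dual-channel 1D-conv blocks (16→128 channels, kernel 3×1, max
  pooling) to a 19×128 feature matrix M₁ = f₁(X_abs).
* **Fluorescence branch** – the EEM is scatter-corrected (Delaunay
  interpolation over the Rayleigh/Raman bands found from a blank),
  cubic-spline upsampled 32×9 → 2217×2217, filtered with 35 Gabor kernels
  g(x, y; λ, θ, ψ, σ, γ) (λ ∈ {3..15}, θ ∈ [0, π/2)), flattened to a
  306,916×35 matrix, embedded by Isomap into 20 components (method choice
  scored by the mean coefficient of variation Cv̄ = Σᵢ σᵢ/μᵢ / n), and
  reshaped to the 5×128 block M₂.
* **Fusion head** – M₃ = [M₁, M₂] ∈ R^(24×128), flattened, dropout on the
  convolutional nodes, one linear neuron → COD (mg/L), trained with Adam +
  exponentially decaying learning rate under an MSE loss.

No public measured dataset exists for this system, so
`codfusion.synth` generates the ten-mixture phenylalanine/tyrosine/
tryptophan design synthetically (Beer–Lambert bands, Gaussian fluorophores,
optional inner-filter distortion 10^(−(A_ex+A_em)/2), Rayleigh/Raman
ridges, Gaussian noise), and `codfusion.preprocess` densifies the
absorption dataset on the 0.01 mg/L COD-label grid (944 spectra between
labels 9.34 and 18.78; 14,657 spectra in total over (0, 146.57]).

## Worked example

```python
import numpy as np
from codfusion import chem, synth, preprocess

reg = chem.load_compound_registry()
print(round(chem.theoretical_cod_coefficient(reg["phenylalanine"]), 4))
# 2.0825          (mg O2 per mg, theoretical)

coeff = chem.measured_coefficients()
mix = chem.MixtureSpec.of(tyrosine=15, phenylalanine=80, tryptophan=6)
print(round(chem.mixture_cod(mix, coeff), 2))
# 146.57          (mg/L, the largest design label)

print(chem.fill_count(9.34, 18.78))
# 944             (0.01 mg/L augmentation labels in (9.34, 18.78])

spectra, eems, manifest = synth.generate_design_dataset(
    chem.design_mixtures(), noise_abs=synth.NoiseSpec(5e-4, 1),
    noise_eem=synth.NoiseSpec(0.5, 2))
blank = synth.AbsorptionSpectrum(spectra[0].wavelengths,
                                 np.zeros(2559), 0.0, "measured")
aug = preprocess.augment_absorption([blank] + list(spectra), step=0.01)
print(len(aug))
# 14657           (augmented absorbance spectra, labels 0–146.57 mg/L)
```

A desk-scale end-to-end run (0.1 mg/L augmentation, 20 epochs, seed 1)
trains the fusion network and its absorption-only ablation and prints
retrieval metrics like

```
fusion:   val_r2=0.9973  rrmsep=2.990%  acc5=76.4%
abs-only: val_r2=0.9894  rrmsep=5.671%  acc5=65.8%
```

i.e. fusing the fluorescence block roughly halves the relative RMS
prediction error under inner-filter distortion. The full pipeline —
simulate → preprocess → features → reduce → pair → train → evaluate — is
scriptable through `codfusion.pipeline.run_pipeline` or the CLI:

```
codfusion run --config config.yaml        # end-to-end
codfusion simulate --outdir out/          # stage by stage
codfusion reduce --outdir out/ --compare  # rank reduction methods by Cv̄
codfusion report --outdir out/
```

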