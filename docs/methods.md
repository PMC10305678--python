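# Methods

`codfusion` estimates chemical oxygen demand (COD, mg O₂/L) of water samples
from two simultaneously measured spectra: a UV-Vis absorption spectrum
(200–700 nm, 2559 points) and an excitation–emission fluorescence matrix
(EEM; 9 excitation × 32 emission channels, excitation 255–380 nm). The
package covers the full chain — chemistry-based labeling, synthetic data
generation, EEM preprocessing, 2D Gabor texture features, coefficient-of-
variation-guided dimensionality reduction, and a dual-branch 1D-CNN fusion
regressor — for the three aromatic amino acids phenylalanine, tyrosine and
tryptophan as model analytes.

## COD chemistry

For a compound CmHnOl fully oxidized to CO₂ and H₂O, the oxidant demand per
unit mass is

    α_COD = (2m + n/2 − l) · Mr(O) / Mr,    Mr(O) = 16.00 g/mol.

The formula ignores nitrogen; for the N-containing amino acids the shipped
*measured* dichromate-digestion coefficients (tyrosine 1.31, phenylalanine
1.48, tryptophan 1.42 mg O₂/mg) label all datasets, and the theoretical
values are informational. Mixture COD is Σ cᵢαᵢ (Beer–Lambert-additive
chemistry). Three of the ten shipped design rows carry printed labels that
disagree with this arithmetic (9.34 vs 9.39, 29.60 vs 32.44, 136.05 vs
138.05); the package always labels from the coefficients and exposes the
discrepancy through `chem.check_design_consistency`.

Label-grid arithmetic is done in integer hundredths of mg/L over half-open
intervals (low, high]. This convention simultaneously reproduces the two
reference counts — 944 spectra between the 9.34 and 18.78 labels and 14,657
spectra in total over (0, 146.57] — and makes segment counts exactly
additive. The augmentation grid is anchored at the label-0 blank; the total
count forces that choice.

## Synthetic spectra

No measured dataset is distributed, so the generator emulates the study
conditions:

* **Absorption** — per-compound Gaussian bands (far-UV plus near-UV) with
  literature-scale specific absorbances (e.g. tryptophan ≈ 0.17 and 0.027
  L·mg⁻¹·cm⁻¹ at 219 and 280 nm), additive over components, 1 cm path,
  optional Gaussian noise (default sd 5·10⁻⁴ AU).
* **Fluorescence** — separable Gaussian fluorophores (Phe 258/282, Tyr
  275/303, Trp 280/350 nm, yields 2/20/60 a.u. per mg/L), inner-filter
  attenuation `10^(−(A(ex)+A(em))/2)` computed from the mixture's own
  synthetic absorbance (the conventional primary+secondary inner-filter form), first/second-order Rayleigh
  ridges and a water Raman band at 3400 cm⁻¹ (Gaussian profiles in
  perpendicular distance to the scatter line, sd 10 nm, amplitudes
  200/60/30 a.u.), then Gaussian noise (default sd 0.5 a.u.).

All generators are pure functions of (inputs, seed). What the generator does
**not** model: detector shot noise and stray light, pH/temperature effects,
instrument response, quenching beyond IFE. Passing tests therefore
demonstrate the pipeline's internal correctness and the fusion architecture's
behavior under controlled distortions, not performance on real water.

## Preprocessing

Scatter bands are located on a deionized-water blank: cells above
mean + 3·sd are assigned to the nearest order line (em = o·ex, o ∈ {1, 2})
and each order's half-width is the maximum perpendicular extent of its
assigned cells. Band cells are masked and refilled by Delaunay-triangulation
barycentric-linear interpolation — exact on affine intensity fields, convex
(never negative on non-negative input), and idempotent. Masked cells outside
the convex hull of surviving points are set to 0.

Raw 32×9 EEMs are upsampled by separable cubic splines (emission axis, then
excitation) onto uniform 2217×2217 grids; knots are reproduced and negative
interpolants are clipped to 0 (logged). Absorption datasets are densified by
fitting, per wavelength channel, a cubic spline of absorbance against COD
label through all measured spectra and evaluating it on the 0.01 mg/L grid;
measured rows are re-inserted bit-exactly. The test split draws 1000 spectra
uniformly without replacement, seeded.

## Gabor features

Kernels follow the Gaussian-windowed complex sinusoid with rotated
coordinates; defaults σ = 2π px, γ = 0.5, ψ = 0 (ψ is unstated in the
source; 0 gives the even-symmetric real part). The square support is
K = ceil(max(Xmax, Ymax)) rounded up to odd, with both long-axis terms read
as 3σ/γ (the printed extent formula mixes in a λ that contradicts the
accompanying text; the text's "3σ/r is the long axis" wins). Note that this
rule truncates the envelope's long axis at ≈1.5σ: kernel energy therefore
varies by a few percent across orientation, and truncated oblique kernels
keep a small DC leakage — consequences of the extent rule itself, not defects.

The default bank is λ ∈ {3, 6, 9, 12, 15} × θ ∈ {0, π/12, π/8, π/6, π/4,
π/3, 3π/8}, wavelength-major, 35 kernels. Responses are complex magnitudes
(phase-invariant, standard for Gabor texture) of reflect-padded FFT
convolutions, min–max scaled to the 0–255 gray range per response, and
bilinearly resized to 554×554 — chosen because the target feature-matrix
row count 306,916 equals 554² (554 ≈ 2217/4).
Flattening is excitation-major by default (both rasters supported).

## Dimensionality reduction and selection

The 306,916×35 matrix is read as 35 kernel-samples of dimension 306,916;
PCA, FastICA, Isomap, LLE, and sparse/Gaussian random projections embed them
into 20 components (20×35). Methods are scored by the mean coefficient of
variation Cv̄ = (1/n)Σ sdᵢ/|meanᵢ| (population sd — the
coefficient of variation is defined with the standard deviation, even
where σᵢ is loosely called a variance). Isomap uses n_neighbors = 15: with 35 samples and 20
requested components, 10 neighbors frequently leaves the geodesic kernel
with a non-PSD tail that scikit-learn rejects, while 15 keeps the requested
spectrum positive. GRP is implemented but excluded from default rankings
(its reference comparison entry is uninterpretable). PCA uses the full SVD
solver; the automatic choice would pick an unseeded randomized solver at
these shapes.

The 20×35 matrix keeps its 32 highest-Cv kernels (the 700→640 selection rule
is unstated; dropping the 3 lowest-Cv kernels yields exactly 640 values with
a principled criterion) and is reshaped kernel-major to 5×128.

When several EEMs feed one regression dataset, the reduction is fit once on
the pooled kernel vectors of all EEMs and each EEM is transformed through
that shared model (`dimred.reduce_collection`), with one shared kernel
selection. Embeddings fit per EEM carry arbitrary orientation, which would
make blocks from different EEMs incomparable — fatal for label-space
interpolation between them.

## Fusion network

The absorption branch is four blocks of two *dual-channel units*; a unit is
two parallel paths of three chained conv(3×1)+ReLU layers merged by
addition — 12 convolutions per block, matching the reference per-block
operation count of 12 — with channels 16/32/64/128 and a length-2 max pool after
every unit except the last (seven pools take 2559 → 19 by floor division;
a 2-pools-per-block plan would give 9×128 instead of the required 19×128). The branch output 19×128 is concatenated with the 5×128
fluorescence block to 24×128, flattened, passed through dropout and a single
linear neuron. Dropout (rate 0.5) applies to the *convolutional* features
only — it is the convolutional-branch nodes that are randomly discarded —
so the precomputed fluorescence block reaches the dense layer untouched;
dropping it as well measurably degrades the fusion pathway. The network has
723,361 parameters, within 1.5% of the reference total of 733,729 (whose exact block
internals are not specified; exact parity is not claimed).

Because no deep-learning framework is part of the environment, the network
is implemented directly in NumPy (`codfusion.nn`): im2col convolution via
BLAS matmul with hand-written backward passes, verified against finite
differences in piecewise-linear settings. Training is minibatch MSE with
Adam (lr₀ = 10⁻³, per-epoch exponential decay 0.96, batch 32), default
3 cycles × 50 epochs, a 10% validation holdout, and checkpointing of the
best validation R². Inputs and labels are standardized from training
statistics (scalar mean/sd per stream); predictions are returned in mg/L.
Fluorescence features are precomputed — no gradient flows through the Gabor
or embedding stages. All randomness (init, shuffling, dropout) comes from
one seeded generator, so histories are bit-reproducible.

Metrics: R², MSE, RRMSEP (100·RMSE/mean truth), RSS, OLS slope of
predictions on truths, and the fraction of predictions within 5% relative
error. Non-positive truths are excluded from the relative-error accuracy
with a warning.

## Scaled end-to-end study

The acceptance-level study runs the whole chain at desk scale, as the
package's own problem-size choice: the ten-mixture design with IFE and
scatter on; EEMs upsampled to 554 (features taken at the native 554 grid);
shared-Isomap blocks; absorption augmented at 0.1 mg/L (1,466 spectra);
the standard 1000-sample test split (leaving ~420 training spectra);
20 epochs; three fixed seeds with both the fusion network and its
absorption-only ablation (fluorescence block zeroed at train and test).
Medians over the three runs are compared. Full-scale settings (0.01 mg/L,
2217 grid, 150 epochs) are exposed through the same configuration objects.

## Known limitations

* Synthetic spectra are smooth Gaussian idealizations; augmented absorption
  spectra are noiseless between measured knots, so both branches carry more
  recoverable label information than real instruments would provide.
* The fluorescence block of an augmented sample is a label-space
  interpolation between measured blocks — appropriate for the fusion
  architecture's plumbing, but not a physical model of intermediate
  mixtures under IFE.
* Single-EEM `dimred.reduce` is kept for method comparison (Cv̄ ranking);
  cross-EEM work must use `reduce_collection`.
* The Delaunay fill cannot reconstruct fluorescence structure that lies
  entirely inside a scatter band.
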