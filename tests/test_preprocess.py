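"""Scatter detection/removal, spline upsampling, augmentation, splitting."""

import numpy as np
import pytest

from codfusion import preprocess, synth
from codfusion.chem import fill_count
from codfusion.preprocess import ScatterBands
from codfusion.synth import EEM, AbsorptionSpectrum


def _grid_eem(intensity):
    ex = synth.raw_ex_grid()
    em = synth.raw_em_grid()
    return EEM(ex, em, intensity)


def _planted_ridge(order, half_width):
    """Blank whose hot cells are exactly those within half_width of the line."""
    ex = synth.raw_ex_grid()
    em = synth.raw_em_grid()
    exg, emg = np.meshgrid(ex, em)
    d = np.abs(emg - order * exg) / np.sqrt(1 + order**2)
    z = np.where(d <= half_width, 100.0, 0.0)
    return EEM(ex, em, z)


class TestDetectScatterBands:
    def test_flat_blank_empty_bands(self):
        bands = preprocess.detect_scatter_bands(_grid_eem(np.zeros((32, 9))))
        assert bands.half_width_1 == 0.0 and bands.half_width_2 == 0.0

    def test_planted_first_order_width_recovered(self):
        em_step = np.diff(synth.raw_em_grid())[0]
        bands = preprocess.detect_scatter_bands(_planted_ridge(1, 10.0))
        assert bands.half_width_1 > 0
        assert abs(bands.half_width_1 - 10.0) <= em_step

    def test_planted_second_order_only(self):
        bands = preprocess.detect_scatter_bands(_planted_ridge(2, 10.0))
        assert bands.half_width_1 == 0.0
        assert bands.half_width_2 > 0


class TestRemoveScatter:
    def test_empty_bands_identity(self):
        rng = np.random.default_rng(0)
        eem = _grid_eem(rng.random((32, 9)))
        out = preprocess.remove_scatter(eem, ScatterBands(0.0, 0.0))
        np.testing.assert_array_equal(out.intensity, eem.intensity)

    def test_affine_field_recovered_exactly(self):
        ex = synth.raw_ex_grid()
        em = synth.raw_em_grid()
        exg, emg = np.meshgrid(ex, em)
        z = 3.0 + 0.02 * exg + 0.01 * emg
        eem = EEM(ex, em, z)
        bands = ScatterBands(half_width_1=20.0, half_width_2=0.0)
        mask = preprocess.scatter_mask(eem, bands)
        assert mask.any()
        out = preprocess.remove_scatter(eem, bands)
        # interior masked cells: barycentric-linear interpolation is exact on
        # affine fields; unmasked cells pass through bit-exactly
        keep = ~mask
        np.testing.assert_array_equal(out.intensity[keep], z[keep])
        exg_hull = (exg >= ex[0]) & (exg <= ex[-1])
        inside = mask & (emg > em[0] + 1) & (emg < em[-1] - 1) & exg_hull
        np.testing.assert_allclose(out.intensity[inside], z[inside], rtol=1e-9)

    def test_nonnegative_preserved(self):
        rng = np.random.default_rng(1)
        eem = _grid_eem(rng.random((32, 9)))
        out = preprocess.remove_scatter(eem, ScatterBands(15.0, 10.0))
        assert np.all(out.intensity >= 0)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        eem = _grid_eem(rng.random((32, 9)) * 50)
        bands = ScatterBands(15.0, 10.0)
        once = preprocess.remove_scatter(eem, bands)
        twice = preprocess.remove_scatter(once, bands)
        np.testing.assert_array_equal(once.intensity, twice.intensity)


class TestUpsampleEEM:
    def test_constant_stays_constant(self):
        out = preprocess.upsample_eem(_grid_eem(np.full((32, 9), 7.0)), 100)
        np.testing.assert_allclose(out.intensity, 7.0, rtol=1e-9)

    def test_knot_fidelity(self):
        # 249 = 31*8 + 1 puts every raw emission (every 8th point) and raw
        # excitation (every 31st point) knot exactly on the fine grid
        rng = np.random.default_rng(3)
        eem = _grid_eem(rng.random((32, 9)) * 10)
        out = preprocess.upsample_eem(eem, 249)
        np.testing.assert_allclose(
            out.intensity[::8, ::31], np.clip(eem.intensity, 0, None), atol=1e-9)

    def test_default_shape_2217(self):
        eem = _grid_eem(np.random.default_rng(4).random((32, 9)))
        out = preprocess.upsample_eem(eem)
        assert out.intensity.shape == (2217, 2217)
        assert out.ex_wavelengths.size == out.em_wavelengths.size == 2217

    def test_commutes_with_scalar_multiplication(self):
        rng = np.random.default_rng(5)
        z = rng.random((32, 9))
        a = preprocess.upsample_eem(_grid_eem(z), 64).intensity
        b = preprocess.upsample_eem(_grid_eem(3.5 * z), 64).intensity
        np.testing.assert_allclose(b, 3.5 * a, rtol=1e-9, atol=1e-12)

    def test_nonnegative_output(self):
        z = np.zeros((32, 9))
        z[10, 4] = 1.0    # cubic overshoot would go negative nearby
        out = preprocess.upsample_eem(_grid_eem(z), 200)
        assert np.all(out.intensity >= 0)


def _measured(wl, label, rng=None, scale=1.0):
    absb = scale * np.linspace(0, 1, wl.size) * label
    if rng is not None:
        absb = absb + rng.normal(0, 1e-4, wl.size)
    return AbsorptionSpectrum(wl, absb, label, "measured")


class TestAugmentAbsorption:
    wl = np.linspace(200, 700, 2559)

    def test_segment_count_between_two_knots(self):
        blank = AbsorptionSpectrum(self.wl, np.zeros(2559), 0.0, "measured")
        s1 = _measured(self.wl, 9.34)
        s2 = _measured(self.wl, 18.78)
        aug = preprocess.augment_absorption([blank, s1, s2])
        assert len(aug) == fill_count(0, 18.78) == 1878
        labels = aug.labels
        in_segment = (labels > 9.34) & (labels <= 18.78)
        assert int(in_segment.sum()) == 944

    def test_design_total_14657(self, design_spectra, blank_absorption):
        spectra = design_spectra[0]
        aug = preprocess.augment_absorption([blank_absorption] + list(spectra))
        assert len(aug) == 14657

    def test_measured_knots_bit_exact(self, design_spectra, blank_absorption):
        spectra = design_spectra[0]
        aug = preprocess.augment_absorption(
            [blank_absorption] + list(spectra), step=0.1)
        by_label = {s.cod_label: s for s in aug.spectra}
        for s in spectra:
            got = by_label[s.cod_label]
            np.testing.assert_array_equal(got.absorbance, s.absorbance)
            assert got.provenance == "synthetic"

    def test_labels_vary_continuously(self, design_spectra, blank_absorption):
        spectra = design_spectra[0]
        aug = preprocess.augment_absorption(
            [blank_absorption] + list(spectra), step=0.5)
        stack = np.stack([s.absorbance for s in aug.spectra])
        max_adjacent = np.abs(np.diff(stack, axis=0)).max()
        max_measured = np.abs(np.diff(
            np.stack([s.absorbance for s in spectra]), axis=0)).max()
        assert max_adjacent < max_measured

    def test_requires_blank_anchor(self):
        s1 = _measured(self.wl, 5.0)
        s2 = _measured(self.wl, 10.0)
        with pytest.raises(ValueError, match="blank"):
            preprocess.augment_absorption([s1, s2])

    def test_duplicate_labels_rejected(self):
        blank = AbsorptionSpectrum(self.wl, np.zeros(2559), 0.0, "measured")
        with pytest.raises(ValueError, match="duplicate"):
            preprocess.augment_absorption(
                [blank, _measured(self.wl, 5.0), _measured(self.wl, 5.0)])


class TestSplitTest:
    def _aug(self, n=50):
        wl = np.linspace(200, 700, 2559)
        blank = AbsorptionSpectrum(wl, np.zeros(2559), 0.0, "measured")
        knots = [blank, _measured(wl, 10.0), _measured(wl, n / 2.0)]
        return preprocess.augment_absorption(knots, step=0.5)

    def test_min_train_size(self):
        aug = self._aug()
        train, test = preprocess.split_test(aug, n=len(aug) - 1, seed=0)
        assert len(train) == 1 and len(test) == len(aug) - 1

    def test_same_seed_same_split(self):
        aug = self._aug()
        t1 = preprocess.split_test(aug, n=10, seed=3)
        t2 = preprocess.split_test(aug, n=10, seed=3)
        assert [s.cod_label for s in t1[1]] == [s.cod_label for s in t2[1]]

    def test_partition_disjoint_exhaustive(self):
        aug = self._aug()
        train, test = preprocess.split_test(aug, n=10, seed=1)
        assert len(train) + len(test) == len(aug)
        labels = sorted([s.cod_label for s in train] + [s.cod_label for s in test])
        assert labels == sorted(aug.labels.tolist())

    def test_oversized_test_rejected(self):
        aug = self._aug()
        with pytest.raises(ValueError):
            preprocess.split_test(aug, n=len(aug), seed=0)

    def test_scaled_design_split_spans_label_range(
            self, design_spectra, blank_absorption):
        spectra = design_spectra[0]
        aug = preprocess.augment_absorption(
            [blank_absorption] + list(spectra), step=0.1)
        _, test = preprocess.split_test(aug, n=1000, seed=42)
        labels = np.array([s.cod_label for s in test])
        assert labels.min() < 10 and labels.max() > 140
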