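"""Normalisation, modulation PCA and zero-crossing peak calls."""

import numpy as np
import pytest
from scipy import linalg

from wmrs.extract import (
    ModulatedSpectrum,
    SpectraDataset,
    extract_modulated_spectrum,
    find_zero_crossings,
    normalize_stack,
)
from wmrs.simulate import (
    AcquisitionConfig,
    BackgroundModel,
    CellClassModel,
    DonorEffect,
    ModulationStack,
    RamanPeak,
    default_cell_classes,
    generate_stack,
)


def _stack_from(intensities, axis=None):
    intensities = np.asarray(intensities, dtype=float)
    n_steps, n_bins = intensities.shape
    if axis is None:
        axis = np.linspace(600.0, 1800.0, n_bins)
    return ModulationStack(
        cell_id="cell-0000",
        class_label="?",
        donor_id="d",
        axis=axis,
        intensities=intensities,
        excitations=784.5 + np.arange(n_steps) * 0.25,
    )


class TestNormalize:
    def test_constant_row_becomes_uniform(self):
        stack = _stack_from(np.full((5, 1200), 3.7))
        out = normalize_stack(stack)
        assert np.allclose(out.intensities, 1.0 / 1200)

    def test_rows_sum_to_one_and_gain_is_absorbed(self):
        rng = np.random.default_rng(0)
        rows = rng.uniform(0.1, 2.0, size=(5, 300))
        out = normalize_stack(_stack_from(rows))
        assert np.allclose(out.intensities.sum(axis=1), 1.0, atol=1e-12)
        tripled = normalize_stack(_stack_from(3.0 * rows))
        assert np.allclose(out.intensities, tripled.intensities)

    def test_non_positive_row_names_the_step(self):
        rows = np.ones((5, 50))
        rows[3] = 0.0
        with pytest.raises(ValueError, match="step 3"):
            normalize_stack(_stack_from(rows))


class TestModulationPCA:
    def test_background_only_stack_has_no_modulated_component(self, acq, donor):
        model = CellClassModel("bg", (), background=BackgroundModel())
        stack = generate_stack(model, donor, acq, seed=0)
        with pytest.raises(ValueError, match="no modulated component"):
            extract_modulated_spectrum(stack)

    def test_matches_independent_svd_oracle(self, acq, donor, single_peak_model):
        stack = generate_stack(single_peak_model, donor, acq, seed=1)
        ms = extract_modulated_spectrum(stack)
        X = normalize_stack(stack).intensities
        Xc = X - X.mean(axis=0)
        _, s, Vt = linalg.svd(Xc, full_matrices=False)  # independent SVD route
        oracle = Vt[0]
        if oracle @ ms.values < 0:
            oracle = -oracle
        assert np.max(np.abs(ms.values - oracle)) < 1e-8
        assert abs(ms.explained_variance_ratio - s[0] ** 2 / np.sum(s**2)) < 1e-10

    def test_unit_norm_and_derivative_sign_convention(self, acq, donor, single_peak_model):
        stack = generate_stack(single_peak_model, donor, acq, seed=2)
        ms = extract_modulated_spectrum(stack)
        assert abs(np.linalg.norm(ms.values) - 1.0) < 1e-12
        X = normalize_stack(stack).intensities
        grad = np.gradient(X.mean(axis=0), stack.axis)
        assert ms.values @ grad >= 0

    def test_gain_invariance(self, acq, donor):
        model = default_cell_classes()[0]
        stack = generate_stack(model, donor, acq, seed=3)
        scaled = _stack_from(7.0 * stack.intensities, axis=stack.axis)
        a = extract_modulated_spectrum(stack)
        b = extract_modulated_spectrum(scaled)
        assert np.allclose(a.values, b.values, atol=1e-10)

    def test_background_suppression(self, acq, donor):
        """10x background barely perturbs the modulated spectrum but
        dominates the raw mean spectrum."""
        cls = default_cell_classes()[0]  # background scale 10
        with_bg = generate_stack(cls, donor, acq, seed=5)
        raman_only = CellClassModel(cls.name, cls.peaks, None, cls.amplitude_cv, 0.0)
        reference = generate_stack(raman_only, donor, acq, seed=5)  # same jitter
        corr_mod = np.corrcoef(
            extract_modulated_spectrum(with_bg).values,
            extract_modulated_spectrum(reference).values,
        )[0, 1]
        corr_raw = np.corrcoef(
            normalize_stack(with_bg).intensities.mean(axis=0),
            normalize_stack(reference).intensities.mean(axis=0),
        )[0, 1]
        assert corr_mod > 0.95
        assert corr_raw < 0.5


class TestZeroCrossings:
    def test_no_sign_change_yields_no_calls(self):
        n = 64
        ms = ModulatedSpectrum(
            "c", "?", "d", np.arange(n, dtype=float), np.full(n, 1.0 / np.sqrt(n)), 1.0
        )
        assert find_zero_crossings(ms, min_amplitude=0.0) == []

    def test_linear_interpolation_midpoint(self):
        v = np.array([1.0, -1.0]) / np.sqrt(2)
        ms = ModulatedSpectrum("c", "?", "d", np.array([1000.0, 1010.0]), v, 1.0)
        calls = find_zero_crossings(ms, min_amplitude=0.0)
        assert len(calls) == 1
        assert np.isclose(calls[0].position, 1005.0)
        assert calls[0].slope_sign == -1

    def test_exact_zero_counts_once(self):
        v = np.array([0.8, 0.0, -0.6])
        v = v / np.linalg.norm(v)
        ms = ModulatedSpectrum("c", "?", "d", np.array([1.0, 2.0, 3.0]), v, 1.0)
        calls = find_zero_crossings(ms, min_amplitude=0.0)
        assert len(calls) == 1
        assert calls[0].position == 2.0

    def test_single_simulated_peak_crossing_at_band_center(self, acq, donor, single_peak_model):
        ms = extract_modulated_spectrum(generate_stack(single_peak_model, donor, acq, seed=0))
        calls = find_zero_crossings(ms)
        assert len(calls) == 1
        assert abs(calls[0].position - 1007.0) < 2.0

    @pytest.mark.parametrize("centers", [(700.0, 1007.0), (700.0, 1007.0, 1400.0, 1700.0)])
    def test_k_well_separated_peaks_give_k_crossings(self, acq, donor, centers):
        model = CellClassModel("multi", tuple(RamanPeak(c) for c in centers))
        ms = extract_modulated_spectrum(generate_stack(model, donor, acq, seed=0))
        calls = find_zero_crossings(ms)
        assert len(calls) == len(centers)
        for call, center in zip(calls, centers):
            assert abs(call.position - center) < 2.0


def test_dataset_requires_shared_axis(random_unit_spectra):
    spectra = random_unit_spectra(3, 50)
    other = random_unit_spectra(1, 60)
    with pytest.raises(ValueError, match="shared axis"):
        SpectraDataset(spectra + other)
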