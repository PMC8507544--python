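"""Cosmic-ray removal, reference building, EMSC, denoising, quality culling."""

import dataclasses

import numpy as np
import pytest

from cytoscreen.phantom import (
    SpectralPhantomParams,
    class_signature,
    generate_spectrum_set,
    glass_profile,
    inject_cosmic_rays,
)
from cytoscreen.preprocess import (
    CollinearityError,
    DegenerateFitError,
    _legendre_basis,
    build_reference,
    build_substrate_reference,
    emsc_correct,
    quality_cull,
    remove_cosmic_rays,
    savitzky_golay,
)
from cytoscreen.spectral_core import Spectrum, SpectrumSet, WavenumberAxis

from conftest import random_spectrum_set


class TestRemoveCosmicRays:
    def test_twin_pair_spike_restored_exactly(self, rng):
        base = 100.0 + 50.0 * np.exp(
            -((np.linspace(600, 1800, 200) - 1000) ** 2) / 200.0
        ) + rng.normal(0, 1, 200)
        axis = WavenumberAxis(np.linspace(600, 1800, 200))
        spiked = base.copy()
        spiked[70] += 50.0 * base.std()
        ss = SpectrumSet(axis=axis, matrix=np.vstack([spiked, base]))
        out, rep = remove_cosmic_rays(ss)
        assert rep.flagged[0] == [70]
        assert rep.flagged[1] == []
        assert out.matrix[0, 70] == pytest.approx(base[70], rel=1e-9)
        np.testing.assert_array_equal(np.delete(out.matrix[0], 70),
                                      np.delete(spiked, 70))

    def test_clean_dataset_untouched(self, axis, camera, clean_params):
        ss = generate_spectrum_set(["low_grade"] * 12, clean_params, camera,
                                   10.0, axis, seed=3)
        out, rep = remove_cosmic_rays(ss)
        np.testing.assert_array_equal(out.matrix, ss.matrix)
        assert rep.n_flagged_channels == 0

    def test_phantom_ground_truth_recall_and_precision(self, axis, camera,
                                                       phantom_params, clean_params):
        ss = generate_spectrum_set(["high_grade"] * 60, clean_params, camera,
                                   10.0, axis, seed=17)
        spiked, truth = inject_cosmic_rays(ss, camera, phantom_params,
                                           n_per_spectrum=1, seed=18)
        out, rep = remove_cosmic_rays(spiked)
        n_truth = sum(len(t) for t in truth)
        tp = sum(len(set(t) & set(f)) for t, f in zip(truth, rep.flagged))
        fp = sum(len(set(f) - set(t)) for t, f in zip(truth, rep.flagged))
        assert tp == n_truth  # recall 1.0
        assert fp == 0
        for i in range(len(ss)):
            keep = np.setdiff1d(np.arange(ss.n_channels), rep.flagged[i])
            np.testing.assert_array_equal(out.matrix[i, keep], spiked.matrix[i, keep])

    def test_single_spectrum_rejected(self, axis):
        ss = SpectrumSet(axis=axis, matrix=np.ones((1, len(axis))))
        with pytest.raises(ValueError, match="median-filter fallback"):
            remove_cosmic_rays(ss)


class TestBuildReference:
    def test_identical_spectra_give_that_spectrum(self, small_axis):
        row = np.linspace(1.0, 2.0, len(small_axis)) ** 2
        ss = SpectrumSet(axis=small_axis, matrix=np.tile(row, (60, 1)))
        ref = build_reference(ss, k=50)
        np.testing.assert_allclose(ref.intensities, row, rtol=1e-12)

    def test_k_equals_n_is_plain_mean(self, rng):
        ss = random_spectrum_set(rng, n=8, p=40)
        ref = build_reference(ss, k=8)
        np.testing.assert_allclose(ref.intensities, ss.matrix.mean(axis=0), rtol=1e-12)

    def test_corrupted_spectra_excluded_from_top_k(self, axis, camera, clean_params):
        quiet = dataclasses.replace(clean_params, cr_sigma=0.02, cb_sigma=0.02)
        ss = generate_spectrum_set(["high_grade"] * 100, quiet, camera, 10.0,
                                   axis, seed=5)
        g = np.random.default_rng(6)
        bad = g.choice(100, size=40, replace=False)
        M = ss.matrix.copy()
        M[bad] += g.normal(0, 40 * M.std(), size=(40, ss.n_channels))
        corrupted = ss.with_matrix(M)
        ref = build_reference(corrupted, k=50)
        clean_rows = np.delete(M, bad, axis=0)
        # the reference must be built purely from uncorrupted spectra: it
        # cannot sit closer to any corrupted spectrum than to the clean mean
        resid_clean = np.linalg.norm(ref.intensities - clean_rows.mean(axis=0))
        assert resid_clean < 0.05 * np.linalg.norm(clean_rows.mean(axis=0))

    def test_too_few_spectra(self, rng):
        ss = random_spectrum_set(rng, n=5)
        with pytest.raises(ValueError):
            build_reference(ss, k=50)


class TestBuildSubstrateReference:
    def test_constant_preserved(self, small_axis):
        ss = SpectrumSet(axis=small_axis, matrix=np.full((1, len(small_axis)), 3.5))
        ref = build_substrate_reference(ss)
        np.testing.assert_allclose(ref.intensities, 3.5, rtol=1e-12)

    def test_mean_linearity(self, rng):
        ss = random_spectrum_set(rng, n=2, p=60)
        joint = build_substrate_reference(ss)
        mean_first = build_substrate_reference(
            SpectrumSet(axis=ss.axis, matrix=ss.matrix.mean(axis=0, keepdims=True))
        )
        np.testing.assert_allclose(joint.intensities, mean_first.intensities, rtol=1e-10)

    def test_cubic_profile_unchanged(self, small_axis):
        t = np.linspace(-1, 1, len(small_axis))
        cubic = 5.0 + 2.0 * t - 3.0 * t**2 + 0.7 * t**3
        ss = SpectrumSet(axis=small_axis, matrix=cubic[None, :])
        ref = build_substrate_reference(ss)
        np.testing.assert_allclose(ref.intensities[4:-4], cubic[4:-4], atol=1e-10)


class TestEMSC:
    def make_components(self, axis):
        p = SpectralPhantomParams()
        R = Spectrum(axis, class_signature("high_grade", p, axis) + 50.0, "ref")
        B = Spectrum(axis, glass_profile(p, axis) + 20.0, "glass")
        return R, B

    def test_identity_recovery(self, axis):
        R, _ = self.make_components(axis)
        res = emsc_correct(R, R)
        assert res.cr == pytest.approx(1.0, abs=1e-10)
        assert res.cb == 0.0
        np.testing.assert_allclose(res.cm, 0.0, atol=1e-8)
        np.testing.assert_allclose(res.corrected.intensities, R.intensities, atol=1e-8)

    def test_construct_and_recover(self, axis):
        R, B = self.make_components(axis)
        P = _legendre_basis(axis, 5)
        x0 = Spectrum(axis, 2.0 * R.intensities + 3.0 * B.intensities
                      + 0.5 * P[:, 0] + 1.2 * P[:, 1], "x0")
        res = emsc_correct(x0, R, B)
        assert res.cr == pytest.approx(2.0, abs=1e-8)
        assert res.cb == pytest.approx(3.0, abs=1e-8)
        np.testing.assert_allclose(res.cm[:2], [0.5, 1.2], atol=1e-8)
        np.testing.assert_allclose(res.corrected.intensities, R.intensities, atol=1e-8)
        # independent oracle: normal equations solved directly
        D = np.column_stack([R.intensities, B.intensities, P])
        beta = np.linalg.solve(D.T @ D, D.T @ x0.intensities)
        assert res.cr == pytest.approx(beta[0], abs=1e-8)
        assert res.cb == pytest.approx(beta[1], abs=1e-8)

    def test_collinear_substrate_rejected(self, axis):
        R, _ = self.make_components(axis)
        with pytest.raises(CollinearityError, match="substrate"):
            emsc_correct(R, R, substrate=R)

    def test_scale_equivariance(self, axis, rng):
        R, B = self.make_components(axis)
        x0 = Spectrum(axis, 1.5 * R.intensities + 0.5 * B.intensities
                      + rng.normal(0, 1.0, len(axis)), "x0")
        base = emsc_correct(x0, R, B)
        scaled = emsc_correct(Spectrum(axis, 4.0 * x0.intensities, "s"), R, B)
        assert scaled.cr == pytest.approx(4.0 * base.cr, rel=1e-10)
        np.testing.assert_allclose(scaled.corrected.intensities,
                                   base.corrected.intensities, rtol=1e-8)

    def test_negative_fit_rejected(self, axis):
        R, _ = self.make_components(axis)
        x0 = Spectrum(axis, -R.intensities, "neg")
        with pytest.raises(DegenerateFitError):
            emsc_correct(x0, R)

    def test_noise_free_phantom_residual_vanishes(self, axis, rng):
        # the pipeline's analogue of glass/baseline removal on real data
        R, B = self.make_components(axis)
        P = _legendre_basis(axis, 5)
        for _ in range(10):
            cr = rng.uniform(0.5, 2.0)
            cb = rng.uniform(0.1, 3.0)
            cm = rng.uniform(-5, 5, size=6)
            x0 = Spectrum(axis, cr * R.intensities + cb * B.intensities + P @ cm, "x")
            res = emsc_correct(x0, R, B)
            assert res.residual_norm < 1e-8
            np.testing.assert_allclose(res.corrected.intensities, R.intensities,
                                       atol=1e-8)


class TestSavitzkyGolay:
    def test_cubic_invariant_interior(self, small_axis):
        t = np.linspace(-1, 1, len(small_axis))
        cubic = 1.0 - 2.0 * t + 0.5 * t**2 + 4.0 * t**3
        out = savitzky_golay(Spectrum(small_axis, cubic, "c"))
        np.testing.assert_allclose(out.intensities[3:-3], cubic[3:-3], atol=1e-10)

    def test_constant_exact(self, small_axis):
        const = np.full(len(small_axis), 2.25)
        out = savitzky_golay(Spectrum(small_axis, const, "k"))
        np.testing.assert_allclose(out.intensities, const, rtol=1e-14)

    def test_matches_sliding_least_squares_oracle(self, small_axis, rng):
        y = rng.normal(100.0, 5.0, len(small_axis))
        window, order = 7, 3
        out = savitzky_golay(Spectrum(small_axis, y, "r"), window, order)
        half = window // 2
        for c in range(half, len(y) - half):
            idx = np.arange(c - half, c + half + 1)
            coef = np.polyfit(idx - c, y[idx], order)
            assert out.intensities[c] == pytest.approx(np.polyval(coef, 0.0),
                                                       abs=1e-10)

    @pytest.mark.parametrize("window,order", [(6, 3), (7, 7), (3, 3)])
    def test_bad_parameters_rejected(self, small_axis, rng, window, order):
        s = Spectrum(small_axis, rng.normal(size=len(small_axis)), "x")
        with pytest.raises(ValueError):
            savitzky_golay(s, window, order)


class TestQualityCull:
    def test_all_equal_reference_retained(self, small_axis, rng):
        ref_vals = rng.uniform(1, 10, len(small_axis))
        ss = SpectrumSet(axis=small_axis, matrix=np.tile(ref_vals, (5, 1)))
        _, rep = quality_cull(ss, Spectrum(small_axis, ref_vals, "ref"))
        assert rep.retention_fraction == 1.0

    def test_anticorrelated_spectrum_culled(self, small_axis, rng):
        ref_vals = rng.uniform(1, 10, len(small_axis))
        ss = SpectrumSet(axis=small_axis, matrix=np.vstack([ref_vals, -ref_vals]))
        kept, rep = quality_cull(ss, Spectrum(small_axis, ref_vals, "ref"))
        assert len(kept) == 1
        np.testing.assert_array_equal(rep.retained, [True, False])

    def test_retention_monotone_in_noise(self, small_axis, rng):
        ref_vals = 100.0 + 50.0 * np.sin(np.linspace(0, 8, len(small_axis)))
        ref = Spectrum(small_axis, ref_vals, "ref")
        retentions = []
        for scale in (0.1, 0.5, 1.0, 3.0, 10.0):
            noise = rng.normal(0, scale * 5.0, size=(80, len(small_axis)))
            ss = SpectrumSet(axis=small_axis, matrix=ref_vals + noise)
            _, rep = quality_cull(ss, ref)
            retentions.append(rep.retention_fraction)
        assert all(a >= b for a, b in zip(retentions, retentions[1:]))
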