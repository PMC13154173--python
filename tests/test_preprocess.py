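"""Clip/mask/bucket/PQN/scale chain: counts, identities, leakage."""

import logging

import numpy as np
import pytest

import cellfp
from cellfp.synth import AcquisitionParams, MetaboliteLibrary, MetabolitePeak, clean_signal


def flat_spectrum(value=1.0, n=4096):
    ppm = np.linspace(9.4, -0.5, n)
    return cellfp.Spectrum(ppm, np.full(n, float(value)), "flat")


class TestClipAndMask:
    def test_water_region_zeroed_rest_kept(self):
        out = cellfp.clip_and_mask(flat_spectrum(), cellfp.PreprocessSpec())
        assert out.ppm.max() <= 8.6 and out.ppm.min() >= -0.1
        water = (out.ppm > 4.6) & (out.ppm < 5.1)
        assert np.all(out.intensities[water] == 0.0)
        assert np.all(out.intensities[~water] == 1.0)

    def test_empty_mask_is_pure_clip(self):
        spec = cellfp.PreprocessSpec(mask_ranges=[])
        out = cellfp.clip_and_mask(flat_spectrum(), spec)
        assert np.all(out.intensities == 1.0)

    def test_uncovered_range_rejected(self):
        ppm = np.linspace(5.0, 0.0, 500)
        s = cellfp.Spectrum(ppm, np.ones(500), "short")
        with pytest.raises(ValueError, match="cover"):
            cellfp.clip_and_mask(s, cellfp.PreprocessSpec())


class TestBucket:
    def test_default_grid_has_217_buckets(self):
        assert cellfp.n_buckets(cellfp.PreprocessSpec()) == 217
        fm = cellfp.bucket(cellfp.clip_and_mask(flat_spectrum(), cellfp.PreprocessSpec()),
                           cellfp.PreprocessSpec())
        assert fm.n_features == 217

    def test_drop_water_gives_205(self):
        spec = cellfp.PreprocessSpec(water_buckets="drop")
        assert cellfp.n_buckets(spec) == 205
        fm = cellfp.bucket(cellfp.clip_and_mask(flat_spectrum(), spec), spec)
        assert fm.n_features == 205

    def test_constant_spectrum_mean_stat(self):
        spec = cellfp.PreprocessSpec(mask_ranges=[], bucket_stat="mean")
        fm = cellfp.bucket(cellfp.clip_and_mask(flat_spectrum(3.5), spec), spec)
        np.testing.assert_allclose(fm.values, 3.5, rtol=1e-12)

    def test_narrow_unit_peak_lands_in_one_bucket(self):
        lib = MetaboliteLibrary({"m": [MetabolitePeak(3.02, 1.0, natural_width_hz=0.0)]})
        acq = AcquisitionParams(inhom_width_ppm=0.001, n_points=65536, snr=np.inf)
        y = clean_signal({"m": 1.0}, acq, lib)
        s = cellfp.Spectrum(acq.grid(), y, "peak")
        spec = cellfp.PreprocessSpec(mask_ranges=[])
        fm = cellfp.bucket(cellfp.clip_and_mask(s, spec), spec)
        col = int(np.argmin(np.abs(fm.bucket_centers - 3.02)))
        # Lorentzian tails put (2/pi)atan(20) ~ 0.97 of the area in the bucket
        assert fm.values[0, col] == pytest.approx(1.0, abs=0.05)
        far = np.abs(fm.bucket_centers - 3.02) > 0.1
        assert np.all(np.abs(fm.values[0, far]) < 0.01)

    def test_masked_lorentzian_in_water_region_bucketed_to_zero(self):
        lib = MetaboliteLibrary({"w": [MetabolitePeak(4.8, 5.0, natural_width_hz=0.0)]})
        acq = AcquisitionParams(snr=np.inf)
        s = cellfp.Spectrum(acq.grid(), clean_signal({"w": 1.0}, acq, lib), "water")
        spec = cellfp.PreprocessSpec()
        fm = cellfp.bucket(cellfp.clip_and_mask(s, spec), spec)
        inside = (fm.bucket_centers > 4.65) & (fm.bucket_centers < 5.05)
        assert np.all(np.abs(fm.values[0, inside]) < 1e-3)

    def test_width_larger_than_range_rejected(self):
        spec = cellfp.PreprocessSpec(keep_low_ppm=1.0, keep_high_ppm=1.5,
                                     bucket_width_ppm=2.0, mask_ranges=[])
        with pytest.raises(ValueError, match="width"):
            cellfp.bucket(cellfp.clip_and_mask(flat_spectrum(), spec), spec)


def toy_matrix(values, state="raw"):
    values = np.atleast_2d(np.asarray(values, float))
    p = values.shape[1]
    uppers = 8.6 - 0.04 * np.arange(p)
    return cellfp.FeatureMatrix(values, uppers - 0.02,
                                np.column_stack([uppers, uppers - 0.04]),
                                [f"s{i}" for i in range(values.shape[0])], state)


class TestPQN:
    def test_identical_unit_mean_rows_unchanged(self):
        row = np.array([0.5, 2.0, 1.0, 0.5, 1.0])
        assert row.mean() == 1.0
        m = toy_matrix(np.tile(row, (4, 1)))
        res = cellfp.pqn(m)
        np.testing.assert_allclose(res.quotient_medians, 1.0, atol=1e-12)
        np.testing.assert_allclose(res.normalized.values, m.values, atol=1e-12)

    def test_pure_dilution_rows_recovered(self):
        row = np.abs(np.random.default_rng(0).normal(1.0, 0.2, 30))
        m = toy_matrix(np.vstack([row, 2 * row, 4 * row]))
        res = cellfp.pqn(m)
        ratios = res.quotient_medians / res.quotient_medians[0]
        np.testing.assert_allclose(ratios, [1.0, 2.0, 4.0], rtol=1e-10)
        for i in range(1, 3):
            np.testing.assert_allclose(res.normalized.values[i],
                                       res.normalized.values[0], rtol=1e-10)

    def test_global_scale_invariance_exact(self):
        rng = np.random.default_rng(1)
        m = toy_matrix(np.abs(rng.normal(1.0, 0.3, size=(6, 40))))
        a = cellfp.pqn(m).normalized.values
        b = cellfp.pqn(toy_matrix(7.3 * m.values)).normalized.values
        np.testing.assert_allclose(a, b, rtol=1e-13)  # exact up to rounding

    def test_all_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            cellfp.pqn(toy_matrix(np.zeros((3, 5))))

    def test_dilution_recovery_from_simulation(self):
        """End-to-end: estimated dilutions track the simulated truth."""
        from scipy.stats import pearsonr
        design = cellfp.DatasetDesign(classes=cellfp.default_profiles(["neuron"]),
                                      n_per_class=60, dilution_log_sd=0.3, seed=7)
        spectra, truth = cellfp.simulate_dataset(design)
        res = cellfp.preprocess(spectra)
        r = pearsonr(res.quotient_medians, truth["dilution"])[0]
        assert r >= 0.95


class TestScaler:
    def test_train_columns_standardized(self):
        rng = np.random.default_rng(2)
        m = toy_matrix(rng.normal(3.0, 2.0, size=(20, 10)))
        state = cellfp.fit_scaler(m)
        z = cellfp.apply_scaler(state, m).values
        assert np.max(np.abs(z.mean(axis=0))) < 1e-10
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-10)

    def test_already_standardized_unchanged(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 6))
        X = (X - X.mean(0)) / X.std(0)
        m = toy_matrix(X)
        z = cellfp.apply_scaler(cellfp.fit_scaler(m), m).values
        np.testing.assert_allclose(z, X, atol=1e-10)

    def test_constant_column_zeroed_with_warning(self, caplog):
        X = np.random.default_rng(4).normal(size=(10, 3))
        X[:, 1] = 42.0
        m = toy_matrix(X)
        with caplog.at_level(logging.WARNING, logger="cellfp.preprocess"):
            state = cellfp.fit_scaler(m)
        assert "zero-variance" in caplog.text
        z = cellfp.apply_scaler(state, m).values
        assert np.all(z[:, 1] == 0.0)

    def test_held_out_rows_use_training_statistics(self):
        rng = np.random.default_rng(5)
        train, test = toy_matrix(rng.normal(size=(15, 8))), toy_matrix(rng.normal(size=(4, 8)))
        state = cellfp.fit_scaler(train)
        z = cellfp.apply_scaler(state, test).values
        brute = (test.values - train.values.mean(0)) / train.values.std(0)
        np.testing.assert_allclose(z, brute, atol=1e-12)

    def test_no_leakage_from_validation_rows(self):
        rng = np.random.default_rng(6)
        train = toy_matrix(rng.normal(size=(12, 5)))
        state1 = cellfp.fit_scaler(train)
        _ = cellfp.apply_scaler(state1, toy_matrix(rng.normal(size=(7, 5))))
        state2 = cellfp.fit_scaler(train)
        np.testing.assert_array_equal(state1.means, state2.means)
        np.testing.assert_array_equal(state1.sds, state2.sds)
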