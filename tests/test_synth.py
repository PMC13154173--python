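"""Generator correctness: lineshapes, field scaling, mixtures, determinism."""

import math

import numpy as np
import pytest

import cellfp
from cellfp.synth import (AcquisitionParams, MetaboliteLibrary, MetabolitePeak,
                          clean_signal)

NOISELESS = dict(snr=np.inf)


def singlet_library(width_hz=0.0):
    return MetaboliteLibrary({"m": [MetabolitePeak(3.0, 1.0, natural_width_hz=width_hz)]})


class TestLibrary:
    def test_expected_marker_peaks_present(self):
        lib = cellfp.default_library()
        centers = [p.center_ppm for peaks in lib.metabolites.values() for p in peaks]
        for expected in (1.95, 6.01, 8.30, 3.03, 1.33):
            assert any(abs(c - expected) < 1e-6 for c in centers)

    def test_crowded_region_and_humps(self):
        lib = cellfp.default_library()
        crowded = {name for name, peaks in lib.metabolites.items()
                   if any(3.2 <= p.center_ppm <= 4.0 for p in peaks)}
        assert len(crowded) >= 6
        assert len(lib.macromolecule_humps) >= 3

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            MetabolitePeak(1.0, amplitude=-1.0)
        with pytest.raises(ValueError):
            MetaboliteLibrary({"x": [MetabolitePeak(10.2, 1.0)]})


class TestRenderSpectrum:
    def test_empty_profile_renders_zero(self):
        profile = cellfp.ClassProfile("empty", {}, 0.0, macro_level=0.0)
        acq = AcquisitionParams(**NOISELESS)
        spec, truth = cellfp.render_spectrum(profile, acq, cellfp.default_library(),
                                             np.random.default_rng(0))
        assert np.all(spec.intensities == 0.0)

    def test_unit_singlet_height_and_area(self):
        acq = AcquisitionParams(field_mhz=500, inhom_width_ppm=0.02,
                                n_points=16384, **NOISELESS)
        y = clean_signal({"m": 1.0}, acq, singlet_library())
        assert y.max() == pytest.approx(1 / (math.pi * 0.02), rel=1e-4)
        area = abs(np.trapezoid(y[::-1], acq.grid()[::-1]))
        assert area == pytest.approx(1.0, rel=0.01)

    def test_field_invariance_when_inhomogeneity_dominates(self):
        lib = singlet_library(width_hz=0.0)
        y_low = clean_signal({"m": 2.0}, AcquisitionParams(field_mhz=400, **NOISELESS), lib)
        y_high = clean_signal({"m": 2.0}, AcquisitionParams(field_mhz=950, **NOISELESS), lib)
        np.testing.assert_allclose(y_low, y_high, rtol=0, atol=1e-10)

    def test_j_splitting_scales_with_field(self):
        lib = MetaboliteLibrary({"d": [MetabolitePeak(2.0, 1.0, j_hz=7.0, multiplicity=2,
                                                      natural_width_hz=0.0)]})
        acq = AcquisitionParams(field_mhz=400, inhom_width_ppm=0.001,
                                n_points=32768, **NOISELESS)
        y = clean_signal({"d": 1.0}, acq, lib)
        x = acq.grid()
        # doublet lines at center +- J/2 on the Hz axis => +- J/(2*field) ppm
        peaks = x[np.flatnonzero((y > np.roll(y, 1)) & (y > np.roll(y, -1)) & (y > y.max() / 2))]
        assert len(peaks) == 2
        assert abs(peaks[0] - peaks[1]) == pytest.approx(7.0 / 400, rel=0.05)

    def test_cpmg_attenuates_macromolecule_humps(self):
        lib = MetaboliteLibrary({}, [(2.0, 0.3, 1.0), (7.0, 0.5, 0.5)])
        grid = AcquisitionParams().grid()[::-1]
        areas = {}
        for exp in ("cpmg", "excitation_sculpting"):
            y = clean_signal({}, AcquisitionParams(experiment=exp, **NOISELESS),
                             lib, macro_level=1.0)
            areas[exp] = np.trapezoid(y[::-1], grid)
        assert areas["cpmg"] / areas["excitation_sculpting"] == pytest.approx(0.05, rel=1e-6)

    def test_dilution_is_pure_global_scale(self):
        profile = cellfp.default_profiles(["neuron"])[0]
        lib = cellfp.default_library()
        acq = AcquisitionParams(**NOISELESS)
        rng = np.random.default_rng(0)
        conc = cellfp.synth.draw_concentrations(profile, lib, rng)
        s1, _ = cellfp.render_spectrum(profile, acq, lib, rng, concentrations=conc,
                                       dilution=1.0)
        s2, _ = cellfp.render_spectrum(profile, acq, lib, rng, concentrations=conc,
                                       dilution=2.5)
        np.testing.assert_allclose(s2.intensities, 2.5 * s1.intensities, rtol=1e-12)

    def test_snr_must_be_positive(self):
        with pytest.raises(ValueError):
            AcquisitionParams(snr=-1.0)


class TestMixSpectra:
    def make(self, rng, n=300):
        ppm = np.linspace(9.0, -0.4, n)
        return (cellfp.Spectrum(ppm, rng.normal(size=n), "a"),
                cellfp.Spectrum(ppm, rng.normal(size=n), "b"))

    def test_fraction_one_returns_first(self):
        a, b = self.make(np.random.default_rng(0))
        m = cellfp.mix_spectra(a, b, 1.0)
        np.testing.assert_array_equal(m.intensities, a.intensities)
        assert m.sample_id == "a+b"

    def test_half_mix_of_opposites_is_zero(self):
        a, b = self.make(np.random.default_rng(1))
        neg = cellfp.Spectrum(a.ppm, -a.intensities, "b")
        m = cellfp.mix_spectra(a, neg, 0.5)
        np.testing.assert_allclose(m.intensities, 0.0, atol=1e-15)

    @pytest.mark.parametrize("fraction", [0.2, 0.5, 0.73])
    def test_area_is_convex_combination(self, fraction):
        a, b = self.make(np.random.default_rng(2))
        x = a.ppm[::-1]
        area = lambda s: np.trapezoid(s.intensities[::-1], x)  # noqa: E731
        m = cellfp.mix_spectra(a, b, fraction)
        assert area(m) == pytest.approx(fraction * area(a) + (1 - fraction) * area(b),
                                        rel=1e-10, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        a, _ = self.make(np.random.default_rng(3))
        other = cellfp.Spectrum(np.linspace(8.0, 0.0, 300), np.zeros(300), "c")
        with pytest.raises(ValueError, match="grid"):
            cellfp.mix_spectra(a, other, 0.5)


class TestSimulateDataset:
    def test_sample_counting(self):
        design = cellfp.DatasetDesign(classes=cellfp.default_profiles(
            ["neuron", "astrocyte", "npc", "apc"]), n_per_class=10,
            fields_mhz=(950.0,), seed=0, n_points=512)
        spectra, truth = cellfp.simulate_dataset(design)
        assert len(spectra) == 40
        assert len(truth) == 40

    def test_determinism_bit_identical(self):
        design = cellfp.mixture_design(3, n_per_class=4, n_per_pair=2)
        design.n_points = 512
        s1, t1 = cellfp.simulate_dataset(design)
        s2, t2 = cellfp.simulate_dataset(design)
        assert s1.sample_ids == s2.sample_ids
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.intensities, b.intensities)
        assert t1.equals(t2)

    def test_designed_lactate_gap_appears_in_buckets(self):
        base = cellfp.default_profiles(["neuron"])[0].log_mean_concentrations
        hi = dict(base)
        hi["lactate"] = base["lactate"] + 1.0
        classes = [cellfp.ClassProfile("lo", dict(base), 0.2),
                   cellfp.ClassProfile("hi", hi, 0.2)]
        design = cellfp.DatasetDesign(classes=classes, n_per_class=50, seed=4,
                                      dilution_log_sd=0.0)
        spectra, truth = cellfp.simulate_dataset(design)
        matrix = cellfp.bucket_spectra(spectra, cellfp.PreprocessSpec())
        col = int(np.argmin(np.abs(matrix.bucket_centers - 1.33)))
        labels = np.array(spectra.labels())
        lo = matrix.values[labels == "lo", col]
        hi_v = matrix.values[labels == "hi", col]
        # designed log-mean gap of 1.0 => ratio of means near e
        assert hi_v.mean() / lo.mean() == pytest.approx(math.e, rel=0.2)

    def test_replicates_share_latents_across_fields(self):
        design = cellfp.cross_field_design(5, n_per_class=2)
        _, truth = cellfp.simulate_dataset(design)
        one = truth[truth.sample_id.str.startswith("neuron_r00")]
        assert one["dilution"].nunique() == 1
        assert one["conc_lactate"].nunique() == 1

    def test_empty_class_list_rejected(self):
        with pytest.raises(ValueError):
            cellfp.DatasetDesign(classes=[])
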